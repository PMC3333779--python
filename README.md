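# codonbias

Genome-scale analysis of codon usage bias in prokaryotes.

Synonymous codons are not used interchangeably: in many bacteria and
archaea, highly expressed genes — classically represented by the
ribosomal-protein genes — concentrate on a subset of "preferred"
codons, a signature of translational selection. `codonbias` measures
this at two scales and provides the statistical layer to relate the
organism-scale measures to phenotype and phylogeny:

- **Per gene** — the Codon Adaptation Index (CAI): the geometric mean
  of relative-adaptiveness weights `w_c = f_c / f_max` derived from
  the pooled ribosomal genes (range (0, 1]); Wright's effective number
  of codons `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, where `F̄_k` is
  the mean codon homozygosity of the k-fold degenerate families (range
  [20, 61]); and GC content.
- **Per organism** — `CAI_ave` (mean CAI over all genes; *low* values
  mark *biased* genomes in which preferred codons are confined to the
  highly expressed minority), the coefficient of variation of CAI,
  `Nc_diff = (Nc(all) − Nc(rib)) / Nc(all)`, and the mean absolute
  within-family codon-frequency difference between ribosomal and
  other genes.
- **Comparative statistics** — Mann-Whitney / Kruskal-Wallis contrasts
  of bias measures between phenotype groups (pathogenicity, oxygen
  requirement, salinity, temperature range, habitat), chi-square trait
  interdependence, Pearson and first-order partial correlations
  (e.g. growth rate vs bias controlling for habitat), and correlation
  of pairwise |ΔCAI_ave| with patristic tree distance.
- **A genome simulator** — genes drawn under a mutation–selection
  codon-choice model `P(c) ∝ μ_c · exp(S·x_g·δ_c)` with tunable GC
  parameter θ, selection strength S and per-gene expression x_g, with
  a per-gene ground-truth table. This makes every analysis testable
  against genomes whose true selection regime is known.

## Worked example

```python
from codonbias import SimulationConfig, simulate_genome, profile_genome

biased, _ = simulate_genome(SimulationConfig(seed=7, selection=4.0))
unbiased, _ = simulate_genome(SimulationConfig(seed=7, selection=0.0))
for name, recs in [("biased (S=4)", biased), ("unbiased (S=0)", unbiased)]:
    p = profile_genome(recs, name)
    print(f"{name}: CAI_ave={p.cai_ave:.3f}  CV={p.cai_cv:.3f}  "
          f"Nc(rib)={p.nc_rib:.1f}  Nc(all)={p.nc_all:.1f}  "
          f"Nc_diff={p.nc_diff:.3f}  GC={p.gc:.3f}")
```

prints

```
biased (S=4): CAI_ave=0.289  CV=0.931  Nc(rib)=21.6  Nc(all)=51.3  Nc_diff=0.579  GC=0.436
unbiased (S=0): CAI_ave=0.918  CV=0.007  Nc(rib)=59.8  Nc(all)=59.8  Nc_diff=0.001  GC=0.467
```

Under strong selection (S = 4) the ribosomal genes collapse onto
preferred codons (Nc(rib) ≈ 21.6, near the theoretical floor of 20)
while typical genes do not, so CAI_ave is low, its dispersion high and
Nc_diff large. With no selection the two gene classes are
indistinguishable: CAI_ave is high and Nc_diff ≈ 0.

Real genomes enter the same way: `read_cds_fasta` /
`read_genbank_cds` → `flag_ribosomal_genes` (product-annotation
patterns or an explicit id list) → `profile_genome`, then `gc_filter`
(retaining 0.35 < GC < 0.65), `compare_trait_groups`,
`partial_correlation` and `bias_distance_correlation` for the
comparative analyses.

## Command line

```
codonbias simulate --config cfg.json --out sim/       # seed mandatory
codonbias profile sim/*.fasta --out prof/
codonbias compare --profiles prof/profiles.tsv \
    --phenotypes pheno.tsv --trait habitat --out cmp/
codonbias phylo --profiles prof/profiles.tsv --tree tree.nwk --out phy/
```

Each subcommand is a thin wrapper over the library and writes TSV
tables plus a JSON config echo; exit codes are 0 (success), 1 (usage)
and 2 (data error).

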