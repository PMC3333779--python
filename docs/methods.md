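# Methods

## Measures

**CAI.** For each genome the relative adaptiveness of codon `c` is
`w_c = f_c / f_max`, the frequency of `c` among the pooled
ribosomal-protein genes divided by the frequency of the commonest
synonym in the same family. A gene's CAI is the geometric mean of
`w_c` over its codon occurrences, computed in log space for underflow
safety. Met and Trp (single-codon families) and stop codons are
excluded — they carry no synonymous-choice signal. Codons absent from
the reference set receive a pseudo-weight of 0.01 (configurable) so
that CAI never degenerates to zero; a family wholly absent from the
reference gets the pseudo-weight for all members, with a warning.

**Nc.** Within each synonymous family with count `n ≥ 2` the codon
homozygosity is estimated with Wright's bias-corrected form
`F̂ = (n·Σp_i² − 1)/(n − 1)`. Class means `F̄_k` are taken over the
families of degeneracy k ∈ {2, 3, 4, 6} with defined, positive `F̂`
(non-positive estimates arise from tiny samples and are excluded),
and

    Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.

Missing classes: an absent 3-fold class (the code's only 3-fold family
is Ile) is imputed as `(F̄₂ + F̄₄)/2` — Wright's own recommendation —
and an absent 6-fold class as `F̄₄`, a symmetric extension; if the 2-
or 4-fold class is missing the gene's Nc is undefined. Finite-sample
noise inflates Nc slightly above 61 for near-uniform genes (uniform
usage at count 100 per codon gives 61.41 analytically), so reported
values are capped into [20, 61]; the pre-cap value is available via
`nc(..., cap=False)` and is what the oracle-equivalence tests compare.
Genes with fewer than 30 codons in degenerate families are reported as
undefined rather than unstable.

**Organism scale.** `CAI_ave` is the arithmetic mean of CAI over *all*
defined genes (ribosomal included); `Nc(rib)` and `Nc(all)` average Nc
over the ribosomal and the *non-ribosomal* genes respectively, and
`Nc_diff = (Nc(all) − Nc(rib))/Nc(all)`. The asymmetry — CAI averaged
over everything, Nc(all) over the rest only — is preserved
deliberately, matching how the two organism measures are defined. The
coefficient of variation is the sample (n−1) standard deviation of
per-gene CAI divided by CAI_ave. The codon-frequency difference
statistic computes, for every codon of a degenerate family present in
both the ribosomal pool and the rest-of-genome pool, the codon's
within-family frequency in each pool, and averages the *absolute*
differences; a signed mean would cancel within families and could not
produce the strong anticorrelation with CAI_ave that motivates the
measure. GC content is computed over the concatenated retained CDS
(this package ingests CDS sets, not chromosomes; the difference from
whole-genome GC is small for prokaryotes). Comparative analyses
retain genomes with 0.35 < GC < 0.65 (strict bounds): beyond that
window mutational bias alone compresses the attainable range of the
bias measures.

**Ribosomal reference set.** Identification is by case-insensitive
"ribosomal protein" in the product annotation, excluding
modification/associated enzymes (methyltransferase, pseudouridine,
acetyltransferase, kinase patterns); an explicit gene-id list
overrides. At least 20 reference genes are required — below that, the
weight table is too noisy to anchor CAI.

## Statistical layer

All tests are two-sided. Mann-Whitney uses exhaustive enumeration of
all C(n, n₁) group labelings when both groups have ≤ 8 members (exact
even under ties; the two-sided p is twice the smaller tail, capped at
1) and otherwise the tie-corrected normal approximation with
continuity correction (the correction can be disabled; without it the
two-group Kruskal-Wallis p is identical, which the tests exploit as a
cross-check). Kruskal-Wallis uses the tie-corrected H with a
chi-square (k−1 df) reference; a completely constant pooled sample is
reported as H = 0, p = 1. Trait interdependence uses Pearson's
chi-square without Yates correction, warning when expected counts fall
below 5. First-order partial correlation uses
`r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` with a t test on
n−3 df; the binary habitat code (0 = multiple habitats,
1 = specialized) enters as a numeric, i.e. point-biserially.
Patristic distances are path lengths through the most recent common
ancestor, via dendropy; newick trees lacking branch lengths get unit
lengths with a warning. The "phylogenetically remote subset" helper is
a seeded greedy maximin selection on patristic distance — the
selection rule used for published robustness subsets is not specified
anywhere, so this documented, reproducible rule stands in for it.

## The simulator

Genes are i.i.d. sequences of amino acids (uniform over the 20 by
default); within a family the codon is drawn from

    P(c) ∝ μ_c · exp(S · x_g · δ_c),
    μ_c ∝ θ^gc(c) · (1 − θ)^(3 − gc(c)),

with `gc(c)` the number of G/C positions in the codon, θ ∈ (0, 1) the
mutational GC parameter, S ≥ 0 the genome-wide selection strength,
x_g ∈ [0, 1] the gene's expression level and δ_c = 1 for the family's
single preferred codon (one per family, drawn uniformly per genome —
preferred sets genuinely differ between organisms). An ATG start and
TAA stop are added and excluded from metrics downstream.

Defaults model a scaled-down prokaryote chosen once: 200 genes (panels
use 120 to keep a 40-genome panel under a minute), 25–30 of them
ribosomal, lognormal gene lengths with median 300 codons (σ = 0.4,
clipped to [60, 2000]). Ribosomal genes are pinned at x = 1; the rest
draw x ~ Beta(1, 4), a right-skewed distribution in which few genes
are highly expressed. That skew is essential to the biased archetype:
if most genes were highly expressed, all genes would adopt preferred
codons under selection and the genome would look *unbiased* (high
CAI_ave) despite strong S. With S = 0 (or x_g = 0) codon choice is
purely mutational and the genome is unbiased by construction.

What the simulator does **not** emulate: phylogenetic correlation
between genomes (every genome is independent), amino-acid selection,
operon/strand structure, length–expression correlation, graded codon
preferences, or ambiguity codes. Passing the panel tests therefore
shows that the measures recover a known selection gradient under this
generative model — not that real annotation noise, shared ancestry or
reference-set misspecification are handled; those enter real analyses
through the ingestion and filtering layers.

## Panels and test problem sizes

The selection-gradient panel is 40 genomes with S equally spaced in
[0, 5] at fixed θ; panels at θ = 0.5 and θ = 0.9 share the same S grid
and seed stream (child seeds spawned from one seed via numpy's
SeedSequence). On this panel the suite checks Spearman(CAI_ave, S)
≤ −0.9, Spearman(Nc_diff, S) ≥ 0.9 and Pearson couplings CAI_ave vs
Nc_diff ≤ −0.7, vs CV ≤ −0.6, vs codon-frequency difference ≤ −0.7 —
the qualitative counterparts of the strong real-genome correlations —
plus the GC-extreme compression of the CAI_ave range. Statistical
calibration uses 1,000 null replicates per rank test and an n = 2,000
trivariate Gaussian with x ⊥ y | z for the partial correlation. All
stochastic tests run from one fixed suite seed.

## Numerical and degenerate-input choices

- CAI in log space; exact-rational oracles in the tests bound the
  implementation error at 1e-12 (CAI) and 1e-9 (pre-cap Nc).
- Genes failing validation (length not a multiple of 3, > 10%
  ambiguous codons) are excluded and counted, never repaired; codons
  containing ambiguity codes are skipped from all counts.
- Zero-variance inputs to correlations raise rather than return NaN;
  a control variable collinear with an input makes the partial
  correlation undefined and raises.
- Profile computation requires ≥ 20 ribosomal and ≥ 50 valid genes
  (both configurable); all-ribosomal inputs are rejected since
  Nc_diff needs a non-reference gene class.

## Known limitations

- The exact variant of the Nc estimator is a documented choice; other
  published implementations differ in missing-class and small-family
  rules, so per-gene Nc can differ by a few units between tools for
  short genes.
- The codon-frequency-difference statistic skips codons of families
  absent from either gene set rather than treating them as
  zero-frequency; both conventions are defensible and differ only for
  very small gene sets.
- Group comparisons apply no multiple-testing correction, matching
  standard practice for this analysis type; users running many traits
  should correct downstream.
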