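"""Synthetic prokaryote genomes under a mutation-selection codon model.

Each gene's amino acids are drawn i.i.d.; within a synonymous family
the codon is drawn from

    P(c)  proportional to  mu_c * exp(S * x_g * delta_c)

where mu_c ~ theta^gc(c) * (1-theta)^(3-gc(c)) is a GC-parameterised
mutational preference (gc(c) = number of G/C positions in codon c),
S >= 0 is the genome-wide strength of translational selection, x_g in
[0, 1] the gene's expression level, and delta_c = 1 for the family's
single preferred codon.  Ribosomal genes are pinned at x = 1 while the
rest draw x from a right-skewed Beta(1, 4), so only a minority of
genes is highly expressed: as S grows, preferred codons concentrate in
that minority, CAI_ave falls and Nc_diff rises — the biased-genome
archetype.  S = 0 (or x_g = 0) reproduces the unbiased archetype in
which codon choice is purely mutational.

All randomness flows from the config seed; identical configs yield
byte-identical genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .genetic_code import BACTERIAL_CODE, GeneticCode
from .io import GeneRecord
from .profile import profile_genome

START_CODON = "ATG"
STOP_CODON = "TAA"


@dataclass
class SimulationConfig:
    """Parameters of one simulated genome.

    Defaults model a scaled-down prokaryote: 200 genes of median
    length 300 codons (lognormal, clipped to [60, 2000]) of which 30
    are ribosomal.
    """

    seed: int
    n_genes: int = 200
    n_ribosomal: int = 30
    selection: float = 0.0  # S >= 0
    theta: float = 0.5  # GC parameter in (0, 1)
    length_median: float = 300.0
    length_sigma: float = 0.4
    length_min: int = 60
    length_max: int = 2000
    expression_beta: tuple[float, float] = (1.0, 4.0)
    aa_frequencies: np.ndarray | None = None  # 20-simplex, uniform default

    def validate(self, code: GeneticCode = BACTERIAL_CODE) -> None:
        errors = []
        if self.seed is None:
            errors.append("seed is mandatory")
        if self.n_genes < 50:
            errors.append("n_genes must be >= 50")
        if self.n_ribosomal < 20:
            errors.append("n_ribosomal must be >= 20")
        if self.n_ribosomal >= self.n_genes:
            errors.append("n_ribosomal must be < n_genes")
        if self.selection < 0:
            errors.append("selection strength S must be >= 0")
        if not 0 < self.theta < 1:
            errors.append("theta must lie in (0, 1)")
        if not 0 < self.length_min <= self.length_max:
            errors.append("invalid gene-length bounds")
        if self.aa_frequencies is not None:
            freqs = np.asarray(self.aa_frequencies, dtype=float)
            if freqs.shape != (len(code.families),) or freqs.min() < 0 \
                    or not np.isclose(freqs.sum(), 1.0):
                errors.append("aa_frequencies must be a 20-simplex")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))


@dataclass
class TruthTable:
    """Per-gene ground truth of one simulated genome."""

    selection: float
    theta: float
    preferred: dict[str, str]  # amino acid -> preferred codon
    genes: pd.DataFrame  # gene_id, x_g, is_ribosomal, length, pref. fraction
    codon_counts: pd.DataFrame = field(repr=False, default=None)


def sample_preferred_codons(code: GeneticCode = BACTERIAL_CODE,
                            rng: np.random.Generator | None = None,
                            gc_lean: float | None = None) -> dict[str, str]:
    """Pick one preferred codon per degenerate family.

    Uniform by default; with ``gc_lean`` in (0, 1) codons are weighted
    by gc_lean^gc(c)*(1-gc_lean)^(3-gc(c)), letting preferred sets lean
    toward the mutational GC regime.
    """
    rng = rng if rng is not None else np.random.default_rng()
    preferred = {}
    for aa, fam in sorted(code.degenerate_families().items()):
        if gc_lean is None:
            preferred[aa] = fam[rng.integers(len(fam))]
        else:
            w = np.array([gc_lean ** _gc(c) * (1 - gc_lean) ** (3 - _gc(c))
                          for c in fam])
            preferred[aa] = fam[rng.choice(len(fam), p=w / w.sum())]
    return preferred


def _gc(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def codon_choice_probs(family: tuple[str, ...], theta: float, s: float,
                       x_g: float, preferred: str | None) -> np.ndarray:
    """Within-family codon-choice distribution."""
    w = np.array([theta ** _gc(c) * (1 - theta) ** (3 - _gc(c))
                  for c in family], dtype=float)
    if preferred is not None and s > 0 and x_g > 0:
        w *= np.exp(s * x_g * np.array(
            [1.0 if c == preferred else 0.0 for c in family]))
    return w / w.sum()


def simulate_gene(length: int, x_g: float, config: SimulationConfig,
                  preferred: dict[str, str], rng: np.random.Generator, *,
                  gene_id: str = "gene", is_ribosomal: bool = False,
                  code: GeneticCode = BACTERIAL_CODE):
    """Simulate one CDS of ``length`` body codons (plus start/stop).

    Returns (GeneRecord, codon count Series over the sense codons).
    """
    if length < 1:
        raise ValueError("gene length must be >= 1 codon")
    aas = sorted(code.families)
    if config.aa_frequencies is None:
        aa_p = np.full(len(aas), 1.0 / len(aas))
    else:
        aa_p = np.asarray(config.aa_frequencies, dtype=float)
    aa_idx = rng.choice(len(aas), size=length, p=aa_p)

    codons = np.empty(length, dtype="<U3")
    counts = pd.Series(0, index=sorted(code.codon_to_aa), dtype=int)
    for i, aa in enumerate(aas):
        pos = np.flatnonzero(aa_idx == i)
        if pos.size == 0:
            continue
        fam = code.families[aa]
        p = codon_choice_probs(fam, config.theta, config.selection, x_g,
                               preferred.get(aa))
        draws = rng.choice(len(fam), size=pos.size, p=p)
        codons[pos] = np.array(fam)[draws]
        idx, cnt = np.unique(draws, return_counts=True)
        for j, c in zip(idx, cnt):
            counts[fam[j]] += int(c)

    seq = START_CODON + "".join(codons) + STOP_CODON
    counts[START_CODON] += 1
    record = GeneRecord(gene_id=gene_id, sequence=seq,
                        is_ribosomal=is_ribosomal,
                        product=("50S ribosomal protein (simulated)"
                                 if is_ribosomal else None))
    return record, counts


def simulate_genome(config: SimulationConfig, *,
                    organism_id: str = "sim",
                    code: GeneticCode = BACTERIAL_CODE):
    """Simulate a whole genome; returns (records, TruthTable).

    The first ``n_ribosomal`` genes are the ribosomal reference set
    (expression pinned at 1); gene ids encode the ribosomal flag.
    """
    config.validate(code)
    rng = np.random.default_rng(config.seed)
    preferred = sample_preferred_codons(code, rng)

    lengths = np.clip(np.round(rng.lognormal(
        np.log(config.length_median), config.length_sigma,
        size=config.n_genes)).astype(int),
        config.length_min, config.length_max)
    a, b = config.expression_beta
    x = rng.beta(a, b, size=config.n_genes)
    x[:config.n_ribosomal] = 1.0

    records, truth_rows, count_rows = [], [], []
    for g in range(config.n_genes):
        is_rib = g < config.n_ribosomal
        gid = f"{organism_id}_{'rib' if is_rib else 'gene'}_{g:04d}"
        rec, counts = simulate_gene(
            int(lengths[g]), float(x[g]), config, preferred, rng,
            gene_id=gid, is_ribosomal=is_rib, code=code)
        records.append(rec)
        count_rows.append(counts.rename(gid))
        n_pref = sum(counts[c] for c in preferred.values())
        n_deg = sum(counts[c]
                    for fam in code.degenerate_families().values()
                    for c in fam)
        truth_rows.append({
            "gene_id": gid, "x_g": float(x[g]), "is_ribosomal": is_rib,
            "length_codons": int(lengths[g]),
            "preferred_fraction": n_pref / n_deg if n_deg else np.nan,
        })

    truth = TruthTable(
        selection=config.selection, theta=config.theta, preferred=preferred,
        genes=pd.DataFrame(truth_rows),
        codon_counts=pd.DataFrame(count_rows))
    return records, truth


@dataclass
class PanelGenome:
    organism_id: str
    config: SimulationConfig
    records: list
    truth: TruthTable


def simulate_panel(configs: list[SimulationConfig], *,
                   profile: bool = True,
                   code: GeneticCode = BACTERIAL_CODE):
    """Simulate one genome per config.

    Returns (list of PanelGenome, profile DataFrame with ground-truth
    S and theta columns); the profile table is None when ``profile``
    is disabled.
    """
    if len(configs) < 2:
        raise ValueError("a panel needs >= 2 configs")
    genomes, rows = [], []
    for i, cfg in enumerate(configs):
        oid = f"genome_{i:03d}"
        records, truth = simulate_genome(cfg, organism_id=oid, code=code)
        genomes.append(PanelGenome(oid, cfg, records, truth))
        if profile:
            prof = profile_genome(records, oid,
                                  min_ribosomal=min(20, cfg.n_ribosomal),
                                  min_genes=min(50, cfg.n_genes), code=code)
            row = {k: getattr(prof, k) for k in (
                "organism_id", "cai_ave", "cai_median", "cai_cv", "nc_rib",
                "nc_all", "nc_diff", "nc_avg_genome", "gc",
                "codon_freq_diff", "n_genes", "n_ribosomal")}
            row["S"] = cfg.selection
            row["theta"] = cfg.theta
            rows.append(row)
    return genomes, (pd.DataFrame(rows) if profile else None)


def panel_configs(n_genomes: int = 40, *, s_max: float = 5.0,
                  theta: float = 0.5, seed: int = 0, n_genes: int = 120,
                  n_ribosomal: int = 25) -> list[SimulationConfig]:
    """Config grid with S equally spaced in [0, s_max] at fixed theta.

    Child seeds derive deterministically from ``seed``; genome sizes
    default to a scaled-down panel suitable for interactive runs.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_genomes)
    s_grid = np.linspace(0.0, s_max, n_genomes)
    return [SimulationConfig(seed=int(cs % 2**31), n_genes=n_genes,
                             n_ribosomal=n_ribosomal, selection=float(s),
                             theta=theta)
            for cs, s in zip(child_seeds, s_grid)]


def random_tree(leaf_ids: list[str],
                rng: np.random.Generator) -> dendropy.Tree:
    """Random binary tree over the given leaves (random joins,
    exponential branch lengths): the null topology for analyses in
    which bias is assigned independently of phylogeny."""
    if len(leaf_ids) < 2:
        raise ValueError("need >= 2 leaves")
    nodes = [f"{lid}:{rng.exponential(1.0):.6f}" for lid in leaf_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential(1.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return dendropy.Tree.get(data=f"({nodes[0]});", schema="newick")
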