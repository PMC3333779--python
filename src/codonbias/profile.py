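"""Organism-scale codon bias profiles.

CAI_ave is the mean CAI over all genes of a genome, with the weight
table built from the pooled ribosomal-protein genes.  Low CAI_ave
marks a biased organism (preferred codons confined to highly expressed
genes); high CAI_ave an unbiased one.  Nc_diff contrasts the mean Nc
of the non-ribosomal genes, Nc(all), with that of the ribosomal genes,
Nc(rib):

    Nc_diff = (Nc(all) - Nc(rib)) / Nc(all)

so strongly biased genomes, whose ribosomal genes use fewer codon
types, have large positive Nc_diff.  The coefficient of variation of
per-gene CAI (sample SD / CAI_ave) and the mean absolute within-family
codon-frequency difference between ribosomal and other genes complete
the profile.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

from .genetic_code import BACTERIAL_CODE, GeneticCode
from .io import DEFAULT_MIN_RIBOSOMAL, GeneRecord
from .metrics import (
    DEFAULT_PSEUDO_WEIGHT,
    MIN_NC_CODONS,
    CodonCounts,
    cai,
    count_codons,
    gc_content,
    nc,
    pool_counts,
    reference_weights,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 50
GC_FILTER_LO = 0.35
GC_FILTER_HI = 0.65


@dataclass
class GenomeProfile:
    """One organism's codon usage bias summary."""

    organism_id: str
    cai_ave: float
    cai_median: float
    cai_cv: float
    nc_rib: float | None
    nc_all: float | None
    nc_diff: float | None
    nc_avg_genome: float | None
    gc: float
    codon_freq_diff: float
    n_genes: int
    n_ribosomal: int


def codon_frequency_difference(rib_counts: CodonCounts,
                               rest_counts: CodonCounts, *,
                               code: GeneticCode = BACTERIAL_CODE) -> float:
    """Mean absolute within-family codon-frequency difference.

    For every sense codon of a degenerate family represented in BOTH
    gene sets, the codon's frequency out of the total codons encoding
    its amino acid is computed in each set; the statistic is the mean
    of the absolute differences over those codons.  Zero means the two
    gene sets use synonymous codons identically.
    """
    diffs: list[float] = []
    for fam in code.degenerate_families().values():
        n_rib = rib_counts.family_total(fam)
        n_rest = rest_counts.family_total(fam)
        if n_rib == 0 or n_rest == 0:
            continue
        for c in fam:
            f_rib = rib_counts.counts.get(c, 0) / n_rib
            f_rest = rest_counts.counts.get(c, 0) / n_rest
            diffs.append(abs(f_rib - f_rest))
    if not diffs:
        raise ValueError("no synonymous family present in both gene sets")
    return sum(diffs) / len(diffs)


def profile_genome(records: list[GeneRecord], organism_id: str = "genome",
                   *, pseudo: float = DEFAULT_PSEUDO_WEIGHT,
                   min_ribosomal: int = DEFAULT_MIN_RIBOSOMAL,
                   min_genes: int = DEFAULT_MIN_GENES,
                   min_nc_codons: int = MIN_NC_CODONS,
                   code: GeneticCode = BACTERIAL_CODE) -> GenomeProfile:
    """Compute the full organism-scale profile for one genome.

    The adaptiveness weights come from the pooled ribosomal genes; CAI
    is then computed for every valid gene (ribosomal included) and
    averaged into CAI_ave.  Nc(rib) averages over ribosomal genes with
    defined Nc, Nc(all) over the non-ribosomal genes — the asymmetry
    (CAI_ave over all genes, Nc(all) over the rest only) is deliberate
    and mirrors how the two organism measures are defined.
    """
    valid = [r for r in records if r.valid]
    rib = [r for r in valid if r.is_ribosomal]
    if not rib:
        raise ValueError("no ribosomal genes flagged; cannot build weights")
    if len(rib) < min_ribosomal:
        raise ValueError(
            f"{len(rib)} ribosomal genes (< {min_ribosomal} required)")
    if len(valid) < min_genes:
        raise ValueError(
            f"{len(valid)} valid genes (< {min_genes} required)")

    gene_counts = {r.gene_id: count_codons(r.sequence, code=code)
                   for r in valid}
    rib_pool = pool_counts([gene_counts[r.gene_id] for r in rib])
    rest = [r for r in valid if not r.is_ribosomal]
    if not rest:
        raise ValueError("every gene is flagged ribosomal; nothing to "
                         "contrast the reference set against")
    rest_pool = pool_counts([gene_counts[r.gene_id] for r in rest])
    weights = reference_weights(
        rib_pool, pseudo=pseudo, code=code,
        provenance=tuple(r.gene_id for r in rib))

    cai_by_gene = {r.gene_id: cai(gene_counts[r.gene_id], weights, code=code)
                   for r in valid}
    cai_vals = [v for v in cai_by_gene.values() if v is not None]
    if not cai_vals:
        raise ValueError("CAI undefined for every gene")
    cai_ave = statistics.fmean(cai_vals)
    cai_median = statistics.median(cai_vals)
    cai_sd = statistics.stdev(cai_vals) if len(cai_vals) > 1 else 0.0
    cai_cv = cai_sd / cai_ave

    nc_by_gene = {r.gene_id: nc(gene_counts[r.gene_id], code=code,
                                min_codons=min_nc_codons)
                  for r in valid}
    nc_rib_vals = [nc_by_gene[r.gene_id] for r in rib
                   if nc_by_gene[r.gene_id] is not None]
    nc_rest_vals = [nc_by_gene[r.gene_id] for r in rest
                    if nc_by_gene[r.gene_id] is not None]
    nc_all_vals = nc_rib_vals + nc_rest_vals

    nc_rib = statistics.fmean(nc_rib_vals) if nc_rib_vals else None
    nc_all = statistics.fmean(nc_rest_vals) if nc_rest_vals else None
    nc_avg = statistics.fmean(nc_all_vals) if nc_all_vals else None
    if nc_rib is None or nc_all is None:
        logger.warning("%s: Nc undefined for a whole gene class; "
                       "nc_diff unavailable", organism_id)
        nc_diff = None
    else:
        nc_diff = (nc_all - nc_rib) / nc_all

    return GenomeProfile(
        organism_id=organism_id,
        cai_ave=cai_ave,
        cai_median=cai_median,
        cai_cv=cai_cv,
        nc_rib=nc_rib,
        nc_all=nc_all,
        nc_diff=nc_diff,
        nc_avg_genome=nc_avg,
        gc=gc_content([r.sequence for r in valid]),
        codon_freq_diff=codon_frequency_difference(rib_pool, rest_pool,
                                                   code=code),
        n_genes=len(valid),
        n_ribosomal=len(rib),
    )


def gc_filter(profiles: list[GenomeProfile], lo: float = GC_FILTER_LO,
              hi: float = GC_FILTER_HI) -> list[GenomeProfile]:
    """Retain genomes with lo < GC < hi (strict bounds).

    Extreme-GC genomes are excluded from comparative analyses because
    their mutational bias compresses the attainable range of codon
    bias measures.
    """
    kept = [p for p in profiles if lo < p.gc < hi]
    logger.info("GC filter (%g, %g): kept %d of %d genomes",
                lo, hi, len(kept), len(profiles))
    if not kept:
        logger.warning("GC filter removed every genome")
    return kept
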