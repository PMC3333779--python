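"""Per-gene codon usage bias measures: CAI, Wright's Nc, GC content.

The Codon Adaptation Index (CAI) of a gene is the geometric mean of the
relative-adaptiveness weights w_c of its codons, where w_c is the
within-family frequency of codon c in a reference set of highly
expressed genes (here: ribosomal-protein genes), normalised so the most
frequent codon of each family has w = 1.  CAI lies in (0, 1]; 1 means
every codon is its family's preferred codon.

Wright's effective number of codons (Nc) summarises how many codon
types a gene effectively uses.  Within each synonymous family the
codon "homozygosity" is estimated as

    F_hat = (n * sum(p_i^2) - 1) / (n - 1)

with n the family's codon count and p_i the within-family proportions;
class means of F_hat over the 2-, 3-, 4- and 6-fold families give

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

which equals 20 when one codon is used per amino acid and 61 under
uniform usage (finite-sample inflation above 61 is capped).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

from .genetic_code import BACTERIAL_CODE, GeneticCode

logger = logging.getLogger(__name__)

#: default weight assigned to codons absent from the reference set
DEFAULT_PSEUDO_WEIGHT = 0.01

#: genes with fewer informative (degenerate-family) codons get no Nc
MIN_NC_CODONS = 30

NC_MIN = 20.0
NC_MAX = 61.0

#: number of families per degeneracy class in the bacterial code,
#: i.e. the numerators of Wright's formula
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCounts:
    """Codon counts for one gene or a pooled gene set.

    ``counts`` maps codons (sense and stop) to nonnegative integers;
    ``n_skipped`` tallies triplets dropped for containing ambiguity
    codes.
    """

    counts: Counter = field(default_factory=Counter)
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def family_total(self, family: tuple[str, ...]) -> int:
        return sum(self.counts.get(c, 0) for c in family)


@dataclass
class WeightTable:
    """Relative-adaptiveness weight w_c per sense codon.

    Invariant: within every synonymous family the maximum weight is
    exactly 1, and all weights are positive.
    """

    weights: dict[str, float]
    pseudo: float = DEFAULT_PSEUDO_WEIGHT
    provenance: tuple[str, ...] = ()

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


@dataclass
class GeneBiasScores:
    """Per-gene bias scores as written to the per-gene TSV."""

    gene_id: str
    cai: float | None
    nc: float | None
    gc: float
    codons_used: int


def count_codons(sequence: str, *, code: GeneticCode = BACTERIAL_CODE) -> CodonCounts:
    """Count non-overlapping triplets of a validated CDS.

    Triplets containing characters outside A/C/G/T (ambiguity codes)
    are skipped and tallied in ``n_skipped``.  Raises ``ValueError`` if
    the length is not a multiple of 3.
    """
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError(
            f"sequence length {len(seq)} is not a multiple of 3")
    counts: Counter = Counter()
    skipped = 0
    valid = set("ACGT")
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if set(codon) <= valid:
            counts[codon] += 1
        else:
            skipped += 1
    if skipped:
        logger.debug("skipped %d ambiguous codons", skipped)
    return CodonCounts(counts=counts, n_skipped=skipped)


def pool_counts(counts_list: list[CodonCounts]) -> CodonCounts:
    """Elementwise sum of codon counts (reference-set pooling)."""
    if not counts_list:
        raise ValueError("cannot pool an empty list of codon counts")
    total: Counter = Counter()
    skipped = 0
    for cc in counts_list:
        total.update(cc.counts)
        skipped += cc.n_skipped
    return CodonCounts(counts=total, n_skipped=skipped)


def reference_weights(ref_counts: CodonCounts, *,
                      pseudo: float = DEFAULT_PSEUDO_WEIGHT,
                      code: GeneticCode = BACTERIAL_CODE,
                      provenance: tuple[str, ...] = ()) -> WeightTable:
    """Relative adaptiveness w_c = count_c / max family count.

    Codons unobserved in the reference set receive the small positive
    ``pseudo`` weight so CAI never degenerates to zero; single-codon
    families (Met, Trp) get w = 1.  A family entirely absent from the
    reference set gets ``pseudo`` for all its codons, with a warning.
    """
    if pseudo <= 0:
        raise ValueError("pseudo-weight must be positive")
    weights: dict[str, float] = {}
    for aa, fam in code.families.items():
        if len(fam) == 1:
            weights[fam[0]] = 1.0
            continue
        fam_counts = {c: ref_counts.counts.get(c, 0) for c in fam}
        fmax = max(fam_counts.values())
        if fmax == 0:
            logger.warning(
                "family %s absent from reference set; all weights set "
                "to pseudo=%g", aa, pseudo)
            for c in fam:
                weights[c] = pseudo
            continue
        for c, cnt in fam_counts.items():
            weights[c] = cnt / fmax if cnt > 0 else pseudo
    return WeightTable(weights=weights, pseudo=pseudo, provenance=provenance)


def _cai_excluded(code: GeneticCode) -> frozenset[str]:
    # stops never carry a weight; 1-fold families carry no bias signal
    singles = frozenset(
        fam[0] for fam in code.families.values() if len(fam) == 1)
    return singles | code.stop_codons


def cai(gene_counts: CodonCounts, weights: WeightTable, *,
        code: GeneticCode = BACTERIAL_CODE) -> float | None:
    """Codon Adaptation Index: geometric mean of w_c over the gene.

    Met, Trp and stop codons are excluded.  Computed in log space for
    underflow safety.  Returns ``None`` for a gene with no eligible
    codons.
    """
    excluded = _cai_excluded(code)
    log_sum = 0.0
    n_used = 0
    for codon, cnt in gene_counts.counts.items():
        if codon in excluded or codon not in code.codon_to_aa:
            continue
        log_sum += cnt * math.log(weights[codon])
        n_used += cnt
    if n_used == 0:
        return None
    return math.exp(log_sum / n_used)


def family_homozygosity(family_counts: list[int]) -> float | None:
    """Wright's bias-corrected codon homozygosity for one family.

    F_hat = (n * sum(p_i^2) - 1) / (n - 1).  Undefined (None) for
    families with fewer than 2 codons counted.
    """
    n = sum(family_counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in family_counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def nc(gene_counts: CodonCounts, *, code: GeneticCode = BACTERIAL_CODE,
       min_codons: int = MIN_NC_CODONS, cap: bool = True) -> float | None:
    """Wright's effective number of codons for one gene.

    Class means of family homozygosity are taken over families with
    defined, positive F_hat.  A missing 3-fold class (no Ile) is
    imputed as the mean of the 2- and 4-fold class means; a missing
    6-fold class is imputed from the 4-fold class.  If the 2- or
    4-fold class is missing, or the gene has fewer than ``min_codons``
    informative codons, Nc is undefined (None).  With ``cap`` the
    result is clipped into [20, 61].
    """
    informative = sum(
        gene_counts.counts.get(c, 0)
        for fam in code.degenerate_families().values() for c in fam)
    if informative < min_codons:
        return None

    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.degenerate_families().items():
        fhat = family_homozygosity(
            [gene_counts.counts.get(c, 0) for c in fam])
        if fhat is not None and fhat > 0:
            f_by_class[code.degeneracy[aa]].append(fhat)

    fbar: dict[int, float | None] = {
        k: (sum(v) / len(v) if v else None) for k, v in f_by_class.items()}
    if fbar[2] is None or fbar[4] is None:
        return None
    if fbar[3] is None:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
        logger.debug("imputed 3-fold class mean from 2- and 4-fold")
    if fbar[6] is None:
        fbar[6] = fbar[4]
        logger.debug("imputed 6-fold class mean from 4-fold")

    nc_raw = 2.0 + sum(_CLASS_SIZES[k] / fbar[k] for k in (2, 3, 4, 6))
    if not cap:
        return nc_raw
    return min(max(nc_raw, NC_MIN), NC_MAX)


def gc_content(sequences) -> float:
    """Fraction of G/C among unambiguous nucleotides.

    Accepts one sequence or an iterable of sequences; characters
    outside A/C/G/T are ignored in both numerator and denominator.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = 0
    total = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        total += sum(s.count(b) for b in "ACGT")
    if total == 0:
        raise ValueError("no unambiguous nucleotides in input")
    return gc / total


def score_gene(gene_id: str, sequence: str, weights: WeightTable, *,
               code: GeneticCode = BACTERIAL_CODE,
               min_nc_codons: int = MIN_NC_CODONS) -> GeneBiasScores:
    """Compute all per-gene scores for one validated CDS."""
    counts = count_codons(sequence, code=code)
    return GeneBiasScores(
        gene_id=gene_id,
        cai=cai(counts, weights, code=code),
        nc=nc(counts, code=code, min_codons=min_nc_codons),
        gc=gc_content(sequence),
        codons_used=counts.n,
    )
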