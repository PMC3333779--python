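"""The bacterial genetic code and its synonymous-codon family structure.

Every codon bias measure in this package operates on the degeneracy
families of the standard bacterial/archaeal code (NCBI translation
table 11): 61 sense codons partitioned into 20 amino-acid families of
size 1 (Met, Trp), 2 (nine amino acids), 3 (Ile), 4 (five amino acids)
and 6 (Leu, Ser, Arg), plus 3 stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")


@dataclass(frozen=True)
class GeneticCode:
    """Codon-to-amino-acid map with synonymous family bookkeeping.

    Attributes
    ----------
    table_id : NCBI translation table number.
    codon_to_aa : map from each sense codon to its one-letter amino acid.
    stop_codons : the stop triplets (never part of any family).
    families : amino acid -> tuple of its synonymous codons, sorted.
    degeneracy : amino acid -> family size k in {1, 2, 3, 4, 6}.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)
    degeneracy: dict[str, int] = field(default_factory=dict)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonymous codons of ``codon``'s amino acid (incl. itself)."""
        return self.families[self.codon_to_aa[codon]]

    def degenerate_families(self) -> dict[str, tuple[str, ...]]:
        """Families with two or more synonymous codons."""
        return {aa: cods for aa, cods in self.families.items()
                if self.degeneracy[aa] >= 2}

    def families_by_class(self, k: int) -> list[tuple[str, ...]]:
        """All families of degeneracy exactly ``k``."""
        return [cods for aa, cods in self.families.items()
                if self.degeneracy[aa] == k]


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 11) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table."""
    bio_table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(bio_table.forward_table)
    stops = frozenset(bio_table.stop_codons)
    families: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa.items():
        families.setdefault(aa, []).append(codon)
    fam = {aa: tuple(sorted(cods)) for aa, cods in families.items()}
    deg = {aa: len(cods) for aa, cods in fam.items()}
    return GeneticCode(table_id=table_id, codon_to_aa=codon_to_aa,
                       stop_codons=stops, families=fam, degeneracy=deg)


#: The standard bacterial code, used throughout unless overridden.
BACTERIAL_CODE = genetic_code(11)
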