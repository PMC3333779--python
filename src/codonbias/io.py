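"""Genome, phenotype and tree ingestion; profile table output.

Genomes enter as CDS FASTA (one record per protein-coding gene) or
GenBank flat files with CDS features.  Phenotype annotations follow the
trait vocabulary used for prokaryote classification (pathogenicity,
oxygen requirement, salinity, temperature range, habitat, optional
growth rate).  Trees are newick with branch lengths.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: maximum tolerated fraction of ambiguous codons in a valid gene
MAX_AMBIGUOUS_FRACTION = 0.10

#: default product-annotation rules for the ribosomal reference set
RIBOSOMAL_INCLUDE_PATTERNS = ("ribosomal protein",)
RIBOSOMAL_EXCLUDE_PATTERNS = (
    "methyltransferase", "pseudouridine", "acetyltransferase", "kinase",
)
DEFAULT_MIN_RIBOSOMAL = 20

#: Table-style trait vocabulary; tokens are matched case-insensitively
TRAIT_CATEGORIES = {
    "pathogenicity": {"pathogenic", "non-pathogenic"},
    "oxygen": {"aerobic", "anaerobic", "facultative", "microaerophilic"},
    "salinity": {"extreme-halophilic", "mesophilic", "moderate-halophilic",
                 "non-halophilic"},
    "temperature": {"hyperthermophilic", "mesophilic", "psychrophilic",
                    "thermophilic"},
    "habitat": {"multiple", "specialized"},
}


@dataclass
class GeneRecord:
    """One CDS: identity, sequence, ribosomal flag, optional product."""

    gene_id: str
    sequence: str
    is_ribosomal: bool = False
    product: str | None = None
    valid: bool = True
    invalid_reason: str | None = None


def _validate_record(rec: GeneRecord) -> GeneRecord:
    seq = rec.sequence
    if len(seq) == 0:
        rec.valid, rec.invalid_reason = False, "empty sequence"
        return rec
    if len(seq) % 3 != 0:
        rec.valid, rec.invalid_reason = False, "length not multiple of 3"
        return rec
    valid_chars = set("ACGT")
    ambiguous = sum(
        1 for i in range(0, len(seq), 3)
        if not set(seq[i:i + 3]) <= valid_chars)
    if ambiguous / (len(seq) // 3) > MAX_AMBIGUOUS_FRACTION:
        rec.valid = False
        rec.invalid_reason = f"{ambiguous} ambiguous codons (> 10%)"
    return rec


def read_cds_fasta(path) -> list[GeneRecord]:
    """Read a gene-per-record CDS FASTA into GeneRecords.

    Sequences are upper-cased and validated (length multiple of 3,
    limited ambiguity); failing records are kept but flagged invalid so
    downstream metrics can exclude and report them.
    """
    path = Path(path)
    records = [
        _validate_record(GeneRecord(
            gene_id=sr.id, sequence=str(sr.seq).upper(),
            product=sr.description.partition(" ")[2] or None))
        for sr in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    n_invalid = sum(not r.valid for r in records)
    if n_invalid == len(records):
        raise ValueError(
            f"all {len(records)} records in {path} failed validation")
    if n_invalid:
        logger.warning("%s: %d of %d records invalid, excluded from "
                       "metrics", path, n_invalid, len(records))
    return records


def write_cds_fasta(records: list[GeneRecord], path) -> None:
    """Write GeneRecords as a gene-per-record FASTA (round-trip safe)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id,
                  description=r.product or "")
        for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_genbank_cds(path) -> list[GeneRecord]:
    """Extract CDS features from a GenBank flat file.

    Coordinates are interpreted per GenBank convention; join and
    complement locations are honoured (complement-strand CDS are
    reverse-complemented).  The product qualifier is captured for
    ribosomal-gene flagging.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    for sr in SeqIO.parse(str(path), "genbank"):
        for idx, feat in enumerate(sr.features):
            if feat.type != "CDS":
                continue
            seq = str(feat.extract(sr.seq)).upper()
            quals = feat.qualifiers
            gene_id = (quals.get("locus_tag") or quals.get("protein_id")
                       or quals.get("gene") or [f"{sr.id}_cds{idx}"])[0]
            product = quals.get("product", [None])[0]
            records.append(_validate_record(
                GeneRecord(gene_id=gene_id, sequence=seq, product=product)))
    if not records:
        warnings.warn(f"no CDS features found in {path}")
    return records


def flag_ribosomal_genes(
        records: list[GeneRecord], *,
        include_patterns=RIBOSOMAL_INCLUDE_PATTERNS,
        exclude_patterns=RIBOSOMAL_EXCLUDE_PATTERNS,
        id_list=None,
        min_count: int = DEFAULT_MIN_RIBOSOMAL) -> list[GeneRecord]:
    """Flag the ribosomal-protein reference set.

    By default a record is flagged when its product annotation contains
    an inclusion pattern (case-insensitive) and no exclusion pattern;
    an explicit ``id_list`` of gene ids overrides pattern matching.
    Raises if fewer than ``min_count`` genes are flagged, since a small
    reference set makes the adaptiveness weights unreliable.
    """
    if id_list is not None:
        ids = set(id_list)
        for rec in records:
            rec.is_ribosomal = rec.gene_id in ids
    else:
        inc = [re.compile(p, re.IGNORECASE) for p in include_patterns]
        exc = [re.compile(p, re.IGNORECASE) for p in exclude_patterns]
        for rec in records:
            text = rec.product or ""
            rec.is_ribosomal = (
                any(p.search(text) for p in inc)
                and not any(p.search(text) for p in exc))
    n_flagged = sum(r.is_ribosomal for r in records)
    if n_flagged < min_count:
        raise ValueError(
            f"only {n_flagged} ribosomal genes flagged (< {min_count}); "
            "supply an explicit reference id list")
    return records


def read_phenotype_table(path) -> pd.DataFrame:
    """Read a phenotype TSV and validate its trait vocabulary.

    Returns a DataFrame with columns organism_id, pathogenicity,
    oxygen, salinity, temperature, habitat, growth_rate and the derived
    habitat_code (0 = multiple habitats, 1 = specialized).  Tokens
    outside the vocabulary become missing, with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "organism_id" not in df.columns:
        raise ValueError("phenotype table lacks an organism_id column")
    out = pd.DataFrame({"organism_id": df["organism_id"]})
    for trait, allowed in TRAIT_CATEGORIES.items():
        if trait not in df.columns:
            out[trait] = pd.NA
            continue
        vals = df[trait].str.strip().str.lower()
        bad = vals.notna() & ~vals.isin(allowed)
        if bad.any():
            warnings.warn(
                f"{trait}: {sorted(vals[bad].unique())} not in vocabulary; "
                "set to missing")
        out[trait] = vals.where(~bad)
    if "growth_rate" in df.columns:
        out["growth_rate"] = pd.to_numeric(df["growth_rate"],
                                           errors="coerce")
    else:
        out["growth_rate"] = pd.NA
    out["habitat_code"] = out["habitat"].map(
        {"multiple": 0, "specialized": 1}).astype("Int64")
    return out


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a newick tree; absent branch lengths become unit lengths.

    Accepts a file path or a newick string.  Unit-length substitution
    keeps distance analyses runnable on bare topologies; a warning is
    emitted when it happens.
    """
    text = str(path_or_string)
    if not text.lstrip().startswith("("):
        text = Path(path_or_string).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            edge.length = 1.0
            n_missing += 1
        elif edge.length < 0:
            raise ValueError("negative branch length in tree")
    if n_missing:
        warnings.warn(
            f"{n_missing} branches lacked lengths; unit lengths assumed")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


PROFILE_COLUMNS = [
    "organism_id", "cai_ave", "cai_median", "cai_cv", "nc_rib", "nc_all",
    "nc_diff", "nc_avg_genome", "gc", "codon_freq_diff", "n_genes",
    "n_ribosomal",
]


def write_profiles(profiles, path) -> None:
    """Write organism profiles as a TSV (one row per genome)."""
    profiles_frame(profiles).to_csv(path, sep="\t", index=False)


def profiles_frame(profiles) -> pd.DataFrame:
    """Coerce a list of GenomeProfile (or a DataFrame) to a DataFrame."""
    if isinstance(profiles, pd.DataFrame):
        return profiles
    rows = [{col: getattr(p, col) for col in PROFILE_COLUMNS}
            for p in profiles]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def read_profiles(path) -> pd.DataFrame:
    """Read a profile TSV written by :func:`write_profiles`."""
    return pd.read_csv(path, sep="\t")


def write_gene_scores(scores, path) -> None:
    """Write per-gene scores (gene_id, cai, nc, gc, codons_used)."""
    pd.DataFrame(
        [{"gene_id": s.gene_id, "cai": s.cai, "nc": s.nc, "gc": s.gc,
          "codons_used": s.codons_used} for s in scores]
    ).to_csv(path, sep="\t", index=False)
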