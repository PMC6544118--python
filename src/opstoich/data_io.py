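"""Readers, writers and validation for every table the pipeline touches.

All tabular inputs are tab-delimited UTF-8 text with a header row; gzipped
files are handled transparently (pandas infers compression from the ``.gz``
suffix). Gene annotation arrives as GFF3, protein sequences as FASTA.

Coordinates are 1-based inclusive on disk (GFF convention) and exposed both
ways: :class:`GeneAnnotation` keeps the on-disk values and offers the
0-based half-open interval through :meth:`GeneAnnotation.interval0`. All
interval arithmetic elsewhere in the package uses the half-open convention.

Identifier joining across tables is by ``gene_name``, case-sensitive; an
optional user-supplied alias map can be applied before joining.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    CrossReferenceError,
    SchemaError,
    UsageError,
    ValidationError,
)

logger = logging.getLogger(__name__)

VALUE_KINDS = {"intensity", "copies", "rpkM", "half_life_h", "read_count"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene on a contig, 1-based inclusive coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds_length_nt: int
    protein_length_aa: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def interval0(self) -> tuple[int, int]:
        """0-based half-open genomic interval."""
        return self.start - 1, self.end


@dataclass(frozen=True)
class Operon:
    """Ordered gene membership of one transcription unit.

    ``gene_ids`` are in transcript order (5' to 3' of the polycistronic
    mRNA): ascending genomic start for + strand, descending for - strand.
    """

    operon_id: str
    gene_ids: tuple[str, ...]
    strand: str

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValidationError(f"operon {self.operon_id}: no genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"operon {self.operon_id}: duplicate gene ids")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"operon {self.operon_id}: bad strand")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def is_polycistronic(self) -> bool:
        return self.n_genes >= 2


@dataclass(frozen=True)
class KineticsRecord:
    """Michaelis-Menten parameters for one enzyme.

    Values measured in a homologous protein from another organism carry that
    organism name and the percent amino-acid identity to the reference
    protein; values from the reference organism itself carry its name.
    """

    enzyme_gene: str
    k_cat: float | None = None
    K_M: float | None = None
    k_cat_organism: str = "E. coli"
    K_M_organism: str = "E. coli"
    homology_pct: float | None = None

    def __post_init__(self) -> None:
        if self.k_cat is None and self.K_M is None:
            raise ValidationError(
                f"enzyme {self.enzyme_gene}: neither k_cat nor K_M present"
            )
        for name, v in (("k_cat", self.k_cat), ("K_M", self.K_M)):
            if v is not None and v <= 0:
                raise ValidationError(f"enzyme {self.enzyme_gene}: {name} <= 0")

    def has_native_value(self, organism: str = "E. coli") -> bool:
        """True if at least one parameter was measured in *organism*."""
        return (self.k_cat is not None and self.k_cat_organism == organism) or (
            self.K_M is not None and self.K_M_organism == organism
        )


@dataclass
class ValueTable:
    """A keyed table of one non-negative quantity per gene/protein."""

    values: "pd.Series"
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise UsageError(f"unknown value_kind {self.value_kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate keys: {dups[:5]}")
        if (self.values < 0).any():
            raise ValidationError("negative values in ValueTable")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])

    def keys(self) -> set[str]:
        return set(self.values.index)


# ---------------------------------------------------------------------------
# table schemas
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, dict] = {
    "protein_quant": {
        "required": ["protein_id", "gene_name", "intensity"],
        "optional": ["n_unique_peptides", "min_peptide_length", "strain", "replicate"],
        "aliases": {
            "unique_peptides": "n_unique_peptides",
            "peptide_min_length": "min_peptide_length",
        },
        "nonneg": ["intensity", "n_unique_peptides"],
        "key": "gene_name",
    },
    "reference_abundance": {
        "required": ["gene_name", "copies_iBAQ", "copies_emPAI", "copies_APEX"],
        "optional": [],
        "aliases": {"ibaq": "copies_iBAQ", "empai": "copies_emPAI", "apex": "copies_APEX"},
        "nonneg": ["copies_iBAQ", "copies_emPAI", "copies_APEX"],
        "key": "gene_name",
    },
    "value_table": {
        "required": ["key", "value"],
        "optional": ["value_kind"],
        "aliases": {"gene_name": "key", "gene_id": "key"},
        "nonneg": ["value"],
        "key": "key",
    },
    "kinetics": {
        "required": ["enzyme_gene"],
        "optional": ["k_cat", "K_M", "k_cat_organism", "K_M_organism", "homology_pct"],
        "aliases": {"kcat": "k_cat", "km": "K_M"},
        "nonneg": [],
        "key": "enzyme_gene",
    },
}


def read_quant_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against one of the named table schemas.

    Row order is preserved. Duplicate keys are an error — aggregating
    duplicated gene rows silently would be an invisible analysis decision.

    Raises
    ------
    SchemaError
        unknown schema name, or a required column is missing.
    ValidationError
        negative value (with its row number) or duplicated key.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}"
        )
    spec = _SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.rename(columns=spec["aliases"])
    for col in spec["required"]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in spec["nonneg"]:
        if col in df.columns:
            bad = df.index[df[col] < 0]
            if len(bad):
                raise ValidationError(
                    f"{path}: negative {col} at row {int(bad[0]) + 2}"  # 1-based + header
                )
    key = spec["key"]
    if df[key].isna().any() or (df[key].astype(str).str.len() == 0).any():
        raise ValidationError(f"{path}: empty identifier in column {key!r}")
    if df[key].duplicated().any():
        dup = df[key][df[key].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate key {dup!r} in column {key!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV; the exact inverse of :func:`read_quant_table`."""
    df.to_csv(path, sep="\t", index=False)


def read_value_table(path: str | Path, value_kind: str | None = None) -> ValueTable:
    """Read a two/three-column key-value TSV into a :class:`ValueTable`."""
    df = read_quant_table(path, "value_table")
    if value_kind is None:
        if "value_kind" not in df.columns:
            raise SchemaError(f"{path}: no value_kind column and none supplied")
        kinds = df["value_kind"].unique()
        if len(kinds) != 1:
            raise ValidationError(f"{path}: mixed value kinds {list(kinds)}")
        value_kind = str(kinds[0])
    s = pd.Series(df["value"].astype(float).values, index=df["key"].astype(str).values)
    return ValueTable(s, value_kind)


def write_value_table(table: ValueTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"key": table.values.index, "value": table.values.values,
         "value_kind": table.value_kind}
    )
    write_table(df, path)


def read_kinetics_table(path: str | Path) -> list[KineticsRecord]:
    """Read an enzyme-kinetics TSV into :class:`KineticsRecord` objects."""
    df = read_quant_table(path, "kinetics")

    def _get(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return row[col]

    records = []
    for _, row in df.iterrows():
        records.append(
            KineticsRecord(
                enzyme_gene=str(row["enzyme_gene"]),
                k_cat=_get(row, "k_cat"),
                K_M=_get(row, "K_M"),
                k_cat_organism=str(_get(row, "k_cat_organism") or "E. coli"),
                K_M_organism=str(_get(row, "K_M_organism") or "E. coli"),
                homology_pct=_get(row, "homology_pct"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# annotation + operons
# ---------------------------------------------------------------------------

def _opener(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gff3(path: str | Path) -> dict[str, GeneAnnotation]:
    """Parse protein-coding genes from a GFF3 file.

    CDS features are preferred; ``gene`` features are used for genes without
    a CDS line. The gene identifier is taken from the ``ID`` attribute
    (falling back to ``locus_tag`` then ``gene``).
    """
    genes: dict[str, GeneAnnotation] = {}
    seen_cds: set[str] = set()
    with _opener(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise SchemaError(f"{path}: malformed GFF3 line: {line[:80]!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in {"CDS", "gene"}:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("locus_tag") or attr.get("gene")
            if gid is None:
                raise SchemaError(f"{path}: feature without ID/locus_tag/gene")
            gid = gid.removeprefix("cds-").removeprefix("gene-")
            start_i, end_i = int(start), int(end)
            if ftype == "gene" and gid in seen_cds:
                continue  # CDS line already defines this gene
            cds_len = end_i - start_i + 1
            genes[gid] = GeneAnnotation(
                gene_id=gid,
                contig=contig,
                start=start_i,
                end=end_i,
                strand=strand,
                cds_length_nt=cds_len,
                protein_length_aa=max(cds_len // 3 - 1, 1),
            )
            if ftype == "CDS":
                seen_cds.add(gid)
    return genes


def _order_operon_genes(
    gene_ids: Sequence[str], annotation: Mapping[str, GeneAnnotation]
) -> tuple[tuple[str, ...], str]:
    """Re-order genes into transcript (5'->3') order; return (order, strand)."""
    anns = [annotation[g] for g in gene_ids]
    strands = {a.strand for a in anns}
    contigs = {a.contig for a in anns}
    if len(strands) != 1:
        raise ValidationError(f"mixed strands within operon: {list(gene_ids)}")
    if len(contigs) != 1:
        raise ValidationError(f"mixed contigs within operon: {list(gene_ids)}")
    strand = strands.pop()
    ordered = sorted(anns, key=lambda a: a.start, reverse=(strand == "-"))
    return tuple(a.gene_id for a in ordered), strand


def read_operon_table(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read an operon membership table in either supported dialect.

    Dialect 1: columns ``operon_id``, ``gene_ids`` (comma- or
    semicolon-separated). Dialect 2: one row per gene with columns
    ``operon_id``, ``gene_id``, ``rank``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_ids" in df.columns:
        out = []
        for _, row in df.iterrows():
            genes = [g for g in str(row["gene_ids"]).replace(";", ",").split(",") if g]
            out.append((str(row["operon_id"]), genes))
        return out
    if {"operon_id", "gene_id", "rank"} <= set(df.columns):
        df["rank"] = df["rank"].astype(int)
        out = []
        for oid, grp in df.groupby("operon_id", sort=False):
            grp = grp.sort_values("rank")
            out.append((str(oid), [str(g) for g in grp["gene_id"]]))
        return out
    raise SchemaError(
        f"{path}: expected columns (operon_id, gene_ids) or (operon_id, gene_id, rank)"
    )


def read_operon_annotation(
    operon_path: str | Path, gff_path: str | Path
) -> tuple[list[Operon], dict[str, GeneAnnotation]]:
    """Read operon membership + GFF3 annotation and cross-validate them.

    Operon gene lists are re-ordered into transcript order using the
    annotated coordinates and strand. The re-ordering is idempotent.

    Raises
    ------
    CrossReferenceError
        an operon references a gene absent from the annotation.
    ValidationError
        genes of one operon lie on different strands or contigs.
    """
    annotation = read_gff3(gff_path)
    operons = []
    for oid, genes in read_operon_table(operon_path):
        missing = [g for g in genes if g not in annotation]
        if missing:
            raise CrossReferenceError(
                f"operon {oid}: unknown gene(s) {missing}"
            )
        ordered, strand = _order_operon_genes(genes, annotation)
        operons.append(Operon(operon_id=oid, gene_ids=ordered, strand=strand))
    return operons, annotation


def write_operon_table(operons: Iterable[Operon], path: str | Path) -> None:
    ops = list(operons)
    df = pd.DataFrame(
        {
            "operon_id": [o.operon_id for o in ops],
            "gene_ids": [",".join(o.gene_ids) for o in ops],
        }
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# confidence filtering + coverage
# ---------------------------------------------------------------------------

#: identification-confidence thresholds: (min unique peptides, min peptide length)
CONFIDENCE_MODES = {"relaxed": (1, 6), "stringent": (2, 7)}


def filter_confident(quant: pd.DataFrame, mode: str = "stringent") -> pd.DataFrame:
    """Keep proteins meeting the identification-confidence thresholds.

    ``relaxed`` requires at least one unique peptide of length >= 6 aa;
    ``stringent`` requires at least two unique peptides and length >= 7 aa.
    """
    if mode not in CONFIDENCE_MODES:
        raise UsageError(f"unknown mode {mode!r}; expected relaxed or stringent")
    min_pep, min_len = CONFIDENCE_MODES[mode]
    for col in ("n_unique_peptides", "min_peptide_length"):
        if col not in quant.columns:
            raise SchemaError(f"filter_confident: column {col!r} not present")
    keep = (quant["n_unique_peptides"] >= min_pep) & (
        quant["min_peptide_length"] >= min_len
    )
    removed = int((~keep).sum())
    logger.info("filter_confident(%s): kept %d, removed %d", mode, int(keep.sum()), removed)
    return quant[keep].copy()


def sequence_coverage(peptides: Sequence[str], protein_seq: str) -> float:
    """Fraction of residues covered by at least one peptide occurrence.

    Every match position of every peptide is marked; overlapping matches
    count each residue once. A peptide longer than the protein (or absent
    from it) contributes nothing.
    """
    if not protein_seq:
        raise ValidationError("empty protein sequence")
    covered = [False] * len(protein_seq)
    for pep in peptides:
        if not pep:
            raise ValidationError("empty peptide string")
        if len(pep) > len(protein_seq):
            logger.warning("peptide longer than protein; contributes 0")
            continue
        start = protein_seq.find(pep)
        while start != -1:
            for i in range(start, start + len(pep)):
                covered[i] = True
            start = protein_seq.find(pep, start + 1)
    return sum(covered) / len(protein_seq)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence map."""
    with _opener(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
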