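"""RNA read counts to rpkM and the quantifiability filter.

rpkM normalizes a gene's read count by CDS length (per kilobase) and
library size (per million reads mapped to coding sequence). Genes with at
least 10 mapped reads are considered quantifiable; rpkM is still reported
for the rest, flagged unquantifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_io import ValueTable
from .errors import ValidationError

MIN_QUANTIFIABLE_READS = 10


@dataclass(frozen=True)
class RnaQuantRecord:
    gene_id: str
    read_count: int
    cds_length_nt: int
    rpkM: float
    quantifiable: bool


def rpkm(read_count: int, cds_length_nt: int, total_mapped: int) -> float:
    """reads per kilobase of CDS per million mapped reads."""
    if cds_length_nt <= 0:
        raise ValidationError("cds_length_nt must be positive")
    if total_mapped <= 0:
        raise ValidationError("total_mapped must be positive")
    if read_count < 0:
        raise ValidationError("read_count must be non-negative")
    return read_count / ((cds_length_nt / 1e3) * (total_mapped / 1e6))


def quantify_rna(
    counts: dict[str, int],
    cds_lengths: dict[str, int],
    total_mapped: int | None = None,
    min_reads: int = MIN_QUANTIFIABLE_READS,
) -> list[RnaQuantRecord]:
    """rpkM records for a whole counts table.

    ``total_mapped`` defaults to the sum of the supplied counts (reads
    mapped to coding sequence).
    """
    if total_mapped is None:
        total_mapped = sum(counts.values())
    records = []
    for gene, count in counts.items():
        if gene not in cds_lengths:
            raise ValidationError(f"no CDS length for gene {gene}")
        records.append(
            RnaQuantRecord(
                gene_id=gene,
                read_count=int(count),
                cds_length_nt=int(cds_lengths[gene]),
                rpkM=rpkm(count, cds_lengths[gene], total_mapped),
                quantifiable=count >= min_reads,
            )
        )
    return records


def rna_value_table(records: list[RnaQuantRecord], quantifiable_only: bool = True) -> ValueTable:
    recs = [r for r in records if r.quantifiable] if quantifiable_only else records
    s = pd.Series({r.gene_id: r.rpkM for r in recs})
    return ValueTable(s, "rpkM")
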