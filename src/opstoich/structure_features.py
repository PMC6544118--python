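"""Gene intervals, ribosome-scanning classification and CV regressions.

The *gene interval* of two adjacent cistrons is the number of nucleotides
strictly between the upstream CDS end (just past its stop codon) and the
downstream CDS start: 0 means back-to-back ORFs and negative values mean
overlapping ORFs. Coordinates are handled internally as 0-based half-open
intervals, so on the + strand the interval is simply
``start(next) - end(prev)``; the - strand is the mirror computation. The
convention is stated here prominently because +-3 nt offsets (stop codon
in or out) differ between annotation tools.

A terminating 70S ribosome covers roughly 40 nt of mRNA. When the next
start codon lies nearer than that footprint, termination and downstream
initiation cannot be independent events, and translation of the downstream
cistron is attributed to coupled 70S scanning; otherwise to independent
30S initiation. Overlapping ORFs (negative intervals) are maximal
proximity and are always coupled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import GeneAnnotation, Operon, ValueTable
from .errors import CrossReferenceError, StatisticError
from .operon_cv import OperonCVRecord

RIBOSOME_FOOTPRINT_NT = 40


@dataclass(frozen=True)
class GeneInterval:
    operon_id: str
    upstream_gene: str
    downstream_gene: str
    interval_nt: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int


def gene_intervals(
    operon: Operon, annotation: Mapping[str, GeneAnnotation]
) -> list[GeneInterval]:
    """Intervals between consecutive cistrons, in transcript order."""
    missing = [g for g in operon.gene_ids if g not in annotation]
    if missing:
        raise CrossReferenceError(
            f"operon {operon.operon_id}: no coordinates for {missing}"
        )
    out = []
    for up, down in zip(operon.gene_ids, operon.gene_ids[1:]):
        u0, u1 = annotation[up].interval0()
        d0, d1 = annotation[down].interval0()
        if operon.strand == "+":
            interval = d0 - u1
        else:
            interval = u0 - d1
        out.append(
            GeneInterval(
                operon_id=operon.operon_id,
                upstream_gene=up,
                downstream_gene=down,
                interval_nt=int(interval),
            )
        )
    return out


def all_gene_intervals(
    operons: Iterable[Operon], annotation: Mapping[str, GeneAnnotation]
) -> list[GeneInterval]:
    return [iv for op in operons if op.is_polycistronic for iv in gene_intervals(op, annotation)]


def scanning_class(interval_nt: int, footprint_nt: int = RIBOSOME_FOOTPRINT_NT) -> str:
    """Coupled 70S-scanning vs independent initiation at one junction.

    Coupled iff the interval is strictly shorter than the footprint
    (an interval of exactly ``footprint_nt`` is independent).
    """
    return "coupled_70S_scanning" if interval_nt < footprint_nt else "independent_initiation"


def cv_vs_size_regression(
    records: Sequence[OperonCVRecord], class_filter: Mapping[str, str] | None = None,
    class_label: str | None = None,
) -> RegressionResult:
    """OLS of operon CV% on the number of quantified proteins.

    ``class_filter`` maps operon_id -> Complex/Pathway label; when given
    together with ``class_label``, only operons of that class enter the
    regression. The slope p-value is the two-sided test of slope = 0.
    """
    recs = list(records)
    if class_filter is not None and class_label is not None:
        recs = [r for r in recs if class_filter.get(r.operon_id) == class_label]
    if len(recs) < 3:
        raise StatisticError(f"regression needs >= 3 records, got {len(recs)}")
    x = np.array([r.n_quantified for r in recs], dtype=float)
    y = np.array([r.cv_percent for r in recs], dtype=float)
    if np.ptp(x) == 0:
        raise StatisticError("degenerate predictor: all operons have the same size")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n=len(recs),
    )


def rna_protein_correlation(
    rna: ValueTable, protein: ValueTable, genes: Iterable[str] | None = None
) -> RegressionResult:
    """Pearson correlation of log10 RNA vs log10 protein abundance.

    Restricted to ``genes`` when given; genes with a non-positive value on
    either axis are excluded (log undefined). ``r_squared`` is the headline
    statistic.
    """
    keys = rna.keys() & protein.keys()
    if genes is not None:
        keys &= set(genes)
    shared = sorted(k for k in keys if rna[k] > 0 and protein[k] > 0)
    if len(shared) < 3:
        raise StatisticError(f"need >= 3 shared positive genes, got {len(shared)}")
    x = np.log10([rna[k] for k in shared])
    y = np.log10([protein[k] for k in shared])
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n=len(shared),
    )


def pairwise_mwu_matrix(
    groups: Mapping[str, Sequence[float]]
) -> dict[str, dict[str, float]]:
    """Symmetric matrix of two-sided Mann-Whitney p-values between groups.

    Groups with fewer than 3 values are masked (NaN row/column); the
    diagonal is 1.0 by convention.
    """
    names = list(groups)
    mat: dict[str, dict[str, float]] = {a: {} for a in names}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                mat[a][b] = 1.0
            elif len(groups[a]) < 3 or len(groups[b]) < 3:
                mat[a][b] = float("nan")
            elif j < i:
                mat[a][b] = mat[b][a]
            else:
                res = stats.mannwhitneyu(
                    np.asarray(groups[a], dtype=float),
                    np.asarray(groups[b], dtype=float),
                    alternative="two-sided",
                )
                mat[a][b] = float(res.pvalue)
    return mat
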