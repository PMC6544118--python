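"""Within-operon coefficient of variation and its permutation null.

The dispersion statistic for one operon is the coefficient of variation of
the abundances of its quantified gene products,

    CV% = 100 * s / mean,    s = sqrt( sum_i (x_i - mean)^2 / (n - 1) ),

computed on linear-scale quantities over the n >= 2 quantified members.
Because CV is scale-invariant, the statistic is identical on raw
intensities and on calibrated copies per cell.

The null model asks what CVs would look like if operon membership carried
no abundance information: the quantified values of all genes belonging to
polycistronic operons are reshuffled jointly over those same gene slots,
and per-operon CVs are recomputed. The reshuffle preserves the
detected/undetected pattern — only slots that had a value receive one — and
preserves the value multiset exactly in every permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_io import Operon, ValueTable
from .errors import StatisticError, UsageError

logger = logging.getLogger(__name__)

SIZE_GROUPS = ("2", "3", "4", "5plus")


def size_group_of(n: int) -> str:
    """Bucket an operon by its number of quantified proteins."""
    if n < 2:
        raise UsageError("size groups start at 2 quantified proteins")
    return str(n) if n < 5 else "5plus"


@dataclass(frozen=True)
class OperonCVRecord:
    operon_id: str
    n_quantified: int
    cv_percent: float
    size_group: str
    source: str  # "real" | "randomized"
    permutation_index: int | None = None


@dataclass(frozen=True)
class DistributionComparison:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    sidedness: str = "two_sided"


def operon_cv(values: Sequence[float]) -> float:
    """CV% of a list of abundances (n-1 denominator in the SD)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatisticError(f"CV undefined for n={x.size} < 2")
    mean = x.mean()
    if mean <= 0:
        raise StatisticError("CV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def compute_operon_cvs(
    operons: Iterable[Operon],
    abundances: ValueTable,
    source: str = "real",
    permutation_index: int | None = None,
    group_by: str = "quantified",
) -> list[OperonCVRecord]:
    """One CV record per operon with >= 2 quantified member genes.

    Genes absent from ``abundances`` (or with value 0) are dropped, not
    zero-filled; operons left with fewer than 2 quantified genes are
    skipped. ``group_by`` controls whether the size bucket follows the
    number of quantified genes (default) or the annotated gene count.
    """
    if group_by not in {"quantified", "annotated"}:
        raise UsageError(f"group_by must be quantified or annotated, got {group_by!r}")
    vals = abundances.values
    records = []
    n_skipped = 0
    for op in operons:
        x = [float(vals[g]) for g in op.gene_ids if g in vals.index and vals[g] > 0]
        if len(x) < 2:
            n_skipped += 1
            continue
        n_for_group = len(x) if group_by == "quantified" else op.n_genes
        records.append(
            OperonCVRecord(
                operon_id=op.operon_id,
                n_quantified=len(x),
                cv_percent=operon_cv(x),
                size_group=size_group_of(n_for_group),
                source=source,
                permutation_index=permutation_index,
            )
        )
    if n_skipped:
        logger.info("compute_operon_cvs: skipped %d operons with <2 quantified genes", n_skipped)
    return records


def randomize_null(
    operons: Sequence[Operon],
    abundances: ValueTable,
    n_permutations: int = 1000,
    seed: int = 0,
    group_by: str = "quantified",
) -> list[OperonCVRecord]:
    """Reshuffled negative control for the within-operon CV distribution.

    For each permutation the quantified values of all polycistronic-operon
    genes are permuted uniformly at random over those gene slots (jointly
    across operons, then extracted per operon), and CVs are recomputed. The
    multiset of values is invariant; determinism is guaranteed by ``seed``.
    """
    if n_permutations < 1:
        raise UsageError("n_permutations must be >= 1")
    poly = [op for op in operons if op.is_polycistronic]
    vals = abundances.values
    quantified = set(vals.index[vals > 0])
    # gene slots (jointly over all polycistronic operons) and, per operon,
    # the positions of its quantified genes in that joint slot list
    slots: list[str] = []
    op_slot_idx: list[tuple[Operon, list[int]]] = []
    for op in poly:
        idx = []
        for g in op.gene_ids:
            if g in quantified:
                idx.append(len(slots))
                slots.append(g)
        if len(idx) >= 2:
            op_slot_idx.append((op, idx))
    if len(slots) < 2:
        raise StatisticError("fewer than 2 quantified genes in polycistronic operons")
    pool = np.array([float(vals[g]) for g in slots])
    rng = np.random.default_rng(seed)

    records: list[OperonCVRecord] = []
    for p in range(n_permutations):
        shuffled = rng.permutation(pool)
        for op, idx in op_slot_idx:
            x = shuffled[idx]
            n = len(idx)
            n_for_group = n if group_by == "quantified" else op.n_genes
            records.append(
                OperonCVRecord(
                    operon_id=op.operon_id,
                    n_quantified=n,
                    cv_percent=float(100.0 * x.std(ddof=1) / x.mean()),
                    size_group=size_group_of(n_for_group),
                    source="randomized",
                    permutation_index=p,
                )
            )
    return records


def cv_values(records: Iterable[OperonCVRecord], size_group: str | None = None) -> list[float]:
    """Extract cv_percent values, optionally restricted to one size group."""
    return [
        r.cv_percent
        for r in records
        if size_group is None or r.size_group == size_group
    ]


def compare_distributions(
    a: Sequence[float], b: Sequence[float], test: str = "mann_whitney_u",
    *more: Sequence[float],
) -> DistributionComparison:
    """Two-sided comparison of two (or more, for Kruskal-Wallis) samples."""
    groups = [np.asarray(g, dtype=float) for g in (a, b, *more)]
    if any(g.size < 3 for g in groups):
        raise StatisticError("each sample needs >= 3 observations")
    if test == "mann_whitney_u":
        if more:
            raise UsageError("mann_whitney_u takes exactly two samples")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif test == "kolmogorov_smirnov":
        if more:
            raise UsageError("kolmogorov_smirnov takes exactly two samples")
        res = stats.ks_2samp(groups[0], groups[1], alternative="two-sided")
    elif test == "kruskal_wallis":
        res = stats.kruskal(*groups)
    else:
        raise UsageError(f"unknown test {test!r}")
    return DistributionComparison(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(groups[0].size),
        n_b=int(groups[1].size),
    )
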