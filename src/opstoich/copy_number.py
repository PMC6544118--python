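"""Calibration of label-free MS intensities to protein copies per cell.

A single conversion coefficient *k* rescales the whole intensity table:

    k = geomean_i[(B_i + P_i + A_i) / 3] / geomean_i[D_i]
    copies_i = k * D_i

where B, P and A are prior copy-number estimates of the same protein on
three independent label-free scales (iBAQ, emPAI, APEX) and D is the
measured intensity. The product runs over the most abundant proteins of the
reference table (default the top 500, ranked by the mean of the three prior
scales) that were also detected in the intensity table. Geometric means are
accumulated in log space so n ~ 500 products cannot overflow.

Because *k* is a single multiplicative constant, all pairwise abundance
ratios — and hence every coefficient of variation downstream — are
identical whether computed on raw intensities or on calibrated copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ValueTable
from .errors import CalibrationError, QCError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConversionCoefficient:
    """Intensity-to-copies conversion factor and its provenance."""

    k: float
    n_matched: int
    top_n_requested: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError("conversion coefficient must be positive")
        if self.n_matched > self.top_n_requested:
            raise ValidationError("n_matched exceeds top_n_requested")


@dataclass(frozen=True)
class ReproducibilitySummary:
    """Pearson correlations between two replicates on log10 abundances.

    ``r_low``/``r_mid``/``r_high`` are computed within abundance sections
    bounded by ``section_bounds_log10`` on the mean log10 abundance;
    sections with fewer than 3 points report ``nan``.
    """

    r_all: float
    r_low: float
    r_mid: float
    r_high: float
    section_bounds_log10: tuple[float, float]
    n_shared: int


def select_calibration_set(
    reference: pd.DataFrame,
    quant: ValueTable,
    top_n: int = 500,
) -> list[tuple[float, float, float, float]]:
    """Match the most abundant reference proteins to detected intensities.

    Reference genes are ranked by the mean of the three prior copy-number
    columns (ties broken by gene name), the top ``top_n`` are taken, and the
    list is intersected with genes having a positive intensity. Genes with a
    non-positive value on any scale are excluded up front (the geometric
    mean is undefined for them).

    Returns the matched (B_i, P_i, A_i, D_i) tuples, in rank order.
    """
    ref = reference.copy()
    scales = ["copies_iBAQ", "copies_emPAI", "copies_APEX"]
    positive = (ref[scales] > 0).all(axis=1)
    n_excluded = int((~positive).sum())
    if n_excluded:
        logger.info("calibration: excluded %d genes with non-positive priors", n_excluded)
    ref = ref[positive]
    ref = ref.assign(_mean=ref[scales].mean(axis=1))
    ref = ref.sort_values(["_mean", "gene_name"], ascending=[False, True])
    top = ref.head(top_n)

    matched = []
    for _, row in top.iterrows():
        g = row["gene_name"]
        if g in quant.values.index:
            d = float(quant.values[g])
            if d > 0:
                matched.append(
                    (
                        float(row["copies_iBAQ"]),
                        float(row["copies_emPAI"]),
                        float(row["copies_APEX"]),
                        d,
                    )
                )
    if not matched:
        raise CalibrationError(
            "no overlap between top reference proteins and quantified intensities"
        )
    logger.info("calibration: matched %d of top %d reference proteins", len(matched), top_n)
    return matched


def conversion_coefficient(
    matched: list[tuple[float, float, float, float]],
    top_n_requested: int | None = None,
) -> ConversionCoefficient:
    """Compute *k* from matched (B, P, A, D) tuples, in log space."""
    if len(matched) < 1:
        raise CalibrationError("need at least one matched protein")
    arr = np.asarray(matched, dtype=float)
    if (arr <= 0).any():
        raise CalibrationError("non-positive value in calibration set (log undefined)")
    b, p, a, d = arr.T
    log_k = np.mean(np.log((b + p + a) / 3.0)) - np.mean(np.log(d))
    return ConversionCoefficient(
        k=float(np.exp(log_k)),
        n_matched=len(matched),
        top_n_requested=top_n_requested if top_n_requested is not None else len(matched),
    )


def to_copy_number(k: ConversionCoefficient | float, quant: ValueTable) -> ValueTable:
    """Scale an intensity table to copies per cell."""
    factor = k.k if isinstance(k, ConversionCoefficient) else float(k)
    if factor <= 0:
        raise ValidationError("conversion coefficient must be positive")
    return ValueTable(quant.values * factor, "copies")


def calibrate(
    reference: pd.DataFrame, quant: ValueTable, top_n: int = 500
) -> tuple[ConversionCoefficient, ValueTable]:
    """End-to-end calibration: select set, compute k, convert the table."""
    matched = select_calibration_set(reference, quant, top_n=top_n)
    k = conversion_coefficient(matched, top_n_requested=top_n)
    return k, to_copy_number(k, quant)


def replicate_reproducibility(
    rep1: ValueTable,
    rep2: ValueTable,
    bounds_log10: tuple[float, float] = (2.0, 3.5),
) -> ReproducibilitySummary:
    """Pearson correlation of log10 abundances between two replicates.

    The abundance axis is partitioned into low / mid / high sections at
    ``bounds_log10`` on the mean log10 abundance of the two replicates;
    per-section correlations with fewer than 3 points are ``nan``.
    """
    lo, hi = bounds_log10
    if not lo < hi:
        raise ValidationError("section bounds must be increasing")
    shared = sorted(
        k for k in rep1.keys() & rep2.keys() if rep1[k] > 0 and rep2[k] > 0
    )
    if len(shared) < 3:
        raise QCError(f"only {len(shared)} shared positive keys; need >= 3")
    x = np.log10([rep1[k] for k in shared])
    y = np.log10([rep2[k] for k in shared])
    mean_log = (x + y) / 2.0

    def _r(mask: np.ndarray) -> float:
        if mask.sum() < 3:
            return float("nan")
        return float(stats.pearsonr(x[mask], y[mask]).statistic)

    return ReproducibilitySummary(
        r_all=float(stats.pearsonr(x, y).statistic),
        r_low=_r(mean_log < lo),
        r_mid=_r((mean_log >= lo) & (mean_log <= hi)),
        r_high=_r(mean_log > hi),
        section_bounds_log10=(lo, hi),
        n_shared=len(shared),
    )
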