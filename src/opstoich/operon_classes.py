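"""Complex/Pathway operon classification, null-median splits and enrichment.

A polycistronic operon is labelled **Complex** when at least 90% of its
annotated genes encode subunits of one and the same protein complex;
every other polycistronic operon is **Pathway**. The fraction is taken over
the single best-covered complex (not a union of complexes) and over the
operon's annotated gene count (not the detected subset): classification is
a genome property, not a detection property.

``split_by_null_median`` reproduces the H/L subgrouping: within each operon
size group, operons whose CV falls below the median of the randomized-null
CVs of that group are labelled ``L<size>``, the rest ``H<size>`` (ties go
high).

``fisher_enrichment`` is a generic one-sided overrepresentation test of a
gene subset against a background, per functional term, using Fisher's exact
test on the 2x2 membership table. No multiple-testing correction is applied
by default (results are compared against raw significance thresholds); a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .data_io import Operon
from .errors import ValidationError
from .operon_cv import OperonCVRecord, SIZE_GROUPS

logger = logging.getLogger(__name__)

COMPLEX_FRACTION_THRESHOLD = 0.9


@dataclass(frozen=True)
class OperonClassLabel:
    operon_id: str
    label: str  # "Complex" | "Pathway"
    complex_fraction: float
    dominant_complex: str | None


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k_in_subset: int
    n_subset: int
    K_in_background: int
    N_background: int
    p_value: float
    significant: bool


def classify_operon(
    operon: Operon,
    membership: Mapping[str, set[str]],
    threshold: float = COMPLEX_FRACTION_THRESHOLD,
) -> OperonClassLabel:
    """Label one operon Complex or Pathway by complex-subunit content.

    ``membership`` maps gene id -> set of complex ids the gene is a subunit
    of; genes absent from the map belong to no complex. The complex fraction
    is the best single complex's coverage of the operon's gene list, and the
    label is Complex iff that fraction reaches ``threshold`` (boundary
    inclusive). Gene order within the operon is irrelevant.
    """
    if operon.n_genes == 0:
        raise ValidationError(f"operon {operon.operon_id} has no genes")
    counts: dict[str, int] = {}
    for g in operon.gene_ids:
        for cpx in membership.get(g, ()):
            counts[cpx] = counts.get(cpx, 0) + 1
    if counts:
        # deterministic tie-break on complex id
        dominant = min(counts, key=lambda c: (-counts[c], c))
        fraction = counts[dominant] / operon.n_genes
    else:
        dominant, fraction = None, 0.0
    label = "Complex" if fraction >= threshold else "Pathway"
    return OperonClassLabel(
        operon_id=operon.operon_id,
        label=label,
        complex_fraction=fraction,
        dominant_complex=dominant if label == "Complex" else dominant,
    )


def classify_operons(
    operons: Iterable[Operon], membership: Mapping[str, set[str]]
) -> dict[str, OperonClassLabel]:
    return {op.operon_id: classify_operon(op, membership) for op in operons}


def split_by_null_median(
    real_cvs: Iterable[OperonCVRecord],
    null_cvs: Iterable[OperonCVRecord],
) -> tuple[dict[str, str], dict[str, float]]:
    """Split real CV records at the per-size-group randomized median.

    Returns ``(labels, medians)`` where ``labels`` maps operon_id to
    ``L2..L5plus`` / ``H2..H5plus`` and ``medians`` reports the null median
    used per size group. An operon whose CV equals the median goes high.
    Size groups with an empty null pool are skipped with a warning.
    """
    null_by_group: dict[str, list[float]] = {g: [] for g in SIZE_GROUPS}
    for r in null_cvs:
        null_by_group[r.size_group].append(r.cv_percent)
    medians = {
        g: float(np.median(v)) for g, v in null_by_group.items() if v
    }
    labels: dict[str, str] = {}
    for r in real_cvs:
        if r.size_group not in medians:
            logger.warning(
                "size group %s has no null CVs; operon %s skipped",
                r.size_group, r.operon_id,
            )
            continue
        side = "L" if r.cv_percent < medians[r.size_group] else "H"
        labels[r.operon_id] = f"{side}{r.size_group}"
    return labels, medians


def overrepresentation_p(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher exact p for >= k subset genes in a term.

    Upper hypergeometric tail P[X >= k] for X ~ Hypergeom(N, K, n): the
    probability of drawing at least k term genes when n genes are drawn
    from a background of N containing K term genes. Accepts array inputs.
    """
    p = stats.hypergeom.sf(np.asarray(k) - 1, N, K, n)
    return np.minimum(p, 1.0) if np.ndim(p) else float(min(p, 1.0))


def fisher_enrichment(
    subset: set[str],
    background: set[str],
    annotation: Mapping[str, set[str]],
    alpha: float = 0.01,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """One-sided (overrepresentation) Fisher exact test per term.

    For each term with gene set T, the 2x2 table counts subset/background
    membership inside and outside T (restricted to the background), and the
    p-value is the upper hypergeometric tail P[X >= k]. Results are sorted
    by p-value; ``significant`` flags p <= alpha (after Benjamini-Hochberg
    adjustment when ``bh_correct`` is on).
    """
    if not subset <= background:
        raise ValidationError("subset must be contained in the background")
    n, N = len(subset), len(background)
    results = []
    for term_id, genes in annotation.items():
        term_genes = genes & background
        K = len(term_genes)
        k = len(term_genes & subset)
        p = overrepresentation_p(k, n, K, N)
        results.append((term_id, k, K, p))
    results.sort(key=lambda t: (t[3], t[0]))
    ps = [p for *_, p in results]
    if bh_correct and ps:
        m = len(ps)
        adj = [min(p * m / (i + 1), 1.0) for i, p in enumerate(ps)]
        # enforce monotonicity from the largest p down
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        ps_eff = adj
    else:
        ps_eff = ps
    return [
        EnrichmentResult(
            term_id=term_id,
            k_in_subset=k,
            n_subset=n,
            K_in_background=K,
            N_background=N,
            p_value=p,
            significant=p_eff <= alpha,
        )
        for (term_id, k, K, p), p_eff in zip(results, ps_eff)
    ]
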