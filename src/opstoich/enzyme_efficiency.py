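"""Branch-free pathway operons and kinetics-vs-abundance concordance.

Enzymes encoded in one Pathway operon often relay a substrate through
successive reactions. When the relay is *branch-free* — no other reaction
produces or consumes the intermediate metabolites — the flux through every
step is equal at steady state, so a less efficient enzyme (higher K_M,
lower k_cat) must be present in higher copy number to sustain the same
flux. This module finds operons where that prediction is testable and
scores it.

Candidate operons must satisfy three criteria:

(a) at least two quantified proteins act in the same pathway (their
    reactions lie in one connected component of the reaction graph);
(b) the sub-path spanned by those enzymes is branch-free: every internal
    metabolite between consecutive quantified enzymes has exactly one
    producing and one consuming reaction in the whole graph;
(c) kinetic parameters (k_cat or K_M) are available for all quantified
    enzymes, with at least one value measured in the reference organism.

Concordance is formalized as a positive Spearman rank correlation between
K_M and protein copy number over the operon's quantified enzymes (with two
enzymes this reduces to a pairwise order check), and the within-operon
RNA-protein inversion as a negative Spearman correlation of their ranks.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import KineticsRecord, Operon, ValueTable
from .errors import KineticsError, StatisticError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reaction:
    substrate: str
    product: str
    enzyme_gene: str

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValidationError(
                f"reaction of {self.enzyme_gene}: self-loop on {self.substrate}"
            )


@dataclass
class PathwayGraph:
    """A directed metabolite graph; each edge is one enzymatic reaction."""

    reactions: list[Reaction] = field(default_factory=list)

    @property
    def metabolites(self) -> set[str]:
        return {r.substrate for r in self.reactions} | {r.product for r in self.reactions}

    def producers(self, metabolite: str) -> list[Reaction]:
        return [r for r in self.reactions if r.product == metabolite]

    def consumers(self, metabolite: str) -> list[Reaction]:
        return [r for r in self.reactions if r.substrate == metabolite]

    def reaction_of(self, enzyme_gene: str) -> Reaction | None:
        for r in self.reactions:
            if r.enzyme_gene == enzyme_gene:
                return r
        return None

    def _adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = defaultdict(list)
        for r in self.reactions:
            adj[r.substrate].append(r.product)
        return adj

    def directed_path(self, source: str, target: str) -> list[str] | None:
        """Shortest directed metabolite path source -> target (inclusive)."""
        if source == target:
            return [source]
        adj = self._adjacency()
        prev: dict[str, str] = {}
        frontier = [source]
        seen = {source}
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        prev[v] = u
                        if v == target:
                            path = [v]
                            while path[-1] != source:
                                path.append(prev[path[-1]])
                            return path[::-1]
                        nxt.append(v)
            frontier = nxt
        return None


@dataclass(frozen=True)
class ConcordanceVerdict:
    operon_id: str
    n_enzymes: int
    km_abundance_concordant: bool
    rna_protein_inverted: bool
    spearman_km_abundance: float


def _chain_orders(graph: PathwayGraph, reactions: list[Reaction]) -> list[list[Reaction]]:
    """Candidate orderings of the reactions along the directed flow."""

    def reaches(a: Reaction, b: Reaction) -> bool:
        return graph.directed_path(a.product, b.substrate) is not None

    order = sorted(
        reactions, key=lambda r: sum(reaches(r, other) for other in reactions),
        reverse=True,
    )
    out = []
    for candidate in (order, order[::-1]):
        if all(reaches(a, b) for a, b in zip(candidate, candidate[1:])):
            if candidate not in out:
                out.append(candidate)
    return out


def _order_is_branch_free(graph: PathwayGraph, order: list[Reaction]) -> bool:
    for a, b in zip(order, order[1:]):
        path = graph.directed_path(a.product, b.substrate)
        if path is None:
            return False
        for metabolite in path:  # internal metabolites, endpoints included
            if len(graph.producers(metabolite)) != 1 or len(graph.consumers(metabolite)) != 1:
                return False
    return True


def branch_free_candidates(
    operons: list[Operon],
    quant: ValueTable,
    graph: PathwayGraph,
    kinetics: list[KineticsRecord],
    reference_organism: str = "E. coli",
) -> list[str]:
    """Operon ids passing the branch-free pathway criteria (a)-(c)."""
    kin_by_gene = {k.enzyme_gene: k for k in kinetics}
    quantified = {g for g in quant.keys() if quant[g] > 0}
    candidates = []
    for op in operons:
        enzymes = [
            g for g in op.gene_ids
            if g in quantified and graph.reaction_of(g) is not None
        ]
        if len(enzymes) < 2:
            logger.info("operon %s rejected: <2 quantified pathway enzymes", op.operon_id)
            continue
        reactions = [graph.reaction_of(g) for g in enzymes]
        orders = _chain_orders(graph, reactions)  # type: ignore[arg-type]
        if not orders:
            logger.info("operon %s rejected: enzymes not on one directed chain", op.operon_id)
            continue
        if not any(_order_is_branch_free(graph, order) for order in orders):
            logger.info("operon %s rejected: branched or non-linear intermediate", op.operon_id)
            continue
        recs = [kin_by_gene.get(g) for g in enzymes]
        if any(r is None for r in recs):
            logger.info("operon %s rejected: kinetics missing for an enzyme", op.operon_id)
            continue
        if not any(r.has_native_value(reference_organism) for r in recs):  # type: ignore[union-attr]
            logger.info(
                "operon %s rejected: no kinetic value measured in %s",
                op.operon_id, reference_organism,
            )
            continue
        candidates.append(op.operon_id)
    return candidates


def kinetic_ratio(
    e1: KineticsRecord, e2: KineticsRecord, parameter: str = "K_M"
) -> tuple[float, float]:
    """Ratio (and its log10) of one kinetic parameter between two enzymes."""
    if parameter not in {"K_M", "k_cat"}:
        raise KineticsError(f"unknown parameter {parameter!r}")
    vals = []
    for rec in (e1, e2):
        v = rec.K_M if parameter == "K_M" else rec.k_cat
        if v is None:
            raise KineticsError(f"enzyme {rec.enzyme_gene}: {parameter} not available")
        vals.append(v)
    ratio = vals[0] / vals[1]
    return ratio, math.log10(ratio)


def concordance(
    operon: Operon,
    quant_protein: ValueTable,
    quant_rna: ValueTable | None,
    kinetics: list[KineticsRecord],
) -> ConcordanceVerdict:
    """Test whether less active enzymes (higher K_M) are more abundant.

    Uses K_M as the activity proxy. ``km_abundance_concordant`` is True when
    the Spearman correlation between K_M and protein copies over the
    operon's enzymes is strictly positive. When an RNA table is supplied,
    ``rna_protein_inverted`` flags a negative Spearman correlation between
    within-operon RNA and protein ranks.
    """
    kin_by_gene = {k.enzyme_gene: k for k in kinetics}
    genes = [
        g for g in operon.gene_ids
        if g in kin_by_gene and kin_by_gene[g].K_M is not None
        and g in quant_protein.keys() and quant_protein[g] > 0
    ]
    if len(genes) < 2:
        raise StatisticError(
            f"operon {operon.operon_id}: <2 enzymes with both K_M and abundance"
        )
    km = np.array([kin_by_gene[g].K_M for g in genes], dtype=float)
    copies = np.array([quant_protein[g] for g in genes], dtype=float)
    if len(genes) == 2:
        # pairwise order check; ties are non-concordant
        rho = float(np.sign((km[0] - km[1]) * (copies[0] - copies[1])))
    else:
        rho = float(stats.spearmanr(km, copies).statistic)
    inverted = False
    if quant_rna is not None:
        shared = [g for g in genes if g in quant_rna.keys() and quant_rna[g] > 0]
        if len(shared) >= 2:
            rna = np.array([quant_rna[g] for g in shared], dtype=float)
            prot = np.array([quant_protein[g] for g in shared], dtype=float)
            if len(shared) == 2:
                rho_rp = float(np.sign((rna[0] - rna[1]) * (prot[0] - prot[1])))
            else:
                rho_rp = float(stats.spearmanr(rna, prot).statistic)
            inverted = bool(rho_rp < 0)
    return ConcordanceVerdict(
        operon_id=operon.operon_id,
        n_enzymes=len(genes),
        km_abundance_concordant=bool(rho > 0),
        rna_protein_inverted=inverted,
        spearman_km_abundance=rho,
    )


def sign_test_summary(verdicts: list[ConcordanceVerdict]) -> dict:
    """Binomial sign test of concordant vs discordant operon verdicts.

    The per-operon booleans are the primary result; this two-sided binomial
    test against p=0.5 is a convenience summary of how surprising the
    concordant count would be under no kinetics-abundance relation.
    """
    n = len(verdicts)
    k = sum(v.km_abundance_concordant for v in verdicts)
    p = float(stats.binomtest(k, n, 0.5).pvalue) if n else float("nan")
    return {"n_operons": n, "n_concordant": k, "binomial_p": p}
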