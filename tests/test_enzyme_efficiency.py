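import itertools
import math

import pytest

from opstoich import load_table1_kinetics
from opstoich.data_io import KineticsRecord, Operon
from opstoich.enzyme_efficiency import (
    PathwayGraph,
    Reaction,
    branch_free_candidates,
    concordance,
    kinetic_ratio,
)
from opstoich.errors import KineticsError, StatisticError, ValidationError


def linear_graph(genes, prefix="m"):
    return PathwayGraph(
        reactions=[
            Reaction(f"{prefix}{i}", f"{prefix}{i + 1}", g) for i, g in enumerate(genes)
        ]
    )


def kin(gene, km=1.0, kcat=None, native=True):
    org = "E. coli" if native else "S. cerevisiae"
    return KineticsRecord(gene, k_cat=kcat, K_M=km, k_cat_organism=org, K_M_organism=org)


class TestKineticRatio:
    def test_km_ratio_argb_over_argc(self):
        recs = {r.enzyme_gene: r for r in load_table1_kinetics()}
        ratio, _ = kinetic_ratio(recs["ArgB"], recs["ArgC"], "K_M")
        assert ratio == pytest.approx(3.25)

    def test_kcat_log_ratio_bioc_over_biof(self):
        recs = {r.enzyme_gene: r for r in load_table1_kinetics()}
        _, log_ratio = kinetic_ratio(recs["BioC"], recs["BioF"], "k_cat")
        assert log_ratio == pytest.approx(math.log10(98.334 / 0.05825))
        assert log_ratio == pytest.approx(3.23, abs=0.01)

    def test_identical_records_ratio_one(self):
        r = kin("x", km=2.5)
        ratio, log_ratio = kinetic_ratio(r, r, "K_M")
        assert ratio == 1.0
        assert log_ratio == 0.0

    def test_reciprocal_product_is_one(self):
        a, b = kin("a", km=1.3), kin("b", km=0.4)
        r1, _ = kinetic_ratio(a, b)
        r2, _ = kinetic_ratio(b, a)
        assert r1 * r2 == pytest.approx(1.0)

    def test_missing_parameter_named(self):
        a, b = kin("a", km=1.0), kin("b", km=1.0)
        with pytest.raises(KineticsError, match="k_cat"):
            kinetic_ratio(a, b, "k_cat")


class TestBranchFreeCandidates:
    def test_linear_chain_accepted(self, make_value_table):
        op = Operon("o", ("e1", "e2"), "+")
        quant = make_value_table({"e1": 10.0, "e2": 20.0})
        kins = [kin("e1"), kin("e2")]
        assert branch_free_candidates([op], quant, linear_graph(["e1", "e2"]), kins) == ["o"]

    def test_branched_intermediate_rejected(self, make_value_table):
        graph = linear_graph(["e1", "e2"])
        # intermediate m1 is also consumed by a third reaction -> branched
        graph.reactions.append(Reaction("m1", "side", "e3"))
        op = Operon("o", ("e1", "e2"), "+")
        quant = make_value_table({"e1": 10.0, "e2": 20.0})
        kins = [kin("e1"), kin("e2")]
        assert branch_free_candidates([op], quant, graph, kins) == []

    def test_extra_producer_of_intermediate_rejected(self, make_value_table):
        graph = linear_graph(["e1", "e2"])
        graph.reactions.append(Reaction("side", "m1", "e3"))
        op = Operon("o", ("e1", "e2"), "+")
        quant = make_value_table({"e1": 10.0, "e2": 20.0})
        assert branch_free_candidates([op], quant, graph, [kin("e1"), kin("e2")]) == []

    def test_missing_kinetics_rejected(self, make_value_table):
        op = Operon("o", ("e1", "e2"), "+")
        quant = make_value_table({"e1": 10.0, "e2": 20.0})
        assert branch_free_candidates([op], quant, linear_graph(["e1", "e2"]), [kin("e1")]) == []

    def test_no_native_measurement_rejected(self, make_value_table):
        op = Operon("o", ("e1", "e2"), "+")
        quant = make_value_table({"e1": 10.0, "e2": 20.0})
        kins = [kin("e1", native=False), kin("e2", native=False)]
        assert branch_free_candidates([op], quant, linear_graph(["e1", "e2"]), kins) == []

    def test_one_quantified_enzyme_rejected(self, make_value_table):
        op = Operon("o", ("e1", "e2"), "+")
        quant = make_value_table({"e1": 10.0})
        assert branch_free_candidates([op], quant, linear_graph(["e1", "e2"]),
                                      [kin("e1"), kin("e2")]) == []

    def test_unquantified_middle_enzyme_still_linear(self, make_value_table):
        # e2 not quantified: the spanned sub-path m1->m2 must still be branch-free
        graph = linear_graph(["e1", "e2", "e3"])
        op = Operon("o", ("e1", "e2", "e3"), "+")
        quant = make_value_table({"e1": 10.0, "e3": 5.0})
        kins = [kin("e1"), kin("e3")]
        assert branch_free_candidates([op], quant, graph, kins) == ["o"]

    def test_agrees_with_exhaustive_path_oracle(self, make_value_table):
        """Random small graphs: candidate iff some simple path connects the two
        enzyme reactions and every metabolite on it has in=out=1 degree."""
        import numpy as np

        rng = np.random.default_rng(12)
        for trial in range(30):
            n_met = int(rng.integers(3, 8))
            mets = [f"m{i}" for i in range(n_met)]
            reactions = []
            used = set()
            genes = itertools.count()
            for _ in range(int(rng.integers(2, 8))):
                s, t = rng.choice(n_met, size=2, replace=False)
                if (s, t) in used:
                    continue
                used.add((s, t))
                reactions.append(Reaction(mets[s], mets[t], f"e{next(genes)}"))
            if len(reactions) < 2:
                continue
            graph = PathwayGraph(reactions=list(reactions))
            e_a, e_b = reactions[0], reactions[1]
            op = Operon("o", (e_a.enzyme_gene, e_b.enzyme_gene), "+")
            quant = make_value_table({e_a.enzyme_gene: 1.0, e_b.enzyme_gene: 2.0})
            kins = [kin(e_a.enzyme_gene), kin(e_b.enzyme_gene)]
            got = branch_free_candidates([op], quant, graph, kins) == ["o"]

            # oracle: enumerate all simple metabolite paths between the two
            # reactions (either order) and test the degree condition
            adj = {}
            for r in reactions:
                adj.setdefault(r.substrate, []).append(r.product)

            def simple_paths(u, v, seen):
                if u == v:
                    yield [u]
                    return
                for w in adj.get(u, []):
                    if w not in seen:
                        yield from (
                            [u] + rest for rest in simple_paths(w, v, seen | {w})
                        )

            def ok(first, second):
                paths = list(simple_paths(first.product, second.substrate,
                                          {first.product}))
                for path in paths:
                    if all(
                        len(graph.producers(m)) == 1 and len(graph.consumers(m)) == 1
                        for m in path
                    ):
                        return True
                return False

            expect = ok(e_a, e_b) or ok(e_b, e_a)
            assert got == expect, f"trial {trial}: got {got}, oracle {expect}"


class TestConcordance:
    def test_two_enzyme_pairwise_order(self, make_value_table):
        op = Operon("o", ("argB", "argC"), "+")
        kins = [kin("argB", km=1.3), kin("argC", km=0.4)]
        prot = make_value_table({"argB": 1000.0, "argC": 200.0})
        v = concordance(op, prot, None, kins)
        assert v.km_abundance_concordant
        assert v.spearman_km_abundance == 1.0

    def test_matching_ranks_spearman_one(self, make_value_table):
        op = Operon("o", ("a", "b", "c"), "+")
        kins = [kin("a", km=0.1), kin("b", km=1.0), kin("c", km=10.0)]
        prot = make_value_table({"a": 10.0, "b": 100.0, "c": 1000.0})
        v = concordance(op, prot, None, kins)
        assert v.spearman_km_abundance == pytest.approx(1.0)
        assert v.km_abundance_concordant

    def test_reversed_ranks_not_concordant(self, make_value_table):
        op = Operon("o", ("a", "b", "c"), "+")
        kins = [kin("a", km=10.0), kin("b", km=1.0), kin("c", km=0.1)]
        prot = make_value_table({"a": 10.0, "b": 100.0, "c": 1000.0})
        v = concordance(op, prot, None, kins)
        assert v.spearman_km_abundance == pytest.approx(-1.0)
        assert not v.km_abundance_concordant

    def test_rna_protein_inversion_flag(self, make_value_table):
        op = Operon("o", ("a", "b", "c"), "+")
        kins = [kin("a", km=0.1), kin("b", km=1.0), kin("c", km=10.0)]
        prot = make_value_table({"a": 10.0, "b": 100.0, "c": 1000.0})
        rna = make_value_table({"a": 9.0, "b": 5.0, "c": 2.0}, "rpkM")
        v = concordance(op, prot, rna, kins)
        assert v.rna_protein_inverted

    def test_fewer_than_two_enzymes_is_error(self, make_value_table):
        op = Operon("o", ("a", "b"), "+")
        prot = make_value_table({"a": 10.0})
        with pytest.raises(StatisticError):
            concordance(op, prot, None, [kin("a")])


class TestReaction:
    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError):
            Reaction("m1", "m1", "e")
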