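import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progchain import (
    ComorbidityTable,
    DiseaseProteinMatrix,
    PathwayData,
    TermStrengthTable,
    TextEvidence,
    build_adn,
    cosine_weight,
    relative_risk,
)
from progchain.builders import (
    build_pdpn,
    cdpn_weight,
    dcf,
    flow,
    normalize_raw_network,
    pdpn_weight,
    tdpn_weight,
)

bit_vectors = st.lists(st.integers(0, 1), min_size=1, max_size=30).filter(
    lambda v: sum(v) > 0
)


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_weight([1, 0, 1], [1, 0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_proteins(self):
        assert cosine_weight([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_half_overlap(self):
        # one shared protein of two each: 1 / (sqrt(2) * sqrt(2))
        assert cosine_weight([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_weight([0, 0], [1, 0])

    @given(st.tuples(bit_vectors, bit_vectors).filter(lambda p: len(p[0]) == len(p[1])))
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, pair):
        u, v = pair
        w = cosine_weight(u, v)
        assert w == pytest.approx(cosine_weight(v, u), abs=1e-12)
        assert -1e-12 <= w <= 1 + 1e-12


class TestBuildAdn:
    def test_small_k_keeps_everything(self):
        m = DiseaseProteinMatrix.from_associations(
            [("a", "p1"), ("a", "p2"), ("b", "p1"), ("b", "p3"), ("c", "p2"), ("c", "p3")]
        )
        net = build_adn(m, knn_k=2)
        assert net.n_edges == 6  # all three mutual pairs, both directions

    def test_union_rule_top1(self):
        # similarities: (a,b) high, (b,c) medium, (a,c) zero
        m = DiseaseProteinMatrix.from_associations(
            [("a", f"p{i}") for i in range(5)]
            + [("b", f"p{i}") for i in range(4)] + [("b", "p9")]
            + [("c", "p9"), ("c", "p8"), ("c", "p7"), ("c", "p6"), ("c", "p5")]
        )
        net = build_adn(m, knn_k=1)
        kept = set(net.edges)
        assert ("a", "b") in kept and ("b", "a") in kept
        assert ("b", "c") in kept and ("c", "b") in kept  # c's top-1 is b
        assert ("a", "c") not in kept and ("c", "a") not in kept

    def test_bidirection_invariant(self, rng):
        bits = (rng.random((10, 40)) < 0.3).astype(np.uint8)
        bits[bits.sum(axis=1) == 0, 0] = 1
        m = DiseaseProteinMatrix(
            [f"d{i}" for i in range(10)], [f"p{j}" for j in range(40)], bits
        )
        net = build_adn(m, knn_k=3)
        for (u, v), e in net.edges.items():
            assert (v, u) in net.edges
            assert net.edges[(v, u)].weight == e.weight
            assert e.provenance == frozenset({"ADN"})

    def test_invalid_k(self):
        m = DiseaseProteinMatrix.from_associations([("a", "p"), ("b", "p")])
        with pytest.raises(ValueError):
            build_adn(m, knn_k=0)


class TestFlow:
    def fixture_data(self):
        return PathwayData(
            gene_sets={"di": {"a", "b", "s"}, "dj": {"s", "c"}},
            reactions={("a", "s"), ("b", "c"), ("c", "a")},
        )

    @staticmethod
    def brute_force_flow(p, d_i, d_j):
        """Independent enumeration of the flow definition."""
        shared = p.gene_sets[d_i] & p.gene_sets[d_j]
        return sum(
            1
            for (g, g2) in p.reactions
            if g in p.gene_sets[d_i] and g not in shared and g2 in p.gene_sets[d_j]
        )

    def test_fixture_counts(self):
        p = self.fixture_data()
        assert flow(p, "di", "dj") == (2, 1)  # a->s, b->c forward; c->a back

    def test_matches_enumeration_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for _ in range(20):
            sets = {
                "x": set(rng.choice(genes, 5, replace=False)),
                "y": set(rng.choice(genes, 5, replace=False)),
            }
            reactions = set()
            while len(reactions) < 8:
                g1, g2 = rng.choice(genes, 2, replace=False)
                reactions.add((g1, g2))
            p = PathwayData(sets, reactions)
            assert flow(p, "x", "y") == (
                self.brute_force_flow(p, "x", "y"),
                self.brute_force_flow(p, "y", "x"),
            )

    def test_no_reactions(self):
        p = PathwayData({"x": {"a"}, "y": {"b"}}, set())
        assert flow(p, "x", "y") == (0, 0)

    def test_identical_gene_sets(self):
        p = PathwayData({"x": {"a", "b"}, "y": {"a", "b"}}, {("a", "b")})
        assert flow(p, "x", "y") == (0, 0)  # everything is in the sharing block

    def test_missing_gene_set(self):
        p = PathwayData({"x": {"a"}}, set())
        with pytest.raises(KeyError):
            flow(p, "x", "zzz")


class TestDirectionalWeights:
    @pytest.mark.parametrize(
        "flows,expected",
        [((3, 1), (3.0, 0.0)), ((2, 2), (0.0, 0.0)), ((0, 5), (0.0, 5.0))],
    )
    def test_pdpn_weight_examples(self, flows, expected):
        assert pdpn_weight(*flows) == expected

    @pytest.mark.parametrize(
        "rrs,expected",
        [((4.0, 3.0), (4 / 3, 0.0)), ((2.0, 2.0), (0.0, 0.0)), ((1.0, 5.0), (0.0, 5.0))],
    )
    def test_cdpn_weight_examples(self, rrs, expected):
        r = cdpn_weight(*rrs)
        assert r[0] == pytest.approx(expected[0], abs=1e-12)
        assert r[1] == pytest.approx(expected[1], abs=1e-12)

    def test_cdpn_degenerate_rr_rejected(self):
        with pytest.raises(ValueError):
            cdpn_weight(1.0, 0.0)
        with pytest.raises(ValueError):
            cdpn_weight(math.inf, 1.0)

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, derandomize=True)
    def test_pdpn_antisymmetry(self, f_ij, f_ji):
        r_ij, r_ji = pdpn_weight(f_ij, f_ji)
        assert r_ij * r_ji == 0.0

    @given(
        st.floats(0.01, 50, allow_nan=False),
        st.floats(0.01, 50, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_cdpn_antisymmetry_and_dominant_gt1(self, rr_ij, rr_ji):
        r_ij, r_ji = cdpn_weight(rr_ij, rr_ji)
        assert r_ij * r_ji == 0.0
        nonzero = max(r_ij, r_ji)
        if nonzero:
            assert nonzero > 1.0


class TestRelativeRisk:
    def test_enriched_pair(self):
        t = ComorbidityTable(100, {"A": 20, "B": 10}, {("A", "B"): 5})
        assert relative_risk(t, "A", "B") == pytest.approx(4.0, abs=1e-12)

    def test_independence_gives_one(self):
        t = ComorbidityTable(100, {"A": 20, "B": 10}, {("A", "B"): 2})
        assert relative_risk(t, "A", "B") == pytest.approx(1.0, abs=1e-12)

    def test_zero_cooccurrence(self):
        t = ComorbidityTable(100, {"A": 20, "B": 10}, {})
        assert relative_risk(t, "A", "B") == 0.0

    def test_degenerate_conditioning(self):
        t = ComorbidityTable(100, {"A": 0, "B": 10}, {})
        with pytest.raises(ValueError, match="undefined"):
            relative_risk(t, "A", "B")

    def test_infinite_rr_signalled(self):
        # everyone with B also has A
        t = ComorbidityTable(100, {"A": 20, "B": 5}, {("A", "B"): 5})
        assert relative_risk(t, "A", "B") == math.inf

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_matches_direct_arithmetic(self, data):
        n = data.draw(st.integers(10, 1000))
        n_a = data.draw(st.integers(1, n - 1))
        n_b = data.draw(st.integers(1, n - 1))
        n_ab = data.draw(st.integers(0, min(n_a, n_b)))
        t = ComorbidityTable(n, {"A": n_a, "B": n_b}, {("A", "B"): n_ab})
        p_b_a = n_ab / n_a
        p_b_not_a = (n_b - n_ab) / (n - n_a)
        if p_b_not_a == 0 and p_b_a == 0:
            with pytest.raises(ValueError):
                relative_risk(t, "A", "B")
        elif p_b_not_a == 0:
            assert relative_risk(t, "A", "B") == math.inf
        else:
            assert relative_risk(t, "A", "B") == pytest.approx(
                p_b_a / p_b_not_a, rel=1e-12
            )


class TestComorbidityTable:
    def test_pair_exceeding_single_rejected(self):
        with pytest.raises(ValueError):
            ComorbidityTable(100, {"A": 3, "B": 10}, {("A", "B"): 5})

    def test_unsorted_pair_normalized(self):
        t = ComorbidityTable(100, {"A": 10, "B": 10}, {("B", "A"): 5})
        assert t.pair_count("A", "B") == 5


class TestDcf:
    @pytest.mark.parametrize(
        "df,cf,expected",
        [(0, 0, 0.0), (1, 1, math.log(2)), (2, 3, 2 * math.log(4))],
    )
    def test_examples(self, df, cf, expected):
        assert dcf(df, cf) == pytest.approx(expected, abs=1e-12)

    def test_clauses_below_documents_rejected(self):
        with pytest.raises(ValueError, match="clause"):
            dcf(3, 2)

    def test_log_base_rescales(self):
        assert dcf(2, 3, log_base=2) == pytest.approx(2 * math.log2(4), abs=1e-12)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 5), st.integers(0, 5))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_both_counts(self, df, extra_cf, d_inc, c_inc):
        cf = df + extra_cf
        assert dcf(df + d_inc, cf + d_inc + c_inc) >= dcf(df, cf) - 1e-12


class TestTdpnWeight:
    def test_composed_example(self):
        # term strength 2, pair (i, j) in 2 documents / 3 clauses, reverse unseen
        ev = TextEvidence(
            [("causes", "i", "j", "d1", 2), ("causes", "i", "j", "d2", 1)]
        )
        alphas = TermStrengthTable({"causes": 2.0})
        r_ij, r_ji = tdpn_weight(ev, alphas, "i", "j")
        assert r_ij == pytest.approx(2 * 2 * math.log(4), abs=1e-12)
        assert r_ji == 0.0

    def test_positive_part_both_orientations(self):
        alphas = TermStrengthTable({"t": 1.0})
        fwd = [("t", "i", "j", f"f{k}", 1) for k in range(5)]
        rev = [("t", "j", "i", f"r{k}", 1) for k in range(3)]
        ev = TextEvidence(fwd + rev)
        r_ij, r_ji = tdpn_weight(ev, alphas, "i", "j")
        assert r_ij > 0 and r_ji == 0.0
        r_ji2, r_ij2 = tdpn_weight(ev, alphas, "j", "i")
        assert (r_ij2, r_ji2) == (r_ij, r_ji)

    def test_missing_term_named(self):
        ev = TextEvidence([("mystery", "i", "j", "d1", 1)])
        with pytest.raises(KeyError, match="mystery"):
            tdpn_weight(ev, TermStrengthTable({"other": 1.0}), "i", "j")


class TestNormalize:
    def test_divide_by_max(self):
        net = normalize_raw_network({("a", "b"): 2.0, ("b", "c"): 4.0}, "pDPN")
        assert net.weight("a", "b") == pytest.approx(0.5)
        assert net.weight("b", "c") == pytest.approx(1.0)

    def test_single_edge_becomes_one(self):
        net = normalize_raw_network({("a", "b"): 7.0}, "pDPN")
        assert net.weight("a", "b") == 1.0

    def test_zero_edges_dropped(self):
        assert normalize_raw_network({("a", "b"): 0.0}, "pDPN").n_edges == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_raw_network({("a", "b"): -1.0}, "pDPN")


class TestBuilderNetworksSatisfyInvariants:
    def test_all_layers_valid(self, default_layers):
        for tag, net in default_layers:
            net.validate()
            for e in net.edges.values():
                assert e.provenance == frozenset({tag})

    def test_pdpn_from_fixture(self):
        p = PathwayData(
            gene_sets={"di": {"a", "b", "s"}, "dj": {"s", "c"}},
            reactions={("a", "s"), ("b", "c"), ("c", "a")},
        )
        net = build_pdpn(p)
        # flow 2 vs 1: direction di -> dj, single edge normalized to 1
        assert set(net.edges) == {("di", "dj")}
        assert net.weight("di", "dj") == 1.0
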