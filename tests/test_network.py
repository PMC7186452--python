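import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mon.network import (
    DomainMap,
    ExpressionProfile,
    MultiplexNetwork,
    PinGraph,
    ProteinUniverse,
    WeightedLayer,
    assemble_multiplex,
    build_co_expression,
    build_co_neighbor,
    build_co_structure,
    coverage_rate,
    domain_score_raw,
    domain_scores_normalized,
    pearson_correlation,
)

from .conftest import make_layer


# ---------------------------------------------------------------------------
# ProteinUniverse / PinGraph


class TestUniverse:
    def test_round_trip_index(self):
        u = ProteinUniverse.from_ids(["b", "a", "c"])
        for i, p in enumerate(u.ids):
            assert u.position(p) == i
        assert len(u) == 3

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            ProteinUniverse.from_ids(["a", "a"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ProteinUniverse.from_ids([])


class TestPinGraph:
    def test_dedup_and_self_loops(self):
        pin = PinGraph.from_edges([("a", "b"), ("b", "a"), ("a", "a")])
        assert pin.edges == frozenset({("a", "b")})

    def test_neighbors_exclude_self(self, triangle_pin):
        nbrs = triangle_pin.neighbors()
        assert nbrs["a"] == frozenset({"b", "c"})
        assert "a" not in nbrs["a"]


# ---------------------------------------------------------------------------
# Co-neighbor layer


class TestCoNeighbor:
    def test_triangle_edge_weight_one(self, triangle_pin):
        layer = build_co_neighbor(triangle_pin)
        # N_a = {b,c}, N_b = {a,c}, one common neighbor: 1 / (1*1)
        assert layer.weight("a", "b") == pytest.approx(1.0)

    def test_path_has_no_common_neighbor_edge(self):
        pin = PinGraph.from_edges([("a", "b"), ("b", "c")])
        layer = build_co_neighbor(pin)
        assert layer.n_edges == 0

    def test_star_with_chord(self, star_plus_pin):
        layer = build_co_neighbor(star_plus_pin)
        # edge (a,b): N_a = {b,c,d}, N_b = {a,c}, common = {c}
        assert layer.weight("a", "b") == pytest.approx(1.0 / ((3 - 1) * (2 - 1)))

    def test_subset_of_pin_edges(self, star_plus_pin):
        layer = build_co_neighbor(star_plus_pin)
        assert set(layer.weights) <= set(star_plus_pin.edges)

    @given(st.sets(
        st.tuples(st.integers(0, 11), st.integers(0, 11)).filter(lambda e: e[0] != e[1]),
        min_size=1, max_size=30,
    ))
    @settings(max_examples=60, deadline=None)
    def test_weights_in_unit_interval(self, raw_edges):
        pin = PinGraph.from_edges([(f"n{a}", f"n{b}") for a, b in raw_edges])
        layer = build_co_neighbor(pin)
        for w in layer.weights.values():
            assert 0.0 < w <= 1.0
        assert set(layer.weights) <= set(pin.edges)

    @given(st.sets(
        st.tuples(st.integers(0, 9), st.integers(0, 9)).filter(lambda e: e[0] != e[1]),
        min_size=1, max_size=20,
    ), st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_permutation_equivariance(self, raw_edges, rnd):
        nodes = sorted({x for e in raw_edges for x in e})
        relabel = {a: b for a, b in zip(nodes, rnd.sample(nodes, len(nodes)))}
        pin = PinGraph.from_edges([(f"n{a}", f"n{b}") for a, b in raw_edges])
        pin2 = PinGraph.from_edges(
            [(f"n{relabel[a]}", f"n{relabel[b]}") for a, b in raw_edges]
        )
        l1 = build_co_neighbor(pin)
        l2 = build_co_neighbor(pin2)
        for (a, b), w in l1.weights.items():
            ra, rb = relabel[int(a[1:])], relabel[int(b[1:])]
            assert l2.weight(f"n{ra}", f"n{rb}") == pytest.approx(w)
        assert l1.n_edges == l2.n_edges


# ---------------------------------------------------------------------------
# Domain scores / co-structure layer


@pytest.fixture
def toy_domains():
    # NP(d1) = 1, NP(d2) = 2
    return DomainMap.from_pairs([("p1", "d1"), ("p1", "d2"), ("p2", "d2")])


class TestDomainScores:
    def test_raw_score(self, toy_domains):
        assert domain_score_raw("p1", toy_domains) == pytest.approx(1.5)
        assert domain_score_raw("p2", toy_domains) == pytest.approx(0.5)

    def test_raw_score_no_domains(self, toy_domains):
        assert domain_score_raw("p3", toy_domains) == 0.0

    def test_normalized(self, toy_domains):
        u = ProteinUniverse.from_ids(["p1", "p2", "p3"])
        norm = domain_scores_normalized(u, toy_domains)
        assert norm == pytest.approx({"p1": 1.0, "p2": 1.0 / 3.0, "p3": 0.0})

    def test_single_protein_degenerate(self):
        u = ProteinUniverse.from_ids(["p1"])
        dm = DomainMap.from_pairs([("p1", "d1")])
        assert domain_scores_normalized(u, dm) == {"p1": 0.0}

    def test_constant_scores_degenerate(self):
        u = ProteinUniverse.from_ids(["p1", "p2"])
        dm = DomainMap.from_pairs([("p1", "d1"), ("p2", "d1")])
        assert domain_scores_normalized(u, dm) == {"p1": 0.0, "p2": 0.0}

    def test_range_and_extremes(self, small_bundle):
        norm = domain_scores_normalized(
            small_bundle.pin.universe, small_bundle.domains
        )
        vals = list(norm.values())
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert max(vals) == pytest.approx(1.0)
        assert min(vals) == pytest.approx(0.0)


class TestCoStructure:
    def test_product_weight(self, toy_domains):
        pin = PinGraph.from_edges(
            [("p1", "p2"), ("p2", "p3")],
            universe=ProteinUniverse.from_ids(["p1", "p2", "p3"]),
        )
        layer = build_co_structure(pin, toy_domains)
        assert layer.weight("p1", "p2") == pytest.approx(1.0 / 3.0)

    def test_zero_score_endpoint_gives_no_edge(self, toy_domains):
        pin = PinGraph.from_edges(
            [("p1", "p2"), ("p2", "p3")],
            universe=ProteinUniverse.from_ids(["p1", "p2", "p3"]),
        )
        layer = build_co_structure(pin, toy_domains)
        assert layer.weight("p2", "p3") == 0.0  # p3 normalizes to 0
        assert ("p2", "p3") not in layer.weights

    def test_restricted_to_pin_edges(self):
        # p1 and p3 both score high but do not interact
        dm = DomainMap.from_pairs(
            [("p1", "d1"), ("p3", "d2"), ("p2", "d3"), ("p4", "d3")]
        )
        pin = PinGraph.from_edges(
            [("p1", "p2"), ("p3", "p4")],
            universe=ProteinUniverse.from_ids(["p1", "p2", "p3", "p4"]),
        )
        layer = build_co_structure(pin, dm)
        assert layer.weight("p1", "p3") == 0.0
        assert set(layer.weights) <= set(pin.edges)


# ---------------------------------------------------------------------------
# Pearson / co-expression layer


class TestPearson:
    def test_identity(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_antithetic(self):
        assert pearson_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        assert pearson_correlation([1, 2, 3], [2, 2, 2]) is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0], [2.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_against_two_pass_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        # brute-force: raw-moment form, n*sum(xy) - sum(x)sum(y) over the
        # product of the two standard deviations' raw-moment expressions
        num = n * float(np.sum(x * y)) - float(np.sum(x)) * float(np.sum(y))
        den = math.sqrt(n * float(np.sum(x * x)) - float(np.sum(x)) ** 2) * math.sqrt(
            n * float(np.sum(y * y)) - float(np.sum(y)) ** 2
        )
        assert pearson_correlation(x, y) == pytest.approx(num / den, abs=1e-12)


class TestCoExpression:
    def _profile(self, **vecs):
        return ExpressionProfile.from_dict(vecs)

    def test_absolute_value_of_negative_pcc(self):
        pin = PinGraph.from_edges([("a", "b")])
        expr = self._profile(a=[1.0, 2.0, 3.0, 5.0], b=[5.0, 3.0, 2.0, 1.0])
        layer = build_co_expression(pin, expr)
        r = pearson_correlation([1.0, 2.0, 3.0, 5.0], [5.0, 3.0, 2.0, 1.0])
        assert r < 0
        assert layer.weight("a", "b") == pytest.approx(abs(r))

    def test_missing_endpoint_dropped(self):
        pin = PinGraph.from_edges([("a", "b")])
        expr = self._profile(a=[1.0, 2.0, 3.0])
        layer = build_co_expression(pin, expr)
        assert layer.n_edges == 0

    def test_perfect_correlation(self):
        pin = PinGraph.from_edges([("a", "b")])
        expr = self._profile(a=[1.0, 2.0, 3.0], b=[2.0, 4.0, 6.0])
        layer = build_co_expression(pin, expr)
        assert layer.weight("a", "b") == pytest.approx(1.0)

    def test_zero_variance_dropped(self):
        pin = PinGraph.from_edges([("a", "b")])
        expr = self._profile(a=[1.0, 2.0, 3.0], b=[2.0, 2.0, 2.0])
        layer = build_co_expression(pin, expr)
        assert layer.n_edges == 0


# ---------------------------------------------------------------------------
# Multiplex assembly / coverage arithmetic


class TestAssemble:
    def test_three_layers(self):
        u = ProteinUniverse.from_ids([f"p{i}" for i in range(5)])
        layers = [make_layer(u, {("p0", "p1"): 0.5}, f"l{k}") for k in range(3)]
        net = assemble_multiplex(layers)
        assert net.L == 3 and net.n == 5
        assert [l.layer_name for l in net.layers] == ["l0", "l1", "l2"]

    def test_mismatched_universes_rejected(self):
        u1 = ProteinUniverse.from_ids(["a", "b"])
        u2 = ProteinUniverse.from_ids(["a", "c"])
        with pytest.raises(ValueError):
            assemble_multiplex([
                make_layer(u1, {("a", "b"): 1.0}),
                make_layer(u2, {("a", "c"): 1.0}),
            ])

    def test_single_layer_ok(self):
        u = ProteinUniverse.from_ids(["a", "b"])
        net = assemble_multiplex([make_layer(u, {("a", "b"): 1.0})])
        assert net.L == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_multiplex([])


class TestCoverageRate:
    def test_dip_counts(self):
        assert coverage_rate(4985, 5093) == 97.88

    def test_gavin_counts(self):
        assert coverage_rate(1827, 1855) == 98.49

    def test_zero_covered(self):
        assert coverage_rate(0, 10) == 0.0

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            coverage_rate(1, 0)

    def test_covered_above_total(self):
        with pytest.raises(ValueError):
            coverage_rate(11, 10)


# ---------------------------------------------------------------------------
# Layer validation


class TestWeightedLayerInvariants:
    def test_weight_above_one_rejected(self):
        u = ProteinUniverse.from_ids(["a", "b"])
        with pytest.raises(ValueError):
            WeightedLayer(u, {("a", "b"): 1.5}, "bad")

    def test_zero_weight_rejected(self):
        u = ProteinUniverse.from_ids(["a", "b"])
        with pytest.raises(ValueError):
            WeightedLayer(u, {("a", "b"): 0.0}, "bad")

    def test_self_pair_rejected(self):
        u = ProteinUniverse.from_ids(["a", "b"])
        with pytest.raises(ValueError):
            WeightedLayer(u, {("a", "a"): 0.5}, "bad")
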