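"""Degree, generality, connectance, robustness, and interlayer turnover."""

import itertools

import numpy as np
import pytest

from thermoweb import (
    FeasibilityNetwork,
    TemperatureSizeRule,
    build_network,
    connectance,
    degree,
    degrees,
    generality,
    link_turnover,
    robustness,
)

from conftest import REF_T, make_consumer, make_resources, random_community


def net_from_edges(consumer_ids, resource_ids, edges, cutting_forces=None):
    return FeasibilityNetwork(
        temperature=20.0,
        consumer_ids=tuple(consumer_ids),
        resource_ids=tuple(resource_ids),
        edges=frozenset(edges),
        weights={e: 1.0 for e in edges},
        cutting_forces=cutting_forces or {},
    )


def exhaustive_random_robustness(network: FeasibilityNetwork) -> float:
    """Average attack-tolerance area over every resource removal order."""
    consumers = {c: network.consumer_neighbors(c) for c in network.consumer_ids}
    resources = list(network.resource_ids)
    n_c, n_r = len(consumers), len(resources)
    areas = []
    for order in itertools.permutations(resources):
        removed = set()
        curve = [1.0]
        for r in order:
            removed.add(r)
            surviving = sum(1 for nb in consumers.values() if nb - removed) / n_c
            curve.append(surviving)
        fractions = np.arange(n_r + 1) / n_r
        areas.append(np.trapezoid(curve, fractions))
    return float(np.mean(areas))


class TestSimpleMetrics:
    def test_degrees_on_worked_example(self, worked_network):
        net, _, _ = worked_network
        assert degrees(net) == {"c1": 1, "c2": 2}

    def test_isolated_consumer_has_degree_zero(self):
        net = net_from_edges(["a", "b"], ["p"], {("b", "p")})
        assert degree(net, "a") == 0

    def test_unknown_id_lookup_error(self, worked_network):
        net, _, _ = worked_network
        with pytest.raises(KeyError):
            degree(net, "missing")

    def test_generality_is_mean_degree(self, worked_network):
        net, _, _ = worked_network
        assert generality(net) == pytest.approx(1.5)

    def test_generality_edge_cases(self):
        empty = net_from_edges(["a"], ["p"], set())
        assert generality(empty) == 0.0
        complete = net_from_edges(["a"], ["p", "q", "r"],
                                  {("a", "p"), ("a", "q"), ("a", "r")})
        assert generality(complete) == 3.0

    def test_weighted_generality_equal_weights_equals_degree(self):
        net = net_from_edges(["a"], ["p", "q"], {("a", "p"), ("a", "q")})
        assert generality(net, weighted=True) == pytest.approx(2.0)

    def test_connectance_ratio_and_bounds(self, worked_network):
        net, _, _ = worked_network
        assert connectance(net) == pytest.approx(3 / 6)
        empty = net_from_edges(["a"], ["p"], set())
        assert connectance(empty) == 0.0
        full = net_from_edges(["a"], ["p"], {("a", "p")})
        assert connectance(full) == 1.0

    def test_connectance_invariant_under_relabeling(self, worked_network):
        net, _, _ = worked_network
        relabeled = net_from_edges(
            ["x2", "x1"], ["y3", "y1", "y2"],
            {("x1", "y1"), ("x2", "y1"), ("x2", "y2")},
        )
        assert connectance(relabeled) == connectance(net)


class TestRobustness:
    def test_single_edge_network_r_half(self):
        net = net_from_edges(["c"], ["p"], {("c", "p")})
        result = robustness(net, "random", n_replicates=5, seed=0)
        assert list(result.removal_fractions) == [0.0, 1.0]
        assert list(result.surviving_fraction) == [1.0, 0.0]
        assert result.robustness_r == pytest.approx(0.5)

    def test_one_consumer_two_resources_r_three_quarters(self):
        net = net_from_edges(["c"], ["p", "q"], {("c", "p"), ("c", "q")})
        result = robustness(net, "random", n_replicates=3, seed=0)
        assert list(result.surviving_fraction) == [1.0, 1.0, 0.0]
        assert result.robustness_r == pytest.approx(0.75)

    def test_initially_isolated_consumer_counts_as_extinct(self):
        net = net_from_edges(["a", "b"], ["p", "q"], {("b", "p"), ("b", "q")})
        result = robustness(net, "random", n_replicates=2, seed=0)
        assert result.surviving_fraction[0] == 1.0  # prepended start point
        assert result.surviving_fraction[1] == pytest.approx(0.5)

    def test_random_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n_c, n_r = int(rng.integers(1, 5)), int(rng.integers(2, 6))
            edges = {
                (f"c{i}", f"p{j}")
                for i in range(n_c)
                for j in range(n_r)
                if rng.random() < 0.5
            }
            net = net_from_edges(
                [f"c{i}" for i in range(n_c)], [f"p{j}" for j in range(n_r)], edges
            )
            exact = exhaustive_random_robustness(net)
            mc = robustness(net, "random", n_replicates=4000, seed=1).robustness_r
            assert mc == pytest.approx(exact, abs=0.02)

    def test_deterministic_strategies_ignore_replicates(self):
        net = net_from_edges(
            ["a", "b"], ["p", "q", "r"],
            {("a", "p"), ("b", "p"), ("b", "q"), ("b", "r")},
            cutting_forces={"p": 3.0, "q": 1.0, "r": 2.0},
        )
        for strategy in ("most-connected-first", "toughest-resource-first"):
            one = robustness(net, strategy, n_replicates=1)
            many = robustness(net, strategy, n_replicates=1000)
            assert np.array_equal(one.surviving_fraction, many.surviving_fraction)

    def test_most_connected_first_order(self):
        # p is shared; removing it first kills 'a' immediately
        net = net_from_edges(
            ["a", "b"], ["p", "q"], {("a", "p"), ("b", "p"), ("b", "q")}
        )
        result = robustness(net, "most-connected-first")
        assert list(result.surviving_fraction) == [1.0, 0.5, 0.0]

    def test_toughest_first_requires_cutting_forces(self):
        net = net_from_edges(["a"], ["p"], {("a", "p")})
        with pytest.raises(ValueError, match="cutting forces"):
            robustness(net, "toughest-resource-first")

    def test_unknown_strategy_rejected(self):
        net = net_from_edges(["a"], ["p"], {("a", "p")})
        with pytest.raises(ValueError, match="strategy"):
            robustness(net, "alphabetical")

    def test_consumer_side_removal_flag(self):
        net = net_from_edges(["a", "b"], ["p"], {("a", "p"), ("b", "p")})
        result = robustness(net, "random", n_replicates=10, seed=0, remove="consumers")
        # removing either consumer leaves p still linked; after both, p dies
        assert list(result.surviving_fraction) == [1.0, 1.0, 0.0]

    def test_r_always_in_unit_interval(self):
        rng = np.random.default_rng(5)
        rule = TemperatureSizeRule(alpha=0.95, reference_temperature=REF_T)
        for _ in range(10):
            consumers, resources = random_community(rng, 4, 15)
            net = build_network(consumers, resources, REF_T + 2, rule)
            r = robustness(net, "random", n_replicates=20, seed=0).robustness_r
            assert 0.0 <= r <= 1.0

    def test_curve_nonincreasing_for_monotone_strategies(self):
        net = net_from_edges(
            ["a", "b", "c"], ["p", "q", "r"],
            {("a", "p"), ("b", "q"), ("c", "r"), ("a", "q")},
            cutting_forces={"p": 1.0, "q": 5.0, "r": 3.0},
        )
        for strategy in ("most-connected-first", "toughest-resource-first"):
            curve = robustness(net, strategy).surviving_fraction
            assert all(x >= y - 1e-12 for x, y in zip(curve, curve[1:]))


class TestLinkTurnover:
    def test_identical_layers(self, worked_network):
        net, _, _ = worked_network
        assert link_turnover(net, net) == 0.0

    def test_disjoint_nonempty_layers(self):
        a = net_from_edges(["a"], ["p", "q"], {("a", "p")})
        b = net_from_edges(["a"], ["p", "q"], {("a", "q")})
        assert link_turnover(a, b) == 1.0

    def test_partial_overlap(self):
        a = net_from_edges(["a"], ["b", "c"], {("a", "b"), ("a", "c")})
        b = net_from_edges(["a"], ["b", "c"], {("a", "b")})
        assert link_turnover(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_zero(self):
        a = net_from_edges(["a"], ["p"], set())
        assert link_turnover(a, a) == 0.0

    def test_nested_layers_match_subset_identity(self):
        """For nested edge sets, turnover = 1 - |hot| / |cold|."""
        rng = np.random.default_rng(8)
        rule = TemperatureSizeRule(alpha=0.9, reference_temperature=REF_T)
        consumers, resources = random_community(rng, 5, 40)
        cold = build_network(consumers, resources, REF_T, rule)
        hot = build_network(consumers, resources, REF_T + 5, rule)
        if len(cold.edges) == 0:
            pytest.skip("degenerate draw: empty baseline")
        assert link_turnover(cold, hot) == pytest.approx(
            1 - len(hot.edges) / len(cold.edges)
        )
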