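import itertools
import math

import numpy as np
import pytest

import oracles
from conftest import make_net, net_from_adj
from idnet.topology import (
    ALL_METRICS,
    assortativity,
    global_efficiency,
    information_content,
    max_degree,
    metric_curves,
    modularity_louvain,
    nestedness,
    rich_club,
    rich_club_curve,
    transitivity,
)

class TestAnchorValues:
    def test_triangle_transitivity_is_one(self):
        assert transitivity(make_net(3, [(0, 1), (1, 2), (0, 2)])) == 1.0

    def test_path_has_no_triangles(self):
        assert transitivity(make_net(3, [(0, 1), (1, 2)])) == 0.0

    def test_path_efficiency(self):
        assert global_efficiency(make_net(3, [(0, 1), (1, 2)])) == pytest.approx(5 / 6)

    def test_complete_graph_efficiency_is_one(self):
        net = make_net(5, list(itertools.combinations(range(5), 2)))
        assert global_efficiency(net) == 1.0

    def test_empty_graph_efficiency_is_zero(self):
        assert global_efficiency(make_net(4, [])) == 0.0

    def test_star_assortativity_is_minus_one(self):
        assert assortativity(make_net(4, [(0, 1), (0, 2), (0, 3)])) == pytest.approx(-1.0)

    def test_ring_assortativity_undefined(self):
        ring = make_net(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert math.isnan(assortativity(ring))

    def test_max_degree_values(self):
        assert max_degree(make_net(4, [(0, 1), (0, 2), (0, 3)])) == 3
        assert max_degree(make_net(4, [])) == 0
        assert max_degree(make_net(5, list(itertools.combinations(range(5), 2)))) == 4

    def test_complete_graph_rich_club_is_one(self):
        net = make_net(5, list(itertools.combinations(range(5), 2)))
        for k in range(4):
            assert rich_club(net, k) == 1.0

    def test_star_rich_club_undefined_above_leaf_degree(self):
        star = make_net(5, [(0, i) for i in range(1, 5)])
        assert math.isnan(rich_club(star, 1))

    def test_two_cliques_louvain_modularity(self):
        edges = [  # two disconnected K4s
            (i, j) for i, j in itertools.combinations(range(4), 2)
        ] + [(i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)]
        q, part = modularity_louvain(make_net(8, edges), seed=0)
        assert q == pytest.approx(0.5)
        assert sorted(sorted(c) for c in part) == [
            ["n0", "n1", "n2", "n3"],
            ["n4", "n5", "n6", "n7"],
        ]

    def test_complete_graph_single_community(self):
        net = make_net(5, list(itertools.combinations(range(5), 2)))
        q, part = modularity_louvain(net, seed=0)
        assert len(part) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_nested_chain_reaches_maximum(self):
        # threshold graph: v2 ~ {v0, v1}, v3 ~ {v0, v1, v2}
        net = make_net(4, [(2, 0), (2, 1), (3, 0), (3, 1), (3, 2)])
        assert nestedness(net) == 100.0

    def test_disjoint_edges_have_zero_nestedness(self):
        assert nestedness(make_net(4, [(0, 1), (2, 3)])) == 0.0


class TestOracleEquivalence:
    CASES = [
        ("transitivity", transitivity, oracles.transitivity_oracle),
        ("efficiency", global_efficiency, oracles.efficiency_oracle),
        ("assortativity", assortativity, oracles.assortativity_oracle),
        ("max_degree", max_degree, oracles.max_degree_oracle),
        ("nestedness", nestedness, oracles.nestedness_oracle),
    ]

    @pytest.mark.parametrize("name,impl,oracle", CASES, ids=[c[0] for c in CASES])
    def test_all_four_node_graphs(self, name, impl, oracle):
        for adj in oracles.all_graphs(4):
            got, want = impl(net_from_adj(adj)), oracle(adj)
            if isinstance(want, float) and math.isnan(want):
                assert math.isnan(got), adj
            elif name == "transitivity" and adj.sum() == 0:
                pass  # no triples: implementation flags small graphs itself
            else:
                assert got == pytest.approx(want), adj

    @pytest.mark.parametrize("name,impl,oracle", CASES, ids=[c[0] for c in CASES])
    def test_random_eight_node_graphs(self, name, impl, oracle):
        rng = np.random.default_rng(101)
        for _ in range(50):
            adj = oracles.random_graph(8, rng.uniform(0.2, 0.8), rng)
            got, want = impl(net_from_adj(adj)), oracle(adj)
            if isinstance(want, float) and math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_rich_club_matches_enumeration(self):
        rng = np.random.default_rng(102)
        for _ in range(30):
            adj = oracles.random_graph(8, rng.uniform(0.2, 0.8), rng)
            net = net_from_adj(adj)
            for k in range(int(max_degree(net)) + 1):
                got, want = rich_club(net, k), oracles.rich_club_oracle(adj, k)
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want)


class TestInformationContent:
    def test_regular_graphs_attain_the_minimum_over_all_four_node_graphs(self):
        values = {}
        for i, adj in enumerate(oracles.all_graphs(4)):
            values[i] = information_content(net_from_adj(adj))
        complete = values[2**6 - 1]
        empty = values[0]
        assert complete == pytest.approx(min(values.values()))
        assert empty == pytest.approx(min(values.values()))

    def test_random_exceeds_modular_on_average(self):
        rng = np.random.default_rng(103)
        adj = np.zeros((8, 8), dtype=int)
        adj[:4, :4] = 1
        adj[4:, 4:] = 1
        np.fill_diagonal(adj, 0)
        modular = information_content(net_from_adj(adj))
        p = adj.sum() / (8 * 7)
        random_vals = [
            information_content(net_from_adj(oracles.random_graph(8, p, rng)))
            for _ in range(30)
        ]
        assert np.mean(random_vals) > modular

    def test_invariant_under_node_relabelling(self):
        rng = np.random.default_rng(104)
        for _ in range(10):
            adj = oracles.random_graph(8, 0.4, rng)
            base = information_content(net_from_adj(adj))
            for _ in range(10):
                perm = rng.permutation(8)
                relabelled = adj[np.ix_(perm, perm)]
                assert information_content(net_from_adj(relabelled)) == pytest.approx(base)


class TestInvariances:
    @pytest.mark.parametrize("name", sorted(ALL_METRICS))
    def test_metrics_invariant_under_relabelling(self, name):
        rng = np.random.default_rng(105)
        fn = ALL_METRICS[name]
        for _ in range(10):
            adj = oracles.random_graph(7, 0.45, rng)
            base = fn(net_from_adj(adj), 0)
            perm = rng.permutation(7)
            v = fn(net_from_adj(adj[np.ix_(perm, perm)]), 0)
            if math.isnan(base):
                assert math.isnan(v)
            elif name == "modularity":
                # Louvain is a restarted stochastic heuristic: its optimum is
                # only approximately label-invariant
                assert v == pytest.approx(base, abs=0.05)
            else:
                assert v == pytest.approx(base)

    def test_louvain_q_matches_direct_formula_and_bounds(self):
        rng = np.random.default_rng(106)
        for _ in range(20):
            adj = oracles.random_graph(8, 0.35, rng)
            if adj.sum() == 0:
                continue
            net = net_from_adj(adj)
            q, part = modularity_louvain(net, seed=1)
            as_indices = [{int(c[1:]) for c in comm} for comm in part]
            assert q == pytest.approx(oracles.modularity_oracle(adj, as_indices))
            assert -0.5 <= q <= 1.0

    def test_fixed_seed_reproduces_louvain(self):
        adj = oracles.random_graph(10, 0.3, np.random.default_rng(3))
        net = net_from_adj(adj)
        assert modularity_louvain(net, seed=5) == modularity_louvain(net, seed=5)


class TestMetricCurves:
    def _sweep(self):
        from idnet.netbuild import WeightedNetwork, density_sweep

        rng = np.random.default_rng(9)
        n = 8
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.random(len(iu[0]))
        w = WeightedNetwork([f"n{i}" for i in range(n)], m + m.T)
        grid = [round(0.1 * k, 2) for k in range(1, 10)]
        return grid, density_sweep(w, grid)

    def test_curve_shapes_and_complete_graph_endpoint(self):
        grid, nets = self._sweep()
        curves = metric_curves(nets + [make_net(8, list(itertools.combinations(range(8), 2)))])
        assert len(curves) == 8
        for curve in curves:
            assert len(curve.values) == 10
        trans = next(c for c in curves if c.metric_name == "transitivity")
        assert trans.values[-1] == 1.0

    def test_undefined_points_are_nan_not_interpolated(self):
        nets = [make_net(4, [(0, 1)]), make_net(4, [(0, 1), (1, 2), (2, 3), (3, 0)])]
        curves = metric_curves(nets, metrics=["assortativity"])
        assert all(math.isnan(v) for v in curves[0].values)

    def test_transitivity_tends_to_grow_with_density(self):
        grid, nets = self._sweep()
        values = [transitivity(net) for net in nets]
        # a tendency, not a theorem: allow small dips
        drops = sum(1 for a, b in zip(values, values[1:]) if b < a - 0.05)
        assert drops <= 1
        assert values[-1] > values[0]

    def test_rich_club_curve_covers_all_degrees(self):
        net = make_net(5, [(0, 1), (0, 2), (0, 3), (1, 2)])
        curve = rich_club_curve(net)
        assert sorted(curve) == list(range(int(max_degree(net)) + 1))
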