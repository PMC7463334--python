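"""Directional speed accumulation, transition graph, least-cost distances,
and the FST~distance connectivity model."""

import itertools

import numpy as np
import pandas as pd
import pytest

from reefscape import connectivity as conn
from reefscape.grids import GridSpec
from reefscape.synthetic import SeascapeConfig, generate_currents
from tests.conftest import make_series


def grid(rows=3, cols=3):
    return GridSpec(127.0, 28.0, 5.0, rows, cols)


def series_pair(u_vals, v_vals, g=None, mask=None):
    g = g or grid(*u_vals.shape[1:])
    return (make_series(g, u_vals, mask=mask, name="u"),
            make_series(g, v_vals, mask=mask, name="v"))


class TestAccumulateDirectionalSpeed:
    def test_steady_eastward_current_hand_projection(self):
        """Due-east speed s for D days: E = s*D, NE = SE = s*D/sqrt(2),
        all other directions 0."""
        s, D = 0.4, 10
        u, v = series_pair(np.full((D, 3, 3), s), np.zeros((D, 3, 3)))
        acc = conn.accumulate_directional_speed(u, v)
        names = [d[0] for d in conn.DIRECTIONS]
        get = lambda n: acc[names.index(n), 1, 1]
        assert get("E") == pytest.approx(s * D)
        assert get("NE") == pytest.approx(s * D / np.sqrt(2))
        assert get("SE") == pytest.approx(s * D / np.sqrt(2))
        for n in ("N", "S", "W", "NW", "SW"):
            assert get(n) == pytest.approx(0.0)

    def test_zero_current_isolates_node(self):
        u, v = series_pair(np.zeros((5, 3, 3)), np.zeros((5, 3, 3)))
        acc = conn.accumulate_directional_speed(u, v)
        assert np.nansum(acc) == 0
        g = conn.build_transition_graph(acc, u.mask)
        assert g.costs.nnz == 0

    def test_reversing_current_symmetry(self):
        east = np.full((4, 3, 3), 0.5)
        west = np.full((4, 3, 3), -0.5)
        u, v = series_pair(np.concatenate([east, west]), np.zeros((8, 3, 3)))
        acc = conn.accumulate_directional_speed(u, v)
        names = [d[0] for d in conn.DIRECTIONS]
        assert np.allclose(acc[names.index("E")], acc[names.index("W")], equal_nan=True)


class TestBuildTransitionGraph:
    def test_single_direction_gives_conductance_one_cost_one(self):
        acc = np.zeros((8, 3, 3))
        acc[0] = 8.0  # all flow east
        mask = np.ones((3, 3), bool)
        g = conn.build_transition_graph(acc, mask)
        i = g.node_index[(1, 1)]
        j = g.node_index[(1, 2)]
        assert g.conductance[i, j] == pytest.approx(1.0)
        assert g.costs[i, j] == pytest.approx(1.0)

    def test_two_equal_directions_closed_form(self):
        acc = np.zeros((8, 3, 3))
        acc[0] = 3.0  # east
        acc[2] = 3.0  # north
        g = conn.build_transition_graph(acc, np.ones((3, 3), bool))
        i = g.node_index[(1, 1)]
        assert g.conductance[i, g.node_index[(1, 2)]] == pytest.approx(0.5)
        assert g.costs[i, g.node_index[(1, 2)]] == pytest.approx(4.0)
        assert g.costs[i, g.node_index[(0, 1)]] == pytest.approx(4.0)

    def test_matches_brute_force_construction(self):
        rng = np.random.default_rng(31)
        acc = rng.uniform(0, 1, (8, 3, 3))
        acc[:, 0, 0] = 0.0
        mask = np.ones((3, 3), bool)
        mask[2, 2] = False
        g = conn.build_transition_graph(acc, mask)
        # brute force: normalise over all 8 physical directions, then drop
        # invalid targets
        expected = {}
        for d, (_, dr, dc, _) in enumerate(conn.DIRECTIONS):
            for r in range(3):
                for c in range(3):
                    if not mask[r, c]:
                        continue
                    total = acc[:, r, c].sum()
                    if total <= 0 or acc[d, r, c] <= 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < 3 and 0 <= c2 < 3) or not mask[r2, c2]:
                        continue
                    cond = acc[d, r, c] / total
                    expected[((r, c), (r2, c2))] = 1.0 / cond**2
        tab = g.edge_table()
        got = {((a, b), (c, d)): w for a, b, c, d, _, w in
               tab[["from_row", "from_col", "to_row", "to_col", "conductance", "cost"]].itertuples(index=False)}
        assert set(got) == set(expected)
        for k in expected:
            assert got[k] == pytest.approx(expected[k], rel=1e-12)

    def test_conductances_sum_to_one_interior(self):
        """Away from coasts and borders, outgoing conductances of a pixel
        with flow sum to 1."""
        rng = np.random.default_rng(32)
        acc = rng.uniform(0.1, 1, (8, 5, 5))
        g = conn.build_transition_graph(acc, np.ones((5, 5), bool))
        i = g.node_index[(2, 2)]
        assert g.conductance[i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_accumulators_rejected(self):
        acc = -np.ones((8, 3, 3))
        with pytest.raises(ValueError, match="nonnegative"):
            conn.build_transition_graph(acc, np.ones((3, 3), bool))


class TestLeastCost:
    def test_single_edge_distance(self):
        acc = np.zeros((8, 2, 3))
        acc[0] = 2.0
        g = conn.build_transition_graph(acc, np.ones((2, 3), bool))
        d = conn.least_cost(g, [g.node_index[(0, 0)]], [g.node_index[(0, 1)]])
        assert d[0, 0] == pytest.approx(1.0)  # conductance 1 -> cost 1

    def test_uniform_eastward_field_asymmetric(self):
        cfg = SeascapeConfig(rows=3, cols=3, n_days=5, current_direction=(1.0, 0.0),
                             current_noise_sd=0.05, land_blocks=(), seed=3,
                             sites=((1, 0, 1), (1, 2, 1)))
        u, v = generate_currents(cfg)
        acc = conn.accumulate_directional_speed(u, v)
        g = conn.build_transition_graph(acc, u.mask)
        w, e = g.node_index[(1, 0)], g.node_index[(1, 2)]
        d = conn.least_cost(g, [w, e])
        assert d[0, 1] < d[1, 0]  # downstream cheaper than upstream

    @pytest.mark.parametrize("shape", [(2, 2), (3, 3), (4, 4)])
    def test_dijkstra_equals_exhaustive_enumeration(self, shape):
        """Exact agreement with brute-force enumeration of all simple
        paths for every ordered node pair on small grids."""
        import networkx as nx

        rng = np.random.default_rng(sum(shape))
        acc = rng.uniform(0, 1, (8,) + shape)
        acc[:, rng.random(shape) < 0.2] = 0.0
        mask = np.ones(shape, bool)
        g = conn.build_transition_graph(acc, mask)
        nxg = g.to_networkx()
        nodes = [tuple(n) for n in g.nodes]
        idx = list(range(len(nodes)))
        d = conn.least_cost(g, idx, idx)
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                if i == j:
                    assert d[i, j] == 0
                    continue
                best = np.inf
                for path in nx.all_simple_paths(nxg, a, b):
                    cost = sum(nxg[u][v]["cost"] for u, v in zip(path, path[1:]))
                    best = min(best, cost)
                assert d[i, j] == pytest.approx(best) or (np.isinf(d[i, j]) and np.isinf(best))

    def test_unreachable_pair_is_inf(self):
        acc = np.zeros((8, 2, 3))
        acc[0] = 1.0  # only eastward edges
        g = conn.build_transition_graph(acc, np.ones((2, 3), bool))
        d = conn.least_cost(g, [g.node_index[(0, 2)]], [g.node_index[(0, 0)]])
        assert np.isinf(d[0, 0])


class TestMapPointsToNodes:
    def test_land_point_maps_to_nearest_sea_pixel(self):
        mask = np.ones((4, 4), bool)
        mask[1, 1] = False
        acc = np.ones((8, 4, 4))
        g = conn.build_transition_graph(acc, mask)
        nodes = conn.map_points_to_nodes(g, [(1, 1)])
        r, c = g.nodes[nodes[0]]
        assert max(abs(r - 1), abs(c - 1)) == 1

    def test_far_point_rejected(self):
        mask = np.zeros((6, 6), bool)
        mask[0, 0] = True
        acc = np.ones((8, 6, 6))
        g = conn.build_transition_graph(acc, mask)
        with pytest.raises(ValueError, match="no sea pixel"):
            conn.map_points_to_nodes(g, [(5, 5)], max_cells=2)


class TestConnectivityModel:
    def test_exact_linear_data_gives_r2_one(self):
        d = np.array([1.0, 2, 3, 4, 5])
        fst = 0.01 + 0.002 * d
        m = conn.fit_connectivity_model(fst, d)
        assert m.r2 == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.01)
        assert m.slope == pytest.approx(0.002)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(33)
        d = rng.uniform(0, 100, 5)
        fst = 0.01 + 3e-4 * d + rng.normal(0, 0.005, 5)
        m = conn.fit_connectivity_model(fst, d)
        X = np.column_stack([np.ones(5), d])
        beta = np.linalg.solve(X.T @ X, X.T @ fst)
        assert m.intercept == pytest.approx(beta[0], abs=1e-12)
        assert m.slope == pytest.approx(beta[1], abs=1e-12)

    def test_aic_matches_full_gaussian_loglik_convention(self):
        """AIC = -2 ll + 2k with k = 3 (intercept, slope, residual
        variance), ll the Gaussian log-likelihood at the MLE variance."""
        rng = np.random.default_rng(34)
        d = rng.uniform(0, 10, 12)
        fst = 0.02 + 0.003 * d + rng.normal(0, 0.004, 12)
        m = conn.fit_connectivity_model(fst, d)
        X = np.column_stack([np.ones(12), d])
        beta = np.linalg.lstsq(X, fst, rcond=None)[0]
        resid = fst - X @ beta
        n = 12
        s2 = (resid**2).mean()
        ll = -n / 2 * (np.log(2 * np.pi * s2) + 1)
        assert m.aic == pytest.approx(-2 * ll + 6, rel=1e-12)

    def test_zero_variance_distance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            conn.fit_connectivity_model(np.array([0.1, 0.2, 0.3]), np.ones(3))

    def test_slope_recovery_within_two_ses(self):
        """FST = a + b d + N(0, s): the slope is recovered within 2 SEs in
        at least 93/100 seeds (the nominal ~95% interval coverage)."""
        a, b, sigma = 0.01, 2e-4, 0.004
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = rng.uniform(0, 100, 100)  # reef-grid-scale pair count
            fst = a + b * d + rng.normal(0, sigma, 100)
            m = conn.fit_connectivity_model(fst, d)
            if abs(m.slope - b) <= 2 * m.se_slope:
                hits += 1
        assert hits >= 93


class TestPredictDfst:
    def test_zero_slope_constant_off_diagonal(self):
        m = conn.ConnectivityModel(0.03, 0.0, 1.0, 0.0, 5, "least-cost")
        out = conn.predict_dfst(m, np.ones((4, 4)))
        assert np.allclose(out[~np.eye(4, dtype=bool)], 0.03)
        assert np.allclose(np.diag(out), 0.0)

    def test_zero_distance_off_diagonal_gives_intercept(self):
        m = conn.ConnectivityModel(0.02, 5.0, 1.0, 0.0, 5, "least-cost")
        d = np.zeros((3, 3))
        out = conn.predict_dfst(m, d)
        assert out[0, 1] == pytest.approx(0.02)

    def test_matrix_hand_evaluation_and_negative_floor(self):
        m = conn.ConnectivityModel(-0.01, 0.001, 1.0, 0.0, 5, "least-cost")
        d = np.array([[0.0, 5.0], [20.0, 0.0]])
        out = conn.predict_dfst(m, d)
        assert out[0, 1] == pytest.approx(0.0)  # -0.01 + 0.005 < 0 floored
        assert out[1, 0] == pytest.approx(0.01)


class TestDistanceMatrixProperties:
    def test_dominant_current_makes_downstream_cheaper_on_average(self):
        cfg = SeascapeConfig(rows=12, cols=12, n_days=30, land_blocks=(), seed=5,
                             sites=tuple((r, c, 1) for r, c in
                                         [(2, 2), (2, 9), (9, 2), (9, 9), (5, 5)]))
        u, v = generate_currents(cfg)
        acc = conn.accumulate_directional_speed(u, v)
        g = conn.build_transition_graph(acc, u.mask)
        sites = cfg.site_table()
        nodes = conn.map_points_to_nodes(g, list(zip(sites["row"], sites["col"])))
        d = conn.least_cost(g, nodes)
        # direction (1, 0.35): eastward flow; columns increase eastward
        cols = sites["col"].to_numpy()
        down, up = [], []
        for i, j in itertools.permutations(range(len(nodes)), 2):
            if cols[j] > cols[i]:
                down.append(d[i, j])
            elif cols[j] < cols[i]:
                up.append(d[i, j])
        assert np.mean(down) < np.mean(up)

    def test_collapse_options(self):
        d = np.array([[0.0, 2.0], [6.0, 0.0]])
        assert np.allclose(conn.collapse_directed(d, "min"), [[0, 2], [2, 0]])
        assert np.allclose(conn.collapse_directed(d, "mean"), [[0, 4], [4, 0]])
        with pytest.raises(ValueError):
            conn.collapse_directed(d, "max")


class TestOptions:
    def test_binning_assigns_full_speed_to_nearest_direction(self):
        u, v = series_pair(np.full((4, 3, 3), 0.5), np.zeros((4, 3, 3)))
        acc = conn.accumulate_directional_speed(u, v, method="binning")
        names = [d[0] for d in conn.DIRECTIONS]
        assert acc[names.index("E"), 1, 1] == pytest.approx(2.0)
        assert np.nansum(acc[:, 1, 1]) == pytest.approx(2.0)  # nothing leaks sideways

    def test_diagonal_scaling_multiplies_diagonal_costs(self):
        acc = np.zeros((8, 3, 3))
        acc[0] = 1.0  # E
        acc[1] = 1.0  # NE
        mask = np.ones((3, 3), bool)
        plain = conn.build_transition_graph(acc, mask)
        scaled = conn.build_transition_graph(acc, mask, diagonal_scaling=True)
        i = plain.node_index[(1, 1)]
        e, ne = plain.node_index[(1, 2)], plain.node_index[(0, 2)]
        assert scaled.costs[i, e] == pytest.approx(plain.costs[i, e])
        assert scaled.costs[i, ne] == pytest.approx(plain.costs[i, ne] * np.sqrt(2))
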