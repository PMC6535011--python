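import numpy as np
import pytest

from adaptscape.connect import (
    ResistanceSurface,
    build_graph,
    combine_surfaces,
    current_density,
    effective_resistance,
    graph_from_edges,
    ibr_regression,
    mantel_test,
    rank_surfaces,
    reclassify_to_resistance,
    rescue_potential,
)
from adaptscape.rasters import Raster


def pinv_resistance_oracle(n, edges, conductances):
    """Effective resistance via the dense Laplacian Moore-Penrose pseudoinverse."""
    L = np.zeros((n, n))
    for (i, j), g in zip(edges, conductances):
        L[i, i] += g
        L[j, j] += g
        L[i, j] -= g
        L[j, i] -= g
    Lp = np.linalg.pinv(L, hermitian=True)
    R = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            R[i, j] = Lp[i, i] + Lp[j, j] - 2 * Lp[i, j]
    return R


class TestReclassification:
    def test_single_class_uniform_surface(self, checker_raster):
        surf = reclassify_to_resistance(checker_raster, [(0.0, 1.0)])
        vals = surf.raster.valid_values()
        assert (vals == 1.0).all()

    def test_linear_interpolation_midpoint(self):
        layer = Raster(np.array([[0.0, 50.0, 100.0]]))
        surf = reclassify_to_resistance(
            layer, [(0.0, 100.0), (100.0, 1.0)], interpolate=True
        )
        np.testing.assert_allclose(surf.raster.values[0], [100.0, 50.5, 1.0])

    def test_out_of_range_cost_rejected(self, checker_raster):
        with pytest.raises(ValueError):
            reclassify_to_resistance(checker_raster, [(0.0, 200.0)])

    def test_nodata_propagates(self, checker_raster):
        surf = reclassify_to_resistance(checker_raster, [(0.0, 5.0)])
        assert not surf.raster.valid_mask[2, 3]


class TestCombination:
    def _const(self, value, shape=(4, 4)):
        return ResistanceSurface(Raster(np.full(shape, value)))

    def test_mean_of_identical_is_identity(self):
        s = self._const(42.0)
        out = combine_surfaces([s, s], method="mean")
        np.testing.assert_allclose(out.raster.values, 42.0)

    def test_mean_of_extremes(self):
        out = combine_surfaces([self._const(1.0), self._const(100.0)], method="mean")
        np.testing.assert_allclose(out.raster.values, 50.5)

    def test_product_rescaled_spans_range(self):
        rng = np.random.default_rng(0)
        a = ResistanceSurface(Raster(rng.uniform(1, 100, (6, 6))))
        b = ResistanceSurface(Raster(rng.uniform(1, 100, (6, 6))))
        out = combine_surfaces([a, b], method="product_rescaled")
        vals = out.raster.valid_values()
        assert vals.min() == pytest.approx(1.0)
        assert vals.max() == pytest.approx(100.0)

    def test_constant_product_maps_to_midpoint(self):
        out = combine_surfaces([self._const(7.0), self._const(7.0)], method="product_rescaled")
        np.testing.assert_allclose(out.raster.values, 50.5)


class TestGraph:
    def test_uniform_cost_conductances(self):
        surf = ResistanceSurface(Raster(np.full((3, 3), 4.0)))
        graph = build_graph(surf, connectivity=8)
        # orthogonal neighbors: mean conductance = 1/4; diagonal: /sqrt(2)
        uniq = np.unique(np.round(graph.conductances, 12))
        np.testing.assert_allclose(
            uniq, sorted([0.25 / np.sqrt(2), 0.25]), atol=1e-12
        )

    def test_four_neighborhood_has_no_diagonals(self):
        surf = ResistanceSurface(Raster(np.full((3, 3), 2.0)))
        graph = build_graph(surf, connectivity=4)
        assert np.allclose(graph.conductances, 0.5)
        assert graph.edges.shape[0] == 12

    def test_nodata_cell_isolated(self):
        values = np.full((3, 3), 2.0)
        values[1, 1] = -9999.0
        surf = ResistanceSurface(Raster(values))
        graph = build_graph(surf)
        assert graph.n_nodes == 8
        assert -1 == graph.node_of_cell[1, 1]


class TestEffectiveResistance:
    def test_single_edge_ohms_law(self):
        graph = graph_from_edges(2, [(0, 1)], [1.0 / 7.0])  # resistance 7
        R = effective_resistance(graph, [0, 1])
        assert R.values[0, 1] == pytest.approx(7.0)

    def test_series_chain(self):
        k = 6
        edges = [(i, i + 1) for i in range(k)]
        graph = graph_from_edges(k + 1, edges, np.ones(k))
        R = effective_resistance(graph, [0, k])
        assert R.values[0, 1] == pytest.approx(k)

    def test_parallel_edges(self):
        # two unit-resistance paths in parallel via duplicate edge
        graph = graph_from_edges(2, [(0, 1), (0, 1)], [1.0, 1.0])
        R = effective_resistance(graph, [0, 1])
        assert R.values[0, 1] == pytest.approx(0.5)

    def test_matches_pseudoinverse_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            n = int(rng.integers(10, 100))
            # random connected graph: spanning chain + extra random edges
            edges = [(i, i + 1) for i in range(n - 1)]
            extra = rng.integers(0, n, size=(n, 2))
            edges += [(int(a), int(b)) for a, b in extra if a != b]
            conds = rng.uniform(0.1, 5.0, len(edges))
            graph = graph_from_edges(n, np.array(edges), conds)
            focal = rng.choice(n, size=5, replace=False).tolist()
            R = effective_resistance(graph, focal)
            oracle = pinv_resistance_oracle(n, edges, conds)
            for a in range(5):
                for b in range(5):
                    assert R.values[a, b] == pytest.approx(
                        oracle[focal[a], focal[b]], abs=1e-8
                    )

    def test_resistance_is_a_metric(self):
        rng = np.random.default_rng(2)
        n = 30
        edges = [(i, i + 1) for i in range(n - 1)]
        edges += [(int(a), int(b)) for a, b in rng.integers(0, n, (40, 2)) if a != b]
        graph = graph_from_edges(n, np.array(edges), rng.uniform(0.2, 3.0, len(edges)))
        focal = list(range(0, n, 5))
        R = effective_resistance(graph, focal).values
        np.testing.assert_allclose(R, R.T, atol=1e-10)
        k = len(focal)
        for i in range(k):
            for j in range(k):
                for m in range(k):
                    assert R[i, j] <= R[i, m] + R[m, j] + 1e-9

    def test_disconnected_pair_infinite_with_warning(self):
        graph = graph_from_edges(4, [(0, 1), (2, 3)], [1.0, 1.0])
        with pytest.warns(UserWarning, match="disconnected"):
            R = effective_resistance(graph, [0, 2])
        assert np.isinf(R.values[0, 1])

    def test_rayleigh_monotonicity_on_landscapes(self):
        from adaptscape.synthio import LandscapeConfig, generate_climate_rasters

        rng = np.random.default_rng(3)
        for seed in range(10):
            config = LandscapeConfig(
                grid_rows=10, grid_cols=10, autocorrelation_range=2, seed=seed
            )
            layer = generate_climate_rasters(config, n_layers=1)["clim1"]
            surf = reclassify_to_resistance(
                layer, [(-3.0, 1.0), (0.0, 30.0), (2.0, 80.0)]
            )
            graph = build_graph(surf)
            focal = rng.choice(graph.n_nodes, 4, replace=False).tolist()
            R0 = effective_resistance(graph, focal).values
            # raise one random cell's cost to the maximum
            values = surf.raster.values.copy()
            r, c = rng.integers(0, 10, 2)
            values[r, c] = 100.0
            graph2 = build_graph(ResistanceSurface(surf.raster.copy_with(values)))
            R1 = effective_resistance(graph2, focal).values
            assert (R1 - R0 >= -1e-9).all()


class TestCurrentDensity:
    def test_chain_interior_carries_unit_current(self):
        k = 5
        graph = graph_from_edges(k, [(i, i + 1) for i in range(k - 1)], np.ones(k - 1))
        cmap = current_density(graph, [0], [k - 1])
        interior = cmap.raster.values[0, 1 : k - 1]
        np.testing.assert_allclose(interior, 1.0, atol=1e-10)

    def test_two_path_split_proportional_to_conductance(self):
        # node 0 -> {1 (g=2), 2 (g=1)} -> 3, Kirchhoff: currents 2/3 and 1/3
        edges = [(0, 1), (1, 3), (0, 2), (2, 3)]
        conds = [2.0, 2.0, 1.0, 1.0]
        graph = graph_from_edges(4, edges, conds)
        cmap = current_density(graph, [0], [3])
        assert cmap.raster.values[0, 1] == pytest.approx(2 / 3)
        assert cmap.raster.values[0, 2] == pytest.approx(1 / 3)

    def test_source_injection_balances_target_extraction(self):
        rng = np.random.default_rng(4)
        n = 20
        edges = [(i, i + 1) for i in range(n - 1)]
        edges += [(int(a), int(b)) for a, b in rng.integers(0, n, (15, 2)) if a != b]
        graph = graph_from_edges(n, np.array(edges), rng.uniform(0.5, 2.0, len(edges)))
        cmap = current_density(graph, [0], [n - 1])
        # source and target each carry half the absolute incident current
        assert cmap.raster.values[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert cmap.raster.values[0, n - 1] == pytest.approx(0.5, abs=1e-9)

    def test_self_pairs_skipped(self):
        graph = graph_from_edges(3, [(0, 1), (1, 2)], [1.0, 1.0])
        cmap = current_density(graph, [0, 2], [0, 2])
        # only the 0->2 and 2->0 pairs contribute
        assert cmap.raster.values[0, 1] == pytest.approx(2.0)


class TestIbrRegression:
    def test_noise_free_perfect_fit(self):
        rng = np.random.default_rng(5)
        R = np.abs(rng.normal(size=(12, 12)))
        R = R + R.T
        np.fill_diagonal(R, 0.0)
        res = ibr_regression(2.0 * R, R, n_perm=99, seed=6)
        assert res.mantel_r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_mantel_null_p_calibrated(self):
        """Under independence the Mantel rejection rate stays near the
        nominal level (bound = upper 99.9% binomial envelope)."""
        rng = np.random.default_rng(7)
        rejections = 0
        trials = 200
        for _ in range(trials):
            A = np.abs(rng.normal(size=(15, 15)))
            A = A + A.T
            np.fill_diagonal(A, 0)
            B = np.abs(rng.normal(size=(15, 15)))
            B = B + B.T
            np.fill_diagonal(B, 0)
            _, p = mantel_test(A, B, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert rejections / trials <= 0.10

    def test_rank_surfaces_orders_by_r_squared(self):
        rng = np.random.default_rng(8)
        true = np.abs(rng.normal(size=(10, 10)))
        true = true + true.T
        np.fill_diagonal(true, 0)
        noise = np.abs(rng.normal(size=(10, 10)))
        noise = noise + noise.T
        np.fill_diagonal(noise, 0)
        genetic = 3.0 * true
        ranked = rank_surfaces(genetic, {"noise": noise, "true": true}, n_perm=49, seed=9)
        assert ranked[0].surface == "true"
        assert ranked[0].r_squared >= ranked[1].r_squared


class TestRescuePotential:
    def _uniform_surface(self, shape=(8, 8), cost=10.0):
        return ResistanceSurface(Raster(np.full(shape, cost)))

    def test_adjacent_target_has_lowest_resistance(self):
        surf = self._uniform_surface()
        cmap, summary = rescue_potential(
            surf, [(4, 4)], [(4, 5), (0, 0), (7, 7)],
            target_ids=["near", "far1", "far2"],
        )
        assert summary["near"] < summary["far1"]
        assert summary["near"] < summary["far2"]

    def test_cost_wall_raises_resistance(self):
        base = np.full((9, 9), 1.0)
        walled = base.copy()
        walled[:, 4] = 100.0
        open_surface = ResistanceSurface(Raster(base))
        wall_surface = ResistanceSurface(Raster(walled))
        _, open_summary = rescue_potential(open_surface, [(4, 0)], [(4, 8)])
        _, wall_summary = rescue_potential(wall_surface, [(4, 0)], [(4, 8)])
        assert wall_summary["tgt0"] > open_summary["tgt0"]

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError, match="hot_dry"):
            rescue_potential(self._uniform_surface(), [], [(0, 0)])

    def test_shared_source_target_cells_handled(self):
        surf = self._uniform_surface()
        cmap, summary = rescue_potential(surf, [(2, 2)], [(2, 2), (5, 5)])
        assert summary["tgt0"] == 0.0
        assert summary["tgt1"] > 0.0
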