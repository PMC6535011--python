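import numpy as np
import pytest

from adaptscape.enm import (
    OccurrenceSet,
    build_ensemble,
    clean_occurrences,
    combine_ranges,
    cross_validate,
    fit_envelope,
    fit_logistic,
    fit_maxent_like,
    max_tss,
    niche_similarity_test,
    null_model_test,
    project,
    range_change,
    range_overlap,
    rank_auc,
    remove_correlated_variables,
    sample_background,
    schoener_d,
)
from adaptscape.rasters import Raster, RasterStack


class TestOccurrenceCleaning:
    def test_snap_dedupe_and_drop_outside(self, gradient_stack):
        pts = np.array([[0.2, 0.7], [0.4, 0.6], [100.0, 100.0], [3.5, 3.5]])
        occ = clean_occurrences(OccurrenceSet(pts), gradient_stack)
        assert occ.n == 2  # first two share a cell; third is outside
        # snapped to cell centers (half offsets)
        assert np.allclose(occ.coordinates % 1.0, 0.5)


class TestVariableScreening:
    def test_duplicate_layer_dropped(self, gradient_stack):
        stack = RasterStack(dict(gradient_stack.layers))
        stack.add("dup", gradient_stack["clim1"].copy_with(gradient_stack["clim1"].values))
        out = remove_correlated_variables(stack, r_threshold=0.75)
        assert len(out) < 3

    def test_independent_layers_kept(self):
        rng = np.random.default_rng(0)
        stack = RasterStack(
            {f"v{k}": Raster(rng.standard_normal((10, 10))) for k in range(3)}
        )
        out = remove_correlated_variables(stack, r_threshold=0.75)
        assert out.names == ["v0", "v1", "v2"]

    def test_mean_correlation_rule_picks_victim(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((20, 20))
        b = a + 0.1 * rng.standard_normal((20, 20))     # r(A,B) ~ 0.995
        c = 0.25 * a + rng.standard_normal((20, 20))    # r(A,C) modest
        stack = RasterStack({"A": Raster(a), "B": Raster(b), "C": Raster(c)})
        out = remove_correlated_variables(stack, r_threshold=0.75)
        # A has the larger mean |r| (correlated with both B and C) -> dropped
        assert set(out.names) == {"B", "C"}


class TestBackground:
    def test_requesting_too_many_cells_errors(self, gradient_stack):
        with pytest.raises(ValueError):
            sample_background(gradient_stack, 10_000, seed=0)

    def test_no_overlap_with_presences(self, gradient_stack):
        occ = clean_occurrences(
            OccurrenceSet(np.column_stack([np.arange(10) + 0.5, np.arange(10) + 0.5])),
            gradient_stack,
        )
        rows, cols = sample_background(gradient_stack, 200, seed=1, exclusion=occ)
        presence = set(zip(occ.rows, occ.cols))
        assert not presence & set(zip(rows, cols))

    def test_deterministic_per_seed(self, gradient_stack):
        a = sample_background(gradient_stack, 50, seed=2)
        b = sample_background(gradient_stack, 50, seed=2)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestMembers:
    def test_envelope_median_point_fully_suitable(self):
        rng = np.random.default_rng(3)
        P = rng.standard_normal((100, 3))
        model = fit_envelope(P, percentile=0.05)
        median = np.median(P, axis=0, keepdims=True)
        assert model.predict_env(median)[0] == 1.0

    def test_envelope_outside_all_variables_zero(self):
        model = fit_envelope(np.zeros((10, 2)) + [[0.0, 0.0]])
        assert model.predict_env(np.array([[99.0, 99.0]]))[0] == 0.0

    def test_envelope_partial_overlap_half(self):
        P = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 1, 20)])
        model = fit_envelope(P, percentile=0.0)
        assert model.predict_env(np.array([[0.5, 99.0]]))[0] == 0.5

    def test_logistic_separable_training_auc_one(self):
        P = np.full((20, 1), 2.0) + np.random.default_rng(4).normal(0, 0.1, (20, 1))
        B = np.full((50, 1), -2.0) + np.random.default_rng(5).normal(0, 0.1, (50, 1))
        model = fit_logistic(P, B)
        assert rank_auc(model.predict_env(P), model.predict_env(B)) == 1.0

    def test_logistic_missing_class_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((5, 1)), np.zeros((0, 1)))

    def test_logistic_mirrored_classes_give_flat_model(self):
        # presences and background occupy identical env values: no signal,
        # so the fitted probability is the prevalence everywhere
        pts = np.array([[-1.0], [1.0]])
        model = fit_logistic(pts, pts)
        np.testing.assert_allclose(
            model.predict_env(np.array([[-1.0], [0.0], [1.0]])), 0.5, atol=1e-6
        )

    def test_maxent_infinite_penalty_uniform(self):
        rng = np.random.default_rng(6)
        P = rng.standard_normal((30, 2))
        B = rng.standard_normal((100, 2))
        model = fit_maxent_like(P, B, l1_penalty=1e6)
        suit = model.predict_env(rng.standard_normal((50, 2)))
        np.testing.assert_allclose(suit, suit[0], atol=1e-8)

    def test_maxent_zero_penalty_matches_logistic_features(self):
        rng = np.random.default_rng(7)
        P = rng.standard_normal((60, 2)) + 0.8
        B = rng.standard_normal((200, 2))
        mx = fit_maxent_like(P, B, l1_penalty=0.0)
        lg = fit_logistic(P, B, interactions=True)
        assert np.max(np.abs(mx.coefficients - lg.coefficients)) < 1e-4

    def test_maxent_suitability_monotone_along_presence_gradient(self, gradient_stack):
        # presences cluster at the hot (east) end
        rng = np.random.default_rng(8)
        cols = rng.integers(12, 16, 40)
        rows = rng.integers(0, 16, 40)
        P = gradient_stack.env_at_rowcol(rows, cols)
        brows, bcols = sample_background(gradient_stack, 150, seed=9)
        B = gradient_stack.env_at_rowcol(brows, bcols)
        model = fit_maxent_like(P, B)
        grid = np.column_stack([np.linspace(-1.5, 1.5, 7), np.zeros(7)])
        suit = model.predict_env(grid)
        assert suit[-1] > suit[0]

    def test_maxent_single_presence_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent_like(np.zeros((1, 2)), np.zeros((10, 2)))


class TestEvaluation:
    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        pos, neg = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        assert rank_auc(pos, neg) == pytest.approx(
            rank_auc(np.tanh(pos), np.tanh(neg)), abs=1e-12
        )

    def test_tss_identity_at_threshold(self):
        pos = np.array([0.9, 0.8, 0.7, 0.2])
        neg = np.array([0.1, 0.3, 0.6, 0.4])
        tss, thr = max_tss(pos, neg)
        sens = (pos >= thr).mean()
        spec = (neg < thr).mean()
        assert tss == pytest.approx(sens + spec - 1)

    def test_perfect_separation_auc_tss_one(self):
        rng = np.random.default_rng(11)
        P = np.full((30, 1), 3.0)
        B = np.full((60, 1), -3.0)
        evals = cross_validate(lambda p, b: fit_logistic(p, b), P, B, seed=12)
        assert all(e.auc == 1.0 and e.tss == pytest.approx(1.0) for e in evals)

    def test_shuffled_labels_auc_half(self):
        rng = np.random.default_rng(13)
        pool = rng.standard_normal((400, 2))
        P, B = pool[:150], pool[150:]
        evals = cross_validate(lambda p, b: fit_logistic(p, b), P, B, seed=14)
        assert np.mean([e.auc for e in evals]) == pytest.approx(0.5, abs=0.05)

    def test_low_sample_size_uses_five_replicates(self):
        rng = np.random.default_rng(15)
        P = rng.standard_normal((40, 1)) + 2
        B = rng.standard_normal((100, 1))
        evals = cross_validate(lambda p, b: fit_logistic(p, b), P, B, seed=16)
        assert len(evals) == 5
        evals = cross_validate(
            lambda p, b: fit_logistic(p, b), np.vstack([P, P]), B, seed=16
        )
        assert len(evals) == 10


class TestEnsemble:
    class _Const:
        algorithm = "const"

        def __init__(self, value):
            self.value = value

        def predict_env(self, X):
            return np.full(np.atleast_2d(X).shape[0], self.value)

    def test_weights_proportional_to_tss(self):
        P, B = np.zeros((10, 1)), np.ones((10, 1))
        ens = build_ensemble(
            [(self._Const(0.9), 0.8), (self._Const(0.1), 0.4)], P, B
        )
        assert [round(m.weight, 6) for m in ens.members] == [
            round(2 / 3, 6),
            round(1 / 3, 6),
        ]

    def test_single_member_full_weight(self):
        ens = build_ensemble([(self._Const(0.5), 0.9)], np.zeros((5, 1)), np.ones((5, 1)))
        assert ens.members[0].weight == 1.0

    def test_below_cutoff_member_excluded(self):
        ens = build_ensemble(
            [(self._Const(0.9), 0.8), (self._Const(0.5), 0.2)],
            np.zeros((5, 1)),
            np.ones((5, 1)),
        )
        assert len(ens.members) == 1

    def test_no_passing_member_reports_best(self):
        with pytest.raises(ValueError, match="0.300"):
            build_ensemble([(self._Const(0.5), 0.3)], np.zeros((5, 1)), np.ones((5, 1)))


class TestProjection:
    def _ensemble_on(self, stack, seed=0):
        from adaptscape.enm import fit_ensemble_enm

        rng = np.random.default_rng(seed)
        cols = rng.integers(10, 16, 40)
        rows = rng.integers(0, 16, 40)
        x, y = stack.template.rowcol_to_xy(rows, cols)
        occ = clean_occurrences(OccurrenceSet(np.column_stack([x, y])), stack)
        return fit_ensemble_enm(stack, occ, seed=seed, n_background=150)

    def test_future_equals_present_preserves_range(self, gradient_stack):
        ens = self._ensemble_on(gradient_stack)
        present = ens.binarize(ens.predict_raster(gradient_stack))
        _, future = project(ens, [gradient_stack])
        np.testing.assert_array_equal(present.values, future.values)

    def test_identical_stacks_equal_single_prediction(self, gradient_stack):
        ens = self._ensemble_on(gradient_stack)
        single, _ = project(ens, [gradient_stack])
        triple, _ = project(ens, [gradient_stack] * 3)
        np.testing.assert_allclose(single.values, triple.values, atol=1e-12)

    def test_mean_across_stacks_is_hand_average(self, gradient_stack):
        from adaptscape.synthio import generate_future_rasters

        ens = self._ensemble_on(gradient_stack)
        futures = [generate_future_rasters(gradient_stack, d) for d in (0.5, 1.0, 1.5)]
        merged, _ = project(ens, futures)
        hand = np.mean(
            [ens.predict_raster(f).values for f in futures], axis=0
        )
        np.testing.assert_allclose(merged.values, hand, atol=1e-12)


class TestRangeArithmetic:
    def test_range_change_percentages(self, make_binary_raster):
        mask = make_binary_raster(10_000)
        present = make_binary_raster(4682)
        future = make_binary_raster(4950)
        report = range_change(present, future, mask)
        assert report.percent_present == pytest.approx(46.82)
        assert report.percent_future == pytest.approx(49.50)
        assert round(report.percent_change, 2) == 5.72

    def test_no_change_zero_percent(self, make_binary_raster):
        mask = make_binary_raster(10_000)
        b = make_binary_raster(2500)
        assert range_change(b, b, mask).percent_change == 0.0

    def test_union_area_at_least_max(self, make_binary_raster):
        a = make_binary_raster(3000)
        flat = np.zeros(10_000)
        flat[2000:5000] = 1.0
        b = Raster(flat.reshape(100, 100))
        union = combine_ranges(a, b)
        assert (union.values > 0).sum() >= max(3000, 3000)
        assert (union.values > 0).sum() == 5000  # overlap counted once

    def test_disjoint_ranges_sum(self, make_binary_raster):
        a = make_binary_raster(1000)
        flat = np.zeros(10_000)
        flat[1000:1800] = 1.0
        b = Raster(flat.reshape(100, 100))
        assert (combine_ranges(a, b).values > 0).sum() == 1800

    def test_overlap_nested_equals_smaller(self, make_binary_raster):
        mask = make_binary_raster(10_000)
        small, large = make_binary_raster(1000), make_binary_raster(4000)
        assert range_overlap(small, large, mask) == pytest.approx(10.0)

    def test_overlap_disjoint_zero(self, make_binary_raster):
        a = make_binary_raster(1000)
        flat = np.zeros(10_000)
        flat[5000:] = 1.0
        assert range_overlap(a, Raster(flat.reshape(100, 100)), make_binary_raster(10_000)) == 0.0


class TestNicheOverlap:
    def test_identical_surfaces_d_one(self, gradient_stack):
        s = gradient_stack["clim1"].copy_with(np.abs(gradient_stack["clim1"].values))
        assert schoener_d(s, s).d == pytest.approx(1.0)

    def test_disjoint_supports_d_zero(self):
        a = Raster(np.array([[1.0, 0.0], [1.0, 0.0]]))
        b = Raster(np.array([[0.0, 1.0], [0.0, 1.0]]))
        assert schoener_d(a, b).d == pytest.approx(0.0)

    def test_two_cell_example(self):
        a = Raster(np.array([[1.0, 0.0]]))
        b = Raster(np.array([[0.5, 0.5]]))
        assert schoener_d(a, b).d == pytest.approx(0.5)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(17)
        a = Raster(rng.uniform(0, 1, (8, 8)))
        b = Raster(rng.uniform(0, 1, (8, 8)))
        assert schoener_d(a, b).d == pytest.approx(
            schoener_d(a.copy_with(7.3 * a.values), b).d
        )

    def test_symmetry(self):
        rng = np.random.default_rng(18)
        a = Raster(rng.uniform(0, 1, (8, 8)))
        b = Raster(rng.uniform(0, 1, (8, 8)))
        assert schoener_d(a, b).d == pytest.approx(schoener_d(b, a).d)


class TestNicheSimilarityTest:
    def test_identical_occurrences_not_rejected(self, gradient_stack):
        rng = np.random.default_rng(19)
        rows = rng.integers(0, 16, 25)
        cols = rng.integers(0, 16, 25)
        x, y = gradient_stack.template.rowcol_to_xy(rows, cols)
        occ = clean_occurrences(OccurrenceSet(np.column_stack([x, y])), gradient_stack)
        report = niche_similarity_test(occ, occ, gradient_stack, n_perm=49, seed=20)
        assert report.p_lower > 0.05

    def test_opposite_gradient_groups_rejected(self, gradient_stack):
        rng = np.random.default_rng(21)
        east = np.column_stack([rng.integers(0, 16, 25), rng.integers(12, 16, 25)])
        west = np.column_stack([rng.integers(0, 16, 25), rng.integers(0, 4, 25)])
        def occ_of(cells):
            x, y = gradient_stack.template.rowcol_to_xy(cells[:, 0], cells[:, 1])
            return clean_occurrences(OccurrenceSet(np.column_stack([x, y])), gradient_stack)
        report = niche_similarity_test(
            occ_of(east), occ_of(west), gradient_stack, n_perm=99, seed=22
        )
        assert report.p_lower <= 0.05

    def test_zero_permutations_rejected(self, gradient_stack):
        occ = OccurrenceSet(np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            niche_similarity_test(occ, occ, gradient_stack, n_perm=0)


class TestNullModel:
    def test_zero_null_replicates_rejected(self, gradient_stack):
        with pytest.raises(ValueError):
            null_model_test(gradient_stack, 0.9, 20, n_null=0)

    def test_strong_model_beats_null_range(self, gradient_stack):
        out = null_model_test(
            gradient_stack, observed_auc=0.93, n_presences=25, n_null=19, seed=23,
            n_background=120,
        )
        assert out["significant"]
        assert out["null_range"][1] < 0.93
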