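"""Imputation, model registry, LOOCV (incl. the exact fast paths), greedy
forward selection, the hourly grid, and Bland-Altman agreement."""

import numpy as np
import pandas as pd
import pytest

from cmsehrv import mlharness as ml


def _random_fm(rng, n=40, p=6, noise=1.0):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    fm = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    fm["lvef_pct"] = X @ beta + noise * rng.standard_normal(n)
    return fm


class TestMetrics:
    def test_identical_vectors_have_zero_error(self):
        assert ml.rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert ml.mae([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_arithmetic_example(self):
        assert ml.rmse([60, 70], [62, 66]) == pytest.approx(np.sqrt(10.0))
        assert ml.mae([60, 70], [62, 66]) == 3.0

    def test_rmse_dominates_mae(self, rng):
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        assert ml.rmse(a, b) >= ml.mae(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ml.rmse([1, 2], [1])


class TestRegistry:
    def test_lists_exactly_the_ten_model_names(self):
        registry = ml.model_registry()
        assert tuple(registry) == ml.MODEL_NAMES
        assert len(registry) == 10

    def test_cnn_reported_unavailable_without_torch(self):
        registry = ml.model_registry()
        assert registry["CNN"].available is False
        with pytest.raises(ml.ModelUnavailableError):
            ml.make_estimator("CNN")

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            ml.make_estimator("Perceptron9000")

    def test_lr_recovers_exact_line(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = 3.0 + 2.0 * X[:, 0]
        est = ml.make_estimator("LR").fit(X, y)
        assert est.predict(X) == pytest.approx(y, abs=1e-10)

    def test_rf_deterministic_under_fixed_seed(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        p1 = ml.make_estimator("RF", seed=3).fit(X, y).predict(X)
        p2 = ml.make_estimator("RF", seed=3).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)


class TestImputation:
    def test_complete_matrix_passes_through_identically(self, rng):
        fm = _random_fm(rng)
        out = ml.impute_missing(fm, seed=0)
        pd.testing.assert_frame_equal(out, fm)

    def test_same_seed_reproduces_the_completion(self, rng):
        # covariate-like columns stay complete, as in the per-hour matrices
        fm = _random_fm(rng, n=60)
        mask = rng.random((60, 5)) < 0.1
        fm.iloc[:, :5] = fm.iloc[:, :5].mask(mask)
        a = ml.impute_missing(fm, seed=4)
        b = ml.impute_missing(fm, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_mcar_holes_recovered_within_column_sd(self):
        rng = np.random.default_rng(0)
        n = 200
        z = rng.standard_normal(n)
        fm = pd.DataFrame({
            "a": z + 0.1 * rng.standard_normal(n),
            "b": z + 0.1 * rng.standard_normal(n),
            "c": z + 0.1 * rng.standard_normal(n),
        })
        fm["lvef_pct"] = rng.standard_normal(n)
        truth = fm["a"].copy()
        holes = rng.random(n) < 0.1
        fm.loc[holes, "a"] = np.nan
        out = ml.impute_missing(fm, seed=1)
        err = np.sqrt(np.mean((out.loc[holes, "a"] - truth[holes]) ** 2))
        assert err < 1.0 * truth.std()

    def test_entirely_missing_column_dropped_with_warning(self, rng):
        fm = _random_fm(rng)
        fm["dead"] = np.nan
        with pytest.warns(UserWarning):
            out = ml.impute_missing(fm, seed=0)
        assert "dead" not in out.columns


class TestLOOCV:
    def test_lr_on_exactly_linear_data_is_perfect(self, linear_fm):
        preds = ml.loocv_predict("LR", linear_fm, ["f3"])
        assert ml.rmse(linear_fm["lvef_pct"], preds) == pytest.approx(
            0.0, abs=1e-8)

    def test_press_identity_matches_per_fold_refits(self, rng):
        fm = _random_fm(rng, n=50, p=10)
        feats = [f"f{i}" for i in range(10)]
        fast = ml.loocv_predict("LR", fm, feats)
        slow = ml.loocv_predict("LR", fm, feats, method="generic")
        assert np.abs(fast - slow).max() < 1e-8

    def test_knn_fast_path_matches_per_fold_refits(self, rng):
        fm = _random_fm(rng, n=45, p=4)
        feats = [f"f{i}" for i in range(4)]
        fast = ml.loocv_predict("KNN", fm, feats)
        slow = ml.loocv_predict("KNN", fm, feats, method="generic")
        assert np.abs(fast - slow).max() < 1e-10

    def test_gpr_virtual_loo_matches_per_fold_refits(self, rng):
        fm = _random_fm(rng, n=45, p=4)
        feats = [f"f{i}" for i in range(4)]
        fast = ml.loocv_predict("GPR", fm, feats)
        slow = ml.loocv_predict("GPR", fm, feats, method="generic")
        assert np.abs(fast - slow).max() < 1e-8

    def test_knn_with_k_equal_n_minus_1_predicts_leave_one_out_mean(self,
                                                                    rng):
        fm = _random_fm(rng, n=20, p=2)
        y = fm["lvef_pct"].to_numpy()
        spec = ml.ModelSpec("KNN", {"n_neighbors": 19})
        preds = ml.loocv_predict(spec, fm, ["f0", "f1"])
        expected = (y.sum() - y) / (y.size - 1)
        assert preds == pytest.approx(expected, abs=1e-10)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            ml.loocv_predict("LR", _random_fm(rng), [])


class TestGreedySelection:
    def test_noiseless_single_driver_found_and_stops(self, linear_fm):
        selected, trace = ml.greedy_forward_select("LR", linear_fm)
        assert selected == ["f3"]
        assert trace[-1] == pytest.approx(0.0, abs=1e-8)

    def test_two_orthogonal_drivers_found_in_first_two_rounds(self):
        rng = np.random.default_rng(2)
        n = 60
        X = rng.standard_normal((n, 8))
        q, _ = np.linalg.qr(X)
        fm = pd.DataFrame(q, columns=[f"f{i}" for i in range(8)])
        fm["lvef_pct"] = q[:, 1] + q[:, 2]
        selected, trace = ml.greedy_forward_select("LR", fm)
        assert set(selected[:2]) == {"f1", "f2"}
        assert trace[1] == pytest.approx(0.0, abs=1e-8)
        assert trace[0] > trace[1]

    def test_pure_noise_terminates_quickly_with_matching_trace(self):
        rng = np.random.default_rng(3)
        n = 400
        fm = pd.DataFrame(rng.standard_normal((n, 5)),
                          columns=[f"f{i}" for i in range(5)])
        fm["lvef_pct"] = rng.standard_normal(n)
        selected, trace = ml.greedy_forward_select("LR", fm)
        assert len(selected) == len(trace)
        assert len(selected) <= 3

    def test_trace_is_monotone_non_increasing(self, rng):
        fm = _random_fm(rng, n=80, p=10, noise=2.0)
        _, trace = ml.greedy_forward_select("LR", fm)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_cap_limits_the_subset_size(self, rng):
        fm = _random_fm(rng, n=60, p=12, noise=0.5)
        selected, _ = ml.greedy_forward_select("LR", fm, max_features=4)
        assert len(selected) <= 4


class TestHourGrid:
    def test_grid_shape_and_identical_hours_agree(self, rng):
        fm = _random_fm(rng, n=30, p=4)
        fms = {h: fm.copy() for h in (7, 8, 9)}
        results, grid_rmse, grid_mae = ml.evaluate_hour_grid(
            fms, ["LR", "KNN"], max_features=3)
        assert grid_rmse.shape == (3, 2)
        assert len(results) == 6
        for col in grid_rmse:
            assert grid_rmse[col].nunique() == 1  # identical matrices

    def test_signal_hour_wins_the_grid(self):
        rng = np.random.default_rng(5)
        n = 60
        signal_fm = _random_fm(rng, n=n, p=5, noise=0.3)
        fms = {21: signal_fm}
        for h in (20, 22):
            noise_fm = signal_fm.copy()
            noise_fm["lvef_pct"] = rng.permutation(
                signal_fm["lvef_pct"].to_numpy())
            fms[h] = noise_fm
        _, grid_rmse, _ = ml.evaluate_hour_grid(fms, ["LR"], max_features=5)
        assert grid_rmse["LR"].idxmin() == 21

    def test_response_permutation_breaks_the_fit(self, rng):
        # LOOCV hygiene: shuffling y must not yield a better score
        fm = _random_fm(rng, n=80, p=6, noise=0.5)
        sel, trace = ml.greedy_forward_select("LR", fm, max_features=6)
        shuffled = fm.copy()
        shuffled["lvef_pct"] = rng.permutation(fm["lvef_pct"].to_numpy())
        sel_p, trace_p = ml.greedy_forward_select("LR", shuffled,
                                                  max_features=6)
        assert trace_p[-1] > trace[-1]


class TestBlandAltman:
    def test_perfect_agreement_is_degenerate(self):
        ba = ml.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0
        assert ba.loa_low == ba.loa_high == 0.0

    def test_constant_offset_gives_zero_width_limits(self):
        ba = ml.bland_altman(np.arange(10.0), np.arange(10.0) + 3.0)
        assert ba.bias == pytest.approx(3.0)
        assert ba.half_width == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_normal_differences(self):
        rng = np.random.default_rng(11)
        n = 100_000
        actual = np.zeros(n)
        predicted = rng.normal(0.5, 2.0, n)
        ba = ml.bland_altman(actual, predicted)
        assert ba.bias == pytest.approx(0.5, abs=0.02)
        assert ba.half_width == pytest.approx(1.96 * 2.0, abs=0.05)

    def test_half_width_tracks_rmse_when_unbiased(self, rng):
        actual = rng.normal(65, 7, 200)
        predicted = actual + rng.normal(0, 4, 200)
        ba = ml.bland_altman(actual, predicted)
        r = ml.rmse(actual, predicted)
        assert abs(ba.half_width - 1.96 * r) / (1.96 * r) < 0.1

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            ml.bland_altman([1.0], [2.0])
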