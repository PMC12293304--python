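"""Coarse-graining, composite multiscale curves, curve parameters, and
feature-matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmsehrv import cmse, entropy as E, synth


class TestCoarseGrain:
    def test_printed_toy_vectors(self):
        x = [1, 2, 3, 4, 5, 6]
        assert cmse.coarse_grain(x, 2, 1).values.tolist() == [1.5, 3.5, 5.5]
        assert cmse.coarse_grain(x, 2, 2).values.tolist() == [2.5, 4.5]

    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal(37)
        assert np.array_equal(cmse.coarse_grain(x, 1, 1).values, x)

    def test_offset_beyond_scale_rejected(self):
        with pytest.raises(ValueError):
            cmse.coarse_grain(np.arange(10.0), 2, 3)
        with pytest.raises(ValueError):
            cmse.coarse_grain(np.arange(10.0), 2, 0)

    @given(n=st.integers(10, 200), tau=st.integers(1, 9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_offset_lengths_are_exact(self, n, tau):
        x = np.arange(float(n))
        for k in range(1, tau + 1):
            got = cmse.coarse_grain(x, tau, k)
            assert got.values.size == (n - k + 1) // tau

    def test_windows_average_disjoint_blocks(self, rng):
        x = rng.standard_normal(20)
        got = cmse.coarse_grain(x, 3, 2).values
        expected = [x[1:4].mean(), x[4:7].mean(), x[7:10].mean(),
                    x[10:13].mean(), x[13:16].mean(), x[16:19].mean()]
        assert got == pytest.approx(expected, abs=1e-12)


class TestCompositeValue:
    def test_scale_one_equals_base_estimator(self, rng):
        x = rng.standard_normal(200)
        for name in ("SampEn", "PEn", "DispEn"):
            assert cmse.cmse_value(x, name, tau=1) == pytest.approx(
                E.entropy(x, name).value, abs=1e-12)

    def test_equals_explicit_per_offset_average(self, rng):
        x = rng.standard_normal(240)
        tau = 3
        # explicit 3-term average with the tolerance frozen from the parent
        r_abs = 0.2 * x.std()
        parts = [E.entropy(cmse.coarse_grain(x, tau, k).values, "SampEn",
                           {"r": r_abs, "r_absolute": True}).value
                 for k in (1, 2, 3)]
        assert cmse.cmse_value(x, "SampEn", tau=tau) == pytest.approx(
            np.mean(parts), abs=1e-12)

    def test_constant_series_zero_at_every_scale(self):
        x = np.full(300, 0.8)
        for tau in (1, 2, 5):
            assert cmse.cmse_value(x, "PEn", tau=tau) == 0.0

    def test_undefined_offsets_are_averaged_out(self, rng):
        # a short series at large tau: some offsets can be too short for the
        # estimator minimum; defined offsets must still be averaged
        x = rng.standard_normal(9)
        v = cmse.cmse_value(x, "PEn", tau=2)
        assert np.isfinite(v)


class TestCurve:
    def test_white_noise_curve_declines_and_one_over_f_retains(self):
        # classic multiscale signatures, averaged over replicates
        reps = 8
        n = 3000
        white_curves, pink_curves = [], []
        for s in range(reps):
            rng = np.random.default_rng(s)
            white = rng.standard_normal(n)
            pink = synth.one_over_f_noise(n, rng)
            white_curves.append(cmse.cmse_curve(white, "SampEn").values)
            pink_curves.append(cmse.cmse_curve(pink, "SampEn").values)
        wmean = np.mean(white_curves, axis=0)
        pmean = np.mean(pink_curves, axis=0)
        assert np.all(np.diff(wmean) < 0)
        assert pmean[19] > wmean[19]

    def test_short_series_has_undefined_tail(self, rng):
        x = rng.standard_normal(300)  # 300/20 = 15 < 50 coarse points
        curve = cmse.cmse_curve(x, "SampEn")
        assert np.isnan(curve.values[-1])
        assert np.isfinite(curve.values[0])
        assert curve.n_undefined > 0

    def test_variance_contraction_of_coarse_grained_white_noise(self, rng):
        x = rng.standard_normal(100_000)
        for tau in (2, 5, 10):
            v = cmse.coarse_grain(x, tau, 1).values.var()
            assert v == pytest.approx(1.0 / tau, rel=0.05)


class TestCurveParameters:
    def _curve(self, values):
        return cmse.CMSECurve(estimator="SampEn", params={},
                              values=np.asarray(values, dtype=float))

    def test_constant_curve_closed_form(self):
        p = cmse.cmse_parameters(self._curve([2.0] * 20))
        assert p.scale1 == 2.0
        assert p.scale5 == 2.0
        assert p.slope_1_5 == pytest.approx(0.0, abs=1e-12)
        assert p.area_1_5 == pytest.approx(8.0, abs=1e-12)
        assert p.area_6_20 == pytest.approx(28.0, abs=1e-12)

    def test_linear_curve_closed_form(self):
        p = cmse.cmse_parameters(self._curve(np.arange(1.0, 21.0)))
        assert p.slope_1_5 == pytest.approx(1.0, abs=1e-12)
        assert p.area_1_5 == pytest.approx(12.0, abs=1e-12)

    def test_slope_matches_independent_least_squares(self, rng):
        e = rng.standard_normal(20)
        p = cmse.cmse_parameters(self._curve(e))
        taus = np.arange(1.0, 6.0)
        expected = (((taus - 3.0) * (e[:5] - e[:5].mean())).sum()
                    / ((taus - 3.0) ** 2).sum())
        assert p.slope_1_5 == pytest.approx(expected, abs=1e-9)

    def test_area_additivity_over_the_full_scale_range(self, rng):
        e = rng.standard_normal(20)
        p = cmse.cmse_parameters(self._curve(e))
        bridge = (e[4] + e[5]) / 2.0  # trapezoid over the [5, 6] interval
        total = np.trapezoid(e, np.arange(1.0, 21.0))
        assert p.area_1_5 + bridge + p.area_6_20 == pytest.approx(
            total, abs=1e-9)

    def test_sum_convention_switch(self):
        e = np.arange(1.0, 21.0)
        p = cmse.cmse_parameters(self._curve(e), ci_convention="sum")
        assert p.area_1_5 == pytest.approx(15.0)
        assert p.area_6_20 == pytest.approx(float(np.arange(6, 21).sum()))

    def test_undefined_scales_drop_the_dependent_parameters(self):
        values = np.full(20, 1.5)
        values[10] = np.nan
        p = cmse.cmse_parameters(self._curve(values))
        assert p.scale1 == 1.5 and p.slope_1_5 is not None
        assert p.area_6_20 is None


class TestFeatureMatrix:
    def test_feature_vocabulary_is_75_names(self):
        names = cmse.feature_names()
        assert len(names) == 75
        assert names[0] == "PsdEn_sc1"
        assert names[-1] == "SyDyEn_a620"

    def test_cohort_matrix_has_78_columns_plus_response(self, tiny_cohort):
        cohort, spec = tiny_cohort
        fms = cmse.build_feature_matrix(cohort.rr, cohort.covariates)
        fm = fms[21]
        assert fm.shape[1] == 79  # 75 + age + sex + history + response
        feature_cols = [c for c in fm.columns if c != "lvef_pct"]
        assert len(feature_cols) == 78
        assert feature_cols[-3:] == ["age", "sex", "history_years"]

    def test_missing_hour_rows_are_nan_with_covariates_present(self,
                                                               tiny_cohort):
        cohort, spec = tiny_cohort
        fms = cmse.build_feature_matrix(cohort.rr, cohort.covariates,
                                        hours=[21, 22])
        fm22 = fms[22]  # hour 22 was never generated
        ms_cols = cmse.feature_names()
        assert fm22[ms_cols].isna().all().all()
        assert fm22["age"].notna().all()

    def test_deterministic_across_runs(self, tiny_cohort):
        cohort, spec = tiny_cohort
        a = cmse.build_feature_matrix(cohort.rr, cohort.covariates)[21]
        b = cmse.build_feature_matrix(cohort.rr, cohort.covariates)[21]
        pd.testing.assert_frame_equal(a, b)

    def test_shared_path_matches_per_estimator_curves(self, rng):
        x = rng.standard_normal(400) * 0.05 + 0.85
        feats = cmse.features_for_series(x, min_len=10)
        for est in ("SampEn", "BubbEn"):
            curve = cmse.cmse_curve(x, est, min_len=10)
            params = cmse.cmse_parameters(curve).as_dict()
            for suf, v in params.items():
                assert feats[f"{est}_{suf}"] == pytest.approx(v, nan_ok=True)


class TestLongFormatCurves:
    def test_batch_runner_emits_one_row_per_subject_hour_estimator_scale(
            self, tiny_cohort):
        cohort, _ = tiny_cohort
        frame = cmse.curves_long_frame(cohort.rr, estimators=["SampEn",
                                                              "PEn"])
        assert list(frame.columns) == ["subject_id", "hour", "estimator",
                                       "scale", "value"]
        assert len(frame) == 2 * 1 * 2 * 20  # subjects x hours x est x tau
        one = frame[(frame.subject_id == 0) & (frame.estimator == "SampEn")]
        curve = cmse.cmse_curve(
            cohort.rr.query("subject_id == 0 and hour == 21")["rr_s"]
            .to_numpy(), "SampEn")
        assert np.allclose(one["value"].to_numpy(), curve.values,
                           equal_nan=True)
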