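"""Activity transforms, the fasting OLS fit, and residual diagnostics."""

import numpy as np
import pytest

from ditcalc import (
    CalorimetryError,
    fit_fasting_model,
    predict_ee,
    residual_diagnostics,
    select_transform,
    transform_activity,
)
from ditcalc.preprocess import BinnedTrace


def _binned(activity, ee, condition="fasted"):
    activity = np.asarray(activity, dtype=float)
    ee = np.asarray(ee, dtype=float)
    n = len(activity)
    return BinnedTrace(
        time_mid=6.0 + 12.0 * np.arange(n),
        ee=ee,
        rer=np.full(n, 0.8),
        activity=activity,
        photoperiod=np.array(["dark"] * n, dtype=object),
        condition=condition,
        bin_width=12.0,
        animal_id="t1",
    )


def _ols_closed_form(x, y):
    """Independent textbook OLS: slope = cov(x,y)/var(x)."""
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - ym) ** 2)
    return intercept, slope, r2


class TestTransformActivity:
    @pytest.mark.parametrize(
        "counts,method,expected",
        [
            (16.0, "sqrt", 4.0),
            (0.0, "sqrt", 0.0),
            (0.0, "log1p", 0.0),
            (np.e - 1, "log1p", 1.0),
            (7.5, "identity", 7.5),
        ],
    )
    def test_values(self, counts, method, expected):
        assert transform_activity(counts, method) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(CalorimetryError):
            transform_activity(-1.0, "sqrt")

    def test_unknown_method_rejected(self):
        with pytest.raises(CalorimetryError):
            transform_activity(1.0, "cubert")


class TestFit:
    def test_exact_line_recovered(self):
        activity = np.array([0.0, 4.0, 16.0, 64.0, 100.0, 144.0])
        ee = 0.008 + 0.001 * np.sqrt(activity)
        model = fit_fasting_model(_binned(activity, ee), "sqrt")
        assert model.intercept == pytest.approx(0.008, abs=1e-12)
        assert model.slope == pytest.approx(0.001, abs=1e-12)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = rng.integers(5, 60)
            activity = rng.gamma(2.0, 50.0, n)
            ee = 0.005 + 0.0003 * np.sqrt(activity) + rng.normal(0, 5e-4, n)
            ee = np.abs(ee)
            model = fit_fasting_model(_binned(activity, ee), "sqrt")
            a, b, r2 = _ols_closed_form(np.sqrt(activity), ee)
            assert model.intercept == pytest.approx(a, abs=1e-10)
            assert model.slope == pytest.approx(b, abs=1e-10)
            assert model.r2 == pytest.approx(r2, abs=1e-10)

    def test_recovers_truth_within_three_se(self, noiseless_config):
        # noisy generative runs: estimates should straddle the truth
        import dataclasses

        from ditcalc.preprocess import bin_trace
        from ditcalc.simulate import SimConfig, simulate_mouse

        cfg = SimConfig()
        hits = 0
        for seed in range(10):
            fasted, _, truth = simulate_mouse(cfg, seed)
            model = fit_fasting_model(bin_trace(fasted), "sqrt")
            x = np.sqrt(bin_trace(fasted).activity)
            n = len(x)
            s = np.sqrt(np.sum(model.residuals**2) / (n - 2))
            se_slope = s / np.sqrt(np.sum((x - x.mean()) ** 2))
            se_int = s * np.sqrt(1 / n + x.mean() ** 2 / np.sum((x - x.mean()) ** 2))
            if (
                abs(model.slope - truth.slope) < 3 * se_slope
                and abs(model.intercept - truth.intercept) < 3 * se_int
            ):
                hits += 1
        assert hits >= 9

    def test_r2_in_plausible_band_at_default_noise(self):
        # the defaults should produce fasting fits of realistic quality
        from ditcalc.preprocess import bin_trace
        from ditcalc.simulate import SimConfig, simulate_mouse

        r2s = [
            fit_fasting_model(bin_trace(simulate_mouse(SimConfig(), s)[0]), "sqrt").r2
            for s in range(6)
        ]
        assert all(0.45 <= r2 <= 0.95 for r2 in r2s)

    def test_r2_invariant_under_affine_ee_rescale(self):
        rng = np.random.default_rng(5)
        activity = rng.gamma(2.0, 50.0, 40)
        ee = 0.006 + 0.0002 * np.sqrt(activity) + rng.normal(0, 4e-4, 40)
        ee = np.abs(ee)
        m1 = fit_fasting_model(_binned(activity, ee), "sqrt")
        m2 = fit_fasting_model(_binned(activity, 4184.0 * ee + 0.5), "sqrt")
        assert m1.r2 == pytest.approx(m2.r2, rel=1e-9)

    def test_residuals_sum_to_zero(self, binned_pair):
        fasted, _, _ = binned_pair
        model = fit_fasting_model(fasted, "sqrt")
        assert np.sum(model.residuals) == pytest.approx(0.0, abs=1e-12)

    def test_constant_activity_rejected(self):
        with pytest.raises(CalorimetryError, match="degenerate"):
            fit_fasting_model(_binned([5.0] * 6, [0.01] * 6), "sqrt")

    def test_too_few_points_rejected(self):
        with pytest.raises(CalorimetryError):
            fit_fasting_model(_binned([1.0, 4.0], [0.01, 0.02]), "sqrt")


class TestSelectTransform:
    def test_sqrt_law_selects_sqrt(self):
        rng = np.random.default_rng(11)
        activity = rng.gamma(2.0, 80.0, 55)
        ee = 0.005 + 0.0004 * np.sqrt(activity) + rng.normal(0, 2e-4, 55)
        best, table = select_transform(_binned(activity, np.abs(ee)))
        assert best == "sqrt"
        assert set(table) == {"sqrt", "log1p", "identity"}

    def test_linear_law_selects_identity(self):
        rng = np.random.default_rng(12)
        activity = rng.uniform(0.0, 400.0, 55)
        ee = 0.005 + 2e-5 * activity + rng.normal(0, 1e-4, 55)
        best, _ = select_transform(_binned(activity, np.abs(ee)))
        assert best == "identity"

    def test_exact_tie_prefers_sqrt(self):
        # constant EE fits every transform perfectly (r2 = 1 by the SStot=0
        # convention), so the fixed preference order must decide
        best, table = select_transform(_binned([1.0, 4.0, 9.0, 16.0], [0.01] * 4))
        assert len(set(table.values())) == 1
        assert best == "sqrt"

    def test_empty_candidates_rejected(self):
        with pytest.raises(CalorimetryError):
            select_transform(_binned([1.0, 4.0, 9.0], [0.01, 0.02, 0.03]), [])


class TestResidualDiagnostics:
    def test_perfect_line_is_degenerate(self):
        activity = np.array([1.0, 4.0, 9.0, 16.0])
        model = fit_fasting_model(_binned(activity, 0.004 + 0.001 * np.sqrt(activity)))
        diag = residual_diagnostics(model)
        assert diag.degenerate
        assert diag.homoscedasticity_pvalue == 1.0

    def test_null_calibration(self):
        # homoscedastic residuals: rejection rate near the nominal 5%
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 200
        for _ in range(reps):
            activity = rng.gamma(2.0, 60.0, 55)
            ee = np.abs(0.005 + 3e-4 * np.sqrt(activity) + rng.normal(0, 5e-4, 55))
            model = fit_fasting_model(_binned(activity, ee), "sqrt")
            if residual_diagnostics(model).homoscedasticity_pvalue < 0.05:
                rejections += 1
        assert 0.005 <= rejections / reps <= 0.12

    def test_detects_heteroscedasticity(self):
        rng = np.random.default_rng(100)
        detected = 0
        for _ in range(20):
            activity = rng.gamma(2.0, 60.0, 300)
            mu = 0.005 + 3e-4 * np.sqrt(activity)
            ee = np.abs(mu + rng.normal(0, 1.0, 300) * mu * 0.3)
            model = fit_fasting_model(_binned(activity, ee), "sqrt")
            if residual_diagnostics(model).homoscedasticity_pvalue < 0.05:
                detected += 1
        assert detected >= 15

    def test_pairs_exported(self, binned_pair):
        fasted, _, _ = binned_pair
        model = fit_fasting_model(fasted, "sqrt")
        diag = residual_diagnostics(model)
        assert diag.residual_vs_fitted.shape == (model.n_points, 2)
        assert np.array_equal(diag.residual_vs_fitted[:, 1], model.residuals)


class TestPredict:
    def test_known_prediction(self):
        activity = np.array([0.0, 4.0, 16.0, 64.0])
        model = fit_fasting_model(_binned(activity, 0.008 + 0.001 * np.sqrt(activity)))
        assert predict_ee(model, 16.0) == pytest.approx(0.012, abs=1e-12)
        assert predict_ee(model, 0.0) == pytest.approx(model.intercept, abs=1e-15)

    def test_residual_identity(self, binned_pair):
        fasted, _, _ = binned_pair
        model = fit_fasting_model(fasted, "sqrt")
        observed = fasted.ee
        predicted = predict_ee(model, fasted.activity)
        assert observed - predicted == pytest.approx(model.residuals, abs=1e-12)

    def test_monotone_for_nonnegative_slope(self, binned_pair):
        fasted, _, _ = binned_pair
        model = fit_fasting_model(fasted, "sqrt")
        assert model.slope >= 0
        grid = np.linspace(0.0, 400.0, 100)
        preds = predict_ee(model, grid)
        assert np.all(np.diff(preds) >= 0)

    def test_negative_activity_rejected(self, binned_pair):
        fasted, _, _ = binned_pair
        model = fit_fasting_model(fasted, "sqrt")
        with pytest.raises(CalorimetryError):
            predict_ee(model, -5.0)
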