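import numpy as np
import pytest

import radrobust as rr
from radrobust.correction import (
    CorrectabilityCategory,
    FunctionId,
    apply_correction,
    correct_feature,
    default_log_scale,
    evaluate_correction,
    fit_all,
    fit_dependency,
    select_best_model,
)


def _fit(y, w, x, fid, s=1.0):
    return fit_dependency(np.asarray(y), np.asarray(w), np.asarray(x), fid, s)


class TestFitDependency:
    def test_noiseless_inverse_curve_recovered_exactly(self):
        x = np.linspace(0.2, 2.0, 10)
        y = 2.0 / x + 5.0
        m = _fit(y, np.ones(10), x, FunctionId.INV)
        assert m.converged
        assert m.alpha == pytest.approx(2.0, abs=1e-9)
        assert m.beta == pytest.approx(5.0, abs=1e-9)

    def test_wrong_form_has_larger_aic(self):
        x = np.linspace(0.2, 2.0, 12)
        y = 3.0 * x + 1.0
        lin = _fit(y, np.ones(12), x, FunctionId.LIN)
        inv = _fit(y, np.ones(12), x, FunctionId.INV)
        assert lin.aic < inv.aic

    def test_equal_weights_no_outliers_matches_wls_oracle(self):
        import statsmodels.api as sm

        # alternating residuals keep every point inside the Huber threshold,
        # so the robust fit must coincide with ordinary weighted least squares
        x = np.linspace(0.5, 3.0, 20)
        y = 1.3 * np.log(x) + 0.4 + 0.01 * (-1.0) ** np.arange(20)
        m = _fit(y, np.ones(20), x, FunctionId.LOG)
        X = sm.add_constant(np.log(x))
        ols = sm.WLS(y, X, weights=np.ones(20)).fit()
        assert m.beta == pytest.approx(ols.params[0], abs=1e-8)
        assert m.alpha == pytest.approx(ols.params[1], abs=1e-8)

    def test_intrinsic_weights_steer_the_fit(self):
        # one grossly wrong point with near-zero weight must not move the fit
        x = np.linspace(0.5, 3.0, 10)
        y = 2.0 * x + 1.0
        y_bad = y.copy()
        y_bad[4] += 100.0
        w = np.ones(10)
        w[4] = 1e-9
        m = _fit(y_bad, w, x, FunctionId.LIN)
        assert m.alpha == pytest.approx(2.0, abs=1e-4)

    def test_huber_downweights_outlier(self):
        x = np.linspace(0.5, 3.0, 15)
        y = 2.0 * x + 1.0
        y[7] += 50.0  # single outlier, equal intrinsic weights
        m = _fit(y, np.ones(15), x, FunctionId.LIN)
        assert m.alpha == pytest.approx(2.0, abs=0.05)

    def test_singular_design_not_converged(self):
        x = np.linspace(0.5, 3.0, 8)
        m = fit_dependency(
            np.ones(8), np.ones(8), np.full(8, 2.0), FunctionId.LIN
        )
        assert not m.converged
        assert select_best_model([m]) is None

    def test_parameter_recovery_all_eight_forms(self):
        grid = rr.build_parameter_grid("discretisation", "FBW")
        x = np.asarray(grid.values)
        s = default_log_scale(grid)
        for k, fid in enumerate(FunctionId):
            prof = rr.DependencyProfile(fid, 1.0, 0.0, s)
            curve = prof.mean_curve(x)
            rng = np.random.default_rng(1000 + k)
            y = curve + rng.normal(0, 0.02 * np.ptp(curve), x.size)
            m = _fit(y, np.ones(x.size), x, fid, s)
            assert m.converged
            assert m.alpha == pytest.approx(1.0, rel=0.05)


class TestSelectBestModel:
    def test_true_form_wins_in_seeded_simulation(self, small_fbw_grid):
        grid = small_fbw_grid
        prof = rr.DependencyProfile(FunctionId.INV2, 0.01, 3.0)
        spec = rr.SyntheticCohortSpec(
            n_subjects=15,
            grid=grid,
            features=(("f", prof),),
            noise_sd=0.02,
            seed=77,
        )
        fits = fit_all(rr.generate_cohort(spec), "f", grid)
        assert select_best_model(fits).function_id is FunctionId.INV2

    def test_tie_breaks_by_canonical_order(self):
        a = rr.DependencyModel(FunctionId.QUAD, 1, 0, 1, 5.0, 10, True)
        b = rr.DependencyModel(FunctionId.LIN, 1, 0, 1, 5.0, 10, True)
        assert select_best_model([a, b]).function_id is FunctionId.LIN

    def test_non_converged_excluded_from_argmin(self):
        good = rr.DependencyModel(FunctionId.QUAD, 1, 0, 1, 5.0, 10, True)
        bad = rr.DependencyModel(FunctionId.LIN, 1, 0, 1, -np.inf, 10, False)
        assert select_best_model([good, bad]).function_id is FunctionId.QUAD


class TestApplyCorrection:
    def test_exact_inversion_gives_constant_and_zero_cv(self, small_fbw_grid):
        grid = small_fbw_grid
        spec = rr.SyntheticCohortSpec(
            n_subjects=5,
            grid=grid,
            features=(("f", rr.DependencyProfile(FunctionId.INV, 2.0, 5.0)),),
            seed=0,
        )
        table = rr.generate_cohort(spec)
        model = select_best_model(fit_all(table, "f", grid))
        corrected = apply_correction(table, "f", grid, model)
        vals = corrected.wide("f", grid).to_numpy()
        assert np.allclose(vals, 2.0, atol=1e-8)
        m = rr.compute_metrics(corrected, "f", grid)
        assert m.cv_mean == pytest.approx(0.0, abs=1e-6)

    def test_log_scale_rule_avoids_log_one(self):
        grid = rr.build_parameter_grid("discretisation", "FBW")
        assert default_log_scale(grid) == 100.0
        model = rr.DependencyModel(FunctionId.LOG, 1.0, 0.0, 100.0, 0.0, 30, True)
        g = model.g(np.asarray(grid.values))
        assert np.all(np.abs(g) > 1e-12)
        assert g[0] == pytest.approx(np.log(5.0))
        interp = rr.build_parameter_grid("interpolation", "linear")
        assert default_log_scale(interp) == 10.0
        fbn = rr.build_parameter_grid("discretisation", "FBN")
        assert default_log_scale(fbn) == 1.0

    def test_unscaled_log_vanishes_at_one(self):
        model = rr.DependencyModel(FunctionId.LOG, 1.0, 0.0, 1.0, 0.0, 5, True)
        with pytest.raises(ValueError, match="vanishes"):
            model.g(np.asarray([0.5, 1.0, 2.0]))

    def test_double_correction_refused(self, small_fbw_grid):
        grid = small_fbw_grid
        spec = rr.SyntheticCohortSpec(
            n_subjects=5,
            grid=grid,
            features=(("f", rr.DependencyProfile(FunctionId.INV, 2.0, 5.0)),),
            seed=0,
        )
        table = rr.generate_cohort(spec)
        model = select_best_model(fit_all(table, "f", grid))
        corrected = apply_correction(table, "f", grid, model)
        assert corrected.corrected
        with pytest.raises(ValueError, match="already corrected"):
            apply_correction(corrected, "f", grid, model)


class TestEvaluateCorrection:
    def _cohort(self, grid, profile, noise, seed, intercept_sd=0.05):
        spec = rr.SyntheticCohortSpec(
            n_subjects=20,
            grid=grid,
            features=(("f", profile),),
            intercept_sd=intercept_sd,
            slope_sd=0.01,
            noise_sd=noise,
            seed=seed,
        )
        return rr.generate_cohort(spec)

    def test_strong_dependency_is_correctable(self, small_fbw_grid):
        table = self._cohort(
            small_fbw_grid,
            rr.DependencyProfile(FunctionId.INV, 2.0, 5.0),
            0.02,
            21,
        )
        res = correct_feature(table, "f", small_fbw_grid)
        assert res.category is CorrectabilityCategory.CORRECTABLE
        assert res.wilcoxon_p < 0.05
        assert not res.ci_overlap
        assert res.delta_cv < 0 and res.delta_rrm < 0

    def test_unchanged_after_is_not_correctable(self, small_fbw_grid):
        table = self._cohort(
            small_fbw_grid, rr.FlatProfile(10.0), 0.02, 22
        )
        res = evaluate_correction(table, table, "f", small_fbw_grid)
        assert res.category is CorrectabilityCategory.NOT_CORRECTABLE
        assert np.isnan(res.wilcoxon_p)
        assert res.reason

    def test_residual_noise_keeps_feature_moderately_correctable(
        self, small_fbw_grid
    ):
        # strong invertible dependency plus heteroscedastic noise that the
        # correction amplifies at small bin widths: metrics drop clearly
        # but CV_mean stays above threshold
        grid = small_fbw_grid
        noise = tuple(0.3 if i < 3 else 0.01 for i in range(grid.n))
        spec = rr.SyntheticCohortSpec(
            n_subjects=20,
            grid=grid,
            features=(("f", rr.DependencyProfile(FunctionId.INV, 2.0, 0.5)),),
            intercept_sd=0.02,
            noise_sd=noise,
            seed=23,
        )
        table = rr.generate_cohort(spec)
        res = correct_feature(table, "f", grid)
        assert res.category in (
            CorrectabilityCategory.MODERATELY_CORRECTABLE,
            CorrectabilityCategory.CORRECTABLE,
        )

    def test_correction_preserves_subject_order_when_g_positive(
        self, small_fbw_grid
    ):
        grid = small_fbw_grid
        table = self._cohort(
            grid,
            rr.DependencyProfile(FunctionId.INV, 2.0, 5.0),
            0.0,
            24,
            intercept_sd=0.5,
        )
        model = select_best_model(fit_all(table, "f", grid))
        corrected = apply_correction(table, "f", grid, model)
        before = table.wide("f", grid).to_numpy()
        after = corrected.wide("f", grid).to_numpy()
        for col in range(before.shape[1]):
            assert (
                np.argsort(before[:, col]) == np.argsort(after[:, col])
            ).all()
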