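import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apgbp import regression as rg
from apgbp import synth
from apgbp.errors import (DegenerateBaselineError, InputError,
                          MissingFeatureError, SingularFitError)
from apgbp.features import STATIC_FEATURES
from tests.conftest import build_feature_frame


class TestFitOLS:
    def test_exact_line(self):
        m = rg.fit_ols(pd.DataFrame({"x": [0.0, 1.0, 2.0]}), [1.0, 3.0, 5.0], ["x"])
        assert m.intercept == pytest.approx(1.0)
        assert m.coefficients["x"] == pytest.approx(2.0)

    def test_constant_target(self):
        m = rg.fit_ols(pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]}),
                       [7.0] * 4, ["x"])
        assert m.intercept == pytest.approx(7.0)
        assert m.coefficients["x"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generator_coefficients(self):
        # amp_a is affine in the morphology-level SBP by construction
        subs = synth.generate_population(50, seed=5, bp_noise_sd=0.0,
                                         morph_noise_sd=0.0)
        f = synth.population_frame(subs)
        m = rg.fit_ols(f, f["true_sbp"], ["amp_a"])
        slope = 1.0 / synth.A_WAVE_SLOPE
        intercept = synth.SBP_REF - synth.A_WAVE_REF / synth.A_WAVE_SLOPE
        assert m.coefficients["amp_a"] == pytest.approx(slope, rel=1e-6)
        assert m.intercept == pytest.approx(intercept, rel=1e-6)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 51))
            p = int(rng.integers(1, 7))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            m = rg.fit_ols(X, y, [f"x{j}" for j in range(p)])
            Xd = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
            got = np.array([m.intercept] + [m.coefficients[f"x{j}"] for j in range(p)])
            np.testing.assert_allclose(got, beta, rtol=1e-8, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        m = rg.fit_ols(X, y, ["x0", "x1", "x2"])
        pred = m.intercept + X @ np.array([m.coefficients[f"x{j}"] for j in range(3)])
        resid = y - pred
        scale = np.linalg.norm(y)
        for col in X.T:
            assert abs(resid @ col) / scale < 1e-8

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(0, 0.3, 60)
        m = rg.fit_ols(X, y, [f"x{j}" for j in range(4)])
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            [m.intercept] + [m.coefficients[f"x{j}"] for j in range(4)],
            ref.params, rtol=1e-9)

    def test_collinear_design_named(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(SingularFitError):
            rg.fit_ols(X, np.arange(10.0), ["x0", "x1"])


class TestStepwiseSelect:
    def test_recovers_single_true_predictor(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        y = 3.0 * X[:, 0]
        m = rg.stepwise_select(pd.DataFrame(X, columns=["x1", "x2", "x3"]),
                               y, ["x1", "x2", "x3"])
        assert m.selected_features == ["x1"]
        assert m.coefficients["x1"] == pytest.approx(3.0, abs=1e-8)

    def test_pvalue_pipeline_agrees_with_exhaustive_bic_oracle(self):
        import statsmodels.api as sm
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 60
            X = rng.normal(size=(n, 5))
            y = 2.0 * X[:, 0] + rng.normal(0, 1.0, n)
            best = None
            for k in range(6):
                for S in itertools.combinations(range(5), k):
                    Xd = sm.add_constant(X[:, list(S)]) if S else np.ones((n, 1))
                    bic = sm.OLS(y, Xd).fit().bic
                    if best is None or bic < best[1]:
                        best = (set(S), bic)
            est = rg.StepwiseLinearRegression(criterion="bic").fit(X, y)
            assert set(est.selected_idx_) == best[0], f"seed {seed}"

    def test_null_model_mostly_intercept_only(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            X = rng.normal(size=(200, 5))
            y = rng.normal(size=200)
            est = rg.StepwiseLinearRegression(alpha_in=0.05).fit(X, y)
            hits += len(est.selected_idx_) == 0
        assert hits >= 70

    def test_empty_candidates_intercept_only(self):
        m = rg.stepwise_select(pd.DataFrame(), [4.0, 6.0, 8.0], [])
        assert m.selected_features == []
        assert m.intercept == pytest.approx(6.0)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_selection_subset_and_refit_consistency(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 4))
        y = X[:, 0] - 0.5 * X[:, 2] + rng.normal(0, 0.5, 60)
        names = ["p", "q", "r", "s"]
        m = rg.stepwise_select(pd.DataFrame(X, columns=names), y, names)
        assert set(m.selected_features) <= set(names)
        if m.selected_features:
            refit = rg.fit_ols(pd.DataFrame(X, columns=names), y,
                               m.selected_features)
            for name in m.selected_features:
                assert refit.coefficients[name] == pytest.approx(
                    m.coefficients[name], rel=1e-9, abs=1e-12)


class TestPredict:
    def test_linear_form(self):
        m = rg.RegressionModel(intercept=80.0, coefficients={"PR": 0.2},
                               selected_features=["PR"])
        assert rg.predict(m, {"PR": 60.0}) == pytest.approx(92.0)

    def test_intercept_only(self):
        m = rg.RegressionModel(intercept=120.0, coefficients={},
                               selected_features=[])
        assert rg.predict(m, {}) == 120.0

    def test_training_mean_reproduced(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = rng.normal(120, 10, 30)
        m = rg.fit_ols(pd.DataFrame(X, columns=["u", "v"]), y, ["u", "v"])
        preds = [rg.predict(m, {"u": a, "v": b}) for a, b in X]
        assert np.mean(preds) == pytest.approx(np.mean(y), abs=1e-9)

    def test_missing_feature_named(self):
        m = rg.RegressionModel(intercept=0.0, coefficients={"age": 1.0},
                               selected_features=["age"])
        with pytest.raises(MissingFeatureError) as exc:
            rg.predict(m, {"PR": 60.0})
        assert "age" in str(exc.value)

    def test_affine_in_features(self):
        m = rg.RegressionModel(intercept=5.0, coefficients={"x": 2.0, "y": -1.0},
                               selected_features=["x", "y"])
        f1 = {"x": 1.0, "y": 2.0}
        f2 = {"x": -0.5, "y": 4.0}
        fsum = {k: f1[k] + f2[k] for k in f1}
        assert rg.predict(m, fsum) == pytest.approx(
            rg.predict(m, f1) + rg.predict(m, f2) - m.intercept)

    def test_json_round_trip(self, tmp_path):
        m = rg.RegressionModel(intercept=100.5, coefficients={"a": 0.3, "PR": -0.1},
                               selected_features=["a", "PR"], target="SBP",
                               feature_stats={"a": (40.0, 5.0)})
        m.to_json(tmp_path / "m.json")
        back = rg.RegressionModel.from_json(tmp_path / "m.json")
        assert back.intercept == m.intercept
        assert back.coefficients == m.coefficients
        assert back.selected_features == m.selected_features


class TestPTTBaseline:
    def test_exact_affine_recovery(self):
        pttv = np.array([0.0, -5.0, 10.0, 3.0])
        base = rg.fit_ptt_baseline(pttv, -2.0 * pttv)
        assert base.slope == pytest.approx(-2.0)
        assert base.intercept == pytest.approx(0.0, abs=1e-12)

    def test_reference_deviations_zero_by_construction(self):
        ptt = np.array([250.0, 240.0, 260.0, 255.0])
        bp = np.array([120.0, 130.0, 110.0, 115.0])
        est = rg.PTTBaselineRegression().fit(ptt[:, None], bp)
        assert est.reference_ptt_ == 250.0 and est.reference_bp_ == 120.0
        # the reference reading maps back near itself by definition of deviations
        assert est.predict(np.array([[250.0]]))[0] == pytest.approx(
            120.0 + est.intercept_)

    def test_uncorrelated_inputs_give_weak_predictions(self):
        rng = np.random.default_rng(1)
        pttv = rng.normal(0, 10, 27)
        bpv = rng.normal(0, 8, 27)
        base = rg.fit_ptt_baseline(pttv - pttv[0], bpv - bpv[0])
        pred = base.intercept + base.slope * (pttv - pttv[0])
        assert abs(np.corrcoef(pred, bpv)[0, 1]) < 0.3

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateBaselineError):
            rg.fit_ptt_baseline(np.zeros(5), np.arange(5.0))


class TestErrorMetrics:
    def test_hand_arithmetic_triplet(self):
        rep = rg.error_metrics([100.0, 110.0, 120.0], [102.0, 112.0, 118.0])
        assert rep.mean_error == pytest.approx(2.0 / 3.0)
        assert rep.sd_error == pytest.approx(np.sqrt(16.0 / 3.0))
        assert rep.n == 3

    def test_perfect_and_offset_estimates(self):
        rep = rg.error_metrics([100.0, 110.0, 120.0], [100.0, 110.0, 120.0])
        assert (rep.r, rep.mean_error, rep.sd_error) == pytest.approx((1.0, 0.0, 0.0))
        rep = rg.error_metrics([100.0, 110.0, 120.0], [105.0, 115.0, 125.0])
        assert (rep.r, rep.mean_error, rep.sd_error) == pytest.approx((1.0, 5.0, 0.0))

    def test_zero_variance_flags_r_undefined(self):
        rep = rg.error_metrics([100.0, 100.0, 100.0], [101.0, 99.0, 100.0])
        assert not rep.r_defined and np.isnan(rep.r)

    def test_per_subject_breakdown(self):
        rep = rg.error_metrics([100.0, 110.0, 120.0, 130.0],
                               [101.0, 112.0, 119.0, 133.0],
                               subject_ids=["A", "A", "B", "B"])
        per = rep.per_subject.set_index("subject_id")
        assert per.loc["A", "mean_error"] == pytest.approx(1.5)
        assert per.loc["B", "n"] == 2


class TestLOOCV:
    def test_perfect_linear_data(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "sbp": 100 + 2 * x})
        rep = rg.loocv(df, "ols", candidates=["x"])
        assert rep.r == pytest.approx(1.0, abs=1e-8)
        assert rep.mean_error == pytest.approx(0.0, abs=1e-8)
        assert rep.sd_error == pytest.approx(0.0, abs=1e-8)

    def test_three_samples_three_folds(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "sbp": [100.0, 105.0, 110.0]})
        rep = rg.loocv(df, "ols", candidates=["x"])
        assert rep.n == 3
        with pytest.raises(InputError):
            rg.loocv(df.iloc[:2], "ols", candidates=["x"])

    def test_irreducible_noise_band(self, cohort600_features):
        _, frame = cohort600_features
        rep = rg.loocv(frame, "stepwise")
        assert 4.5 <= rep.sd_error <= 6.5

    def test_ptt_fitter(self):
        rng = np.random.default_rng(7)
        sbp = rng.normal(120, 10, 40)
        ptt = 350.0 - sbp + rng.normal(0, 1.0, 40)
        df = pd.DataFrame({"ptt": ptt, "sbp": sbp})
        rep = rg.loocv(df, "ptt")
        assert rep.r > 0.9


class TestAblation:
    def test_covariates_help_when_present(self, ablation_cohort_features):
        full, ablated = rg.ablation_static_features(ablation_cohort_features)
        assert full.r > ablated.r

    def test_ablated_candidates_exclude_static_names(self):
        candidates = ["a", "b", "PR", "height", "weight", "age", "sex"]
        ablated = [c for c in candidates if c not in STATIC_FEATURES]
        assert set(ablated) & set(STATIC_FEATURES) == set()

    def test_no_covariate_effects_indistinguishable(self):
        subs = synth.generate_population(600, seed=21, covariate_effect_scale=0.0,
                                         bp_noise_sd=5.0, morph_noise_sd=0.5)
        frame = build_feature_frame(subs, duration=12.0)
        full, ablated = rg.ablation_static_features(frame)
        assert abs(full.r - ablated.r) < 0.05
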