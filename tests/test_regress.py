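"""Stepwise selection, robust IRLS fitting and dataset-level fitting."""

import numpy as np
import pytest
import statsmodels.api as sm

import gaitnorm as gn
from gaitnorm.regress import (
    CoefficientTable,
    RegressionRecord,
    fit_dataset,
    robust_fit,
    stepwise_select,
)


def predictor_matrix(rng, n):
    """Design resembling the study predictors (speed, age, sex, BMI)."""
    return np.column_stack(
        [
            rng.uniform(0.1, 0.8, n),
            rng.uniform(19, 67, n),
            (rng.random(n) < 0.5).astype(float),
            rng.uniform(17, 31, n),
        ]
    )


class TestStepwiseSelect:
    def test_single_true_predictor(self):
        rng = np.random.default_rng(0)
        X = predictor_matrix(rng, 200)
        y = 2.0 + 3.0 * X[:, 0] + rng.normal(0, 0.01, 200)
        assert stepwise_select(X, y).tolist() == [True, False, False, False]

    def test_pure_noise_rarely_selects_anything(self):
        # each candidate has a ~1 % false-entry chance at alpha = 0.01, so
        # almost all replicates must return the empty (intercept-only) model
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            X = predictor_matrix(rng, 200)
            y = rng.normal(0, 1, 200)
            hits += int(stepwise_select(X, y).any())
        assert hits <= 3

    def test_all_predictors_with_large_effects(self):
        rng = np.random.default_rng(2)
        X = predictor_matrix(rng, 200)
        y = 1.0 + 20 * X[:, 0] - 0.5 * X[:, 1] + 5 * X[:, 2] + 0.8 * X[:, 3]
        y = y + rng.normal(0, 0.5, 200)
        assert stepwise_select(X, y).all()

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(3)
        X = predictor_matrix(rng, 50)
        X[:, 2] = 1.0
        with pytest.raises(ValueError):
            stepwise_select(X, rng.normal(size=50))

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(4)
        X = predictor_matrix(rng, 50)
        X[:, 3] = 2.0 * X[:, 1]
        with pytest.raises(np.linalg.LinAlgError):
            stepwise_select(X, rng.normal(size=50))

    def test_noiseless_constant_response_is_intercept_only(self):
        rng = np.random.default_rng(5)
        X = predictor_matrix(rng, 100)
        y = np.full(100, 7.2097)
        assert not stepwise_select(X, y).any()


class TestRobustFit:
    def test_noiseless_data_recovers_exactly(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(60), predictor_matrix(rng, 60)])
        beta_true = np.array([3.0, -2.0, 0.05, 1.5, -0.3])
        beta, info = robust_fit(X, X @ beta_true)
        assert beta == pytest.approx(beta_true, abs=1e-10)
        assert info["converged"] and np.all(info["weights"] == 1.0)

    def test_noiseless_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = X @ np.array([1.0, 2.0, -0.5])
        beta_irls, _ = robust_fit(X, y)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert beta_irls == pytest.approx(beta_ols, abs=1e-10)

    def test_outlier_resistance_beats_ols(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 51)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.05, 51)
        y[-1] += 100.0  # one gross outlier with leverage on the slope
        X = np.column_stack([np.ones(51), x])
        beta_rob, info = robust_fit(X, y)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert abs(beta_rob[1] - 3.0) < abs(beta_ols[1] - 3.0)
        assert info["weights"][-1] == 0.0  # outlier fully rejected

    def test_intercept_only_constant_response(self):
        beta, _ = robust_fit(np.ones((20, 1)), np.full(20, 4.2))
        assert beta[0] == pytest.approx(4.2, abs=1e-12)

    def test_matches_statsmodels_rlm_cross_check(self):
        # independent implementation of bisquare IRLS as oracle
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(120), rng.normal(size=(120, 2))])
        y = X @ np.array([0.5, 2.0, -1.0]) + rng.standard_t(3, 120)
        beta, _ = robust_fit(X, y)
        ref = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
        assert beta == pytest.approx(ref.params, abs=0.05)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(np.linalg.LinAlgError):
            robust_fit(X, np.zeros(20))


class TestFitDataset:
    def test_boundary_timings_are_constants(self, noiseless_dataset):
        table = fit_dataset(
            noiseless_dataset.predictor_frame(), noiseless_dataset.keypoint_frame()
        )
        for kp, value in (("HIS1", 1.0), ("KNS1", 1.0), ("ANS1", 1.0),
                          ("HIS6", 101.0), ("KNS8", 101.0), ("ANS7", 101.0)):
            rec = table.get(kp, "timing")
            assert rec.is_constant and rec.intercept == value and rec.rmse == 0.0

    def test_noiseless_recovery_of_generating_coefficients(self, noiseless_dataset):
        fitted = fit_dataset(
            noiseless_dataset.predictor_frame(), noiseless_dataset.keypoint_frame()
        )
        for rec in noiseless_dataset.generating_table:
            f = fitted.get(rec.keypoint_id, rec.parameter)
            assert set(f.coefficients) == set(rec.coefficients)
            assert f.intercept == pytest.approx(rec.intercept, rel=1e-6, abs=1e-8)
            for name, beta in rec.coefficients.items():
                assert f.coefficients[name] == pytest.approx(beta, rel=1e-6, abs=1e-8)

    def test_rmse_tracks_injected_noise_scale(self, noisy_dataset):
        fitted = fit_dataset(
            noisy_dataset.predictor_frame(), noisy_dataset.keypoint_frame()
        )
        checked = 0
        for rec in noisy_dataset.generating_table:
            if rec.is_constant or rec.rmse == 0:
                continue
            f = fitted.get(rec.keypoint_id, rec.parameter)
            assert f.rmse == pytest.approx(rec.rmse, rel=0.30)
            checked += 1
        assert checked == 36  # every non-constant timing/angle equation

    def test_deterministic_given_input(self, noiseless_dataset):
        args = (noiseless_dataset.predictor_frame(), noiseless_dataset.keypoint_frame())
        t1, t2 = fit_dataset(*args), fit_dataset(*args)
        for rec in t1:
            other = t2.get(rec.keypoint_id, rec.parameter)
            assert rec.intercept == other.intercept
            assert rec.coefficients == other.coefficients

    def test_rmse_recomputable_from_residuals(self, noisy_dataset):
        predictors = noisy_dataset.predictor_frame()
        keypoints = noisy_dataset.keypoint_frame()
        fitted = fit_dataset(predictors, keypoints)
        rec = fitted.get("KNS6", "angle")
        sub = keypoints[keypoints.keypoint_id == "KNS6"]
        X = predictors.loc[sub["trial"]]
        pred = rec.intercept + sum(
            beta * X[name].to_numpy() for name, beta in rec.coefficients.items()
        )
        resid = sub["angle"].to_numpy() - pred
        assert rec.rmse == pytest.approx(np.sqrt(np.mean(resid**2)), rel=1e-9)


class TestRecordSemantics:
    def test_ns_predictors_contribute_exactly_zero(self):
        rec = RegressionRecord("ANS1", "angle", -1.2223, {"sex": 1.0414})
        p0 = gn.PredictorVector(0.3, 40, 0, 20)
        p1 = gn.PredictorVector(0.9, 70, 0, 35)  # speed/age/bmi all changed
        assert rec.predict(p0) == rec.predict(p1)

    def test_constant_record_ignores_predictors(self):
        rec = RegressionRecord("HIS1", "timing", 1.0, {}, rmse=0.0, is_constant=True)
        assert rec.predict(gn.PredictorVector(0.5, 30, 1, 25)) == 1.0

    def test_duplicate_records_rejected(self):
        rec = RegressionRecord("HIS1", "angle", 0.0)
        table = CoefficientTable([rec])
        with pytest.raises(ValueError):
            table.add(rec)
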