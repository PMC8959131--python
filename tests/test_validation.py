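"""Validation battery: fitting stats, cross-validation, external predictivity,
K indices, Y-scrambling and the Williams applicability domain."""

import numpy as np
import pandas as pd
import pytest

from gaqsar.model_search import fit_mlr, q2_loo
from gaqsar.validation import (DEFAULT_THRESHOLDS, ValidationReport, ccc,
                               check_thresholds, external_stats, internal_stats,
                               k_indices, q2_lmo, rm2_metrics, validate_model,
                               williams_domain, y_scramble)

from conftest import random_regression_problem
from oracles import (ccc_oracle, k_index_oracle, leverage_oracle, q2f_oracle,
                     press_loo_refit, q2_loo_refit, r2_oracle, rm2_oracle)


class TestInternalStats:
    def test_perfect_fit_limits(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = 2.0 + X @ np.array([1.0, -1.0, 0.5])
        stats = internal_stats(fit_mlr(X, y), X, y)
        assert stats["r2"] == pytest.approx(1.0, abs=1e-12)
        assert stats["rmse_tr"] == pytest.approx(0.0, abs=1e-10)

    def test_adjusted_r2_never_exceeds_r2(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X, y = random_regression_problem(rng, with_external=False)
            stats = internal_stats(fit_mlr(X, y), X, y)
            assert stats["r2_adj"] <= stats["r2"] + 1e-12

    def test_shuffled_response_r2_near_chance_level(self):
        # for pure noise E[R^2] = p / (n - 1)
        rng = np.random.default_rng(2)
        n, p = 40, 4
        vals = [
            internal_stats(
                fit_mlr(X := rng.normal(size=(n, p)), y := rng.normal(size=n)),
                X, y)["r2"]
            for _ in range(300)
        ]
        assert np.mean(vals) == pytest.approx(p / (n - 1), abs=0.03)

    def test_rmse_cv_inflates_over_training_rmse(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            X, y = random_regression_problem(rng, with_external=False)
            stats = internal_stats(fit_mlr(X, y), X, y)
            assert stats["rmse_cv"] >= stats["rmse_tr"]


class TestQ2Lmo:
    def test_noiseless_limit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = 1.0 + X @ np.array([1.0, 2.0, -0.5])
        assert q2_lmo(X, y, 0.3, 200, seed=0) == pytest.approx(1.0, abs=1e-10)

    def test_bounded_by_loo_on_well_conditioned_data(self):
        rng = np.random.default_rng(5)
        X, y = random_regression_problem(rng, n=60, p=4, with_external=False)
        assert q2_lmo(X, y, 0.3, 500, seed=1) <= q2_loo(X, y) + 0.05

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        X, y = random_regression_problem(rng, n=50, p=3, with_external=False)
        assert q2_lmo(X, y, 0.3, 100, seed=7) == q2_lmo(X, y, 0.3, 100, seed=7)

    def test_fraction_bounds(self):
        rng = np.random.default_rng(7)
        X, y = random_regression_problem(rng, n=30, p=2, with_external=False)
        with pytest.raises(ValueError):
            q2_lmo(X, y, 0.7, 100)


class TestExternalStats:
    def test_identity_predictions(self):
        rng = np.random.default_rng(8)
        X, y, X_ex, y_ex = random_regression_problem(rng)
        model = fit_mlr(X, y)
        # craft an external block whose predictions equal observations
        y_fake = model.predict(X_ex)
        stats = external_stats(model, X_ex, y_fake, y)
        assert stats["ccc_ex"] == pytest.approx(1.0)
        assert stats["q2_f2"] == pytest.approx(1.0)
        assert stats["rm2_delta"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_penalized_by_ccc_only(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=40)
        shifted = y + 1.5
        assert ccc(y, shifted) < 1.0
        assert np.corrcoef(y, shifted)[0, 1] ** 2 == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ccc(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            rm2_metrics(np.ones(10), np.arange(10.0))


class TestKIndices:
    def test_orthogonal_columns_zero_index(self):
        # exactly orthogonal, centred columns -> uniform eigenvalues -> K = 0
        q, _ = np.linalg.qr(np.random.default_rng(10).normal(size=(40, 4)))
        q = q - q.mean(axis=0)
        q, _ = np.linalg.qr(q)  # re-orthogonalize after centring
        kxx, _ = k_indices(np.column_stack([q[:, :3]]), q[:, 3])
        assert kxx == pytest.approx(0.0, abs=1e-8)

    def test_collinear_pair_saturates(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        kxx, _ = k_indices(np.column_stack([x, 3 * x]), rng.normal(size=30))
        assert kxx == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            k_indices(np.column_stack([np.ones(20), rng.normal(size=20)]),
                      rng.normal(size=20))


class TestYScramble:
    def test_seed_determinism(self):
        rng = np.random.default_rng(13)
        X, y = random_regression_problem(rng, n=40, p=3, with_external=False)
        assert y_scramble(X, y, 200, seed=3) == y_scramble(X, y, 200, seed=3)

    def test_strong_signal_large_gap(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 4))
        y = 1.0 + X @ np.array([1.5, -1.0, 0.8, 0.5]) + rng.normal(scale=0.4, size=60)
        model_r2 = internal_stats(fit_mlr(X, y), X, y)["r2"]
        r2_scr, _ = y_scramble(X, y, 300, seed=4)
        assert model_r2 - r2_scr > 0.4

    def test_pure_noise_response_shows_no_gap(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        model_r2 = internal_stats(fit_mlr(X, y), X, y)["r2"]
        r2_scr, _ = y_scramble(X, y, 500, seed=5)
        assert abs(model_r2 - r2_scr) < 0.15


class TestWilliamsDomain:
    def test_training_leverages_sum_to_p_plus_one(self):
        rng = np.random.default_rng(16)
        X, y = random_regression_problem(rng, n=50, p=4, with_external=False)
        model = fit_mlr(X, y)
        domain = williams_domain(model, X, X, y, y)
        assert domain["leverage"].sum() == pytest.approx(5.0, abs=1e-8)

    def test_centroid_query_leverage_is_one_over_n(self):
        rng = np.random.default_rng(17)
        X, y = random_regression_problem(rng, n=40, p=3, with_external=False)
        model = fit_mlr(X, y)
        domain = williams_domain(model, X, X.mean(axis=0, keepdims=True), y)
        assert domain["leverage"].iloc[0] == pytest.approx(1.0 / 40, abs=1e-10)

    def test_warning_leverage_at_study_scale(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(157, 6))
        y = rng.normal(size=157) + X[:, 0]
        domain = williams_domain(fit_mlr(X, y), X, X, y, y)
        assert domain.attrs["h_star"] == pytest.approx(21 / 157)
        assert domain.attrs["h_star"] == pytest.approx(0.1338, abs=5e-5)

    def test_outlier_flagged_out_of_domain(self):
        rng = np.random.default_rng(19)
        X, y = random_regression_problem(rng, n=50, p=3, with_external=False)
        model = fit_mlr(X, y)
        far = X.mean(axis=0, keepdims=True) + 50 * X.std(axis=0, keepdims=True)
        domain = williams_domain(model, X, far, y)
        assert not domain["in_domain"].iloc[0]

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(20)
        X, y, X_ex, _ = random_regression_problem(rng)
        model = fit_mlr(X, y)
        domain = williams_domain(model, X, X_ex, y)
        np.testing.assert_allclose(domain["leverage"], leverage_oracle(X, X_ex),
                                   atol=1e-10)


class TestOracleBattery:
    def test_every_statistic_matches_from_scratch_oracle(self):
        """All implemented statistics agree with naive loop/refit reference
        implementations to 1e-10 on many random problems."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            X, y, X_ex, y_ex = random_regression_problem(rng)
            model = fit_mlr(X, y)
            yhat = model.predict(X)
            stats = internal_stats(model, X, y)
            assert stats["r2"] == pytest.approx(r2_oracle(y, yhat), abs=1e-10)
            assert stats["press_cv"] == pytest.approx(press_loo_refit(X, y), rel=1e-10)
            assert stats["q2_loo"] == pytest.approx(q2_loo_refit(X, y), abs=1e-10)
            assert stats["ccc_tr"] == pytest.approx(ccc_oracle(y, yhat), abs=1e-10)
            ext = external_stats(model, X_ex, y_ex, y)
            yhat_ex = model.predict(X_ex)
            f1, f2, f3 = q2f_oracle(y_ex, yhat_ex, y)
            assert ext["q2_f1"] == pytest.approx(f1, abs=1e-10)
            assert ext["q2_f2"] == pytest.approx(f2, abs=1e-10)
            assert ext["q2_f3"] == pytest.approx(f3, abs=1e-10)
            assert ext["ccc_ex"] == pytest.approx(ccc_oracle(y_ex, yhat_ex), abs=1e-10)
            roy = rm2_oracle(y_ex, yhat_ex)
            assert ext["k_slope"] == pytest.approx(roy["k"], abs=1e-10)
            assert ext["k_slope_prime"] == pytest.approx(roy["k_prime"], abs=1e-10)
            assert ext["r2o"] == pytest.approx(roy["r2o"], abs=1e-10)
            assert ext["rm2_avg"] == pytest.approx(roy["rm2_avg"], abs=1e-10)
            assert ext["rm2_delta"] == pytest.approx(roy["rm2_delta"], abs=1e-10)
            kxx, dk = k_indices(X, y)
            assert kxx == pytest.approx(k_index_oracle(X), abs=1e-10)
            kxy = k_index_oracle(np.column_stack([X, y]))
            assert dk == pytest.approx(kxy - k_index_oracle(X), abs=1e-10)


class TestReportAndThresholds:
    def test_validate_model_fills_report_and_flags(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame(rng.normal(size=(80, 4)),
                         columns=[f"d{j}" for j in range(4)])
        y = 1.0 + X.to_numpy() @ np.array([1.2, -0.8, 0.6, 1.0]) \
            + rng.normal(scale=0.4, size=80)
        X_ex = pd.DataFrame(rng.normal(size=(20, 4)), columns=X.columns)
        y_ex = 1.0 + X_ex.to_numpy() @ np.array([1.2, -0.8, 0.6, 1.0]) \
            + rng.normal(scale=0.4, size=20)
        model = fit_mlr(X, y)
        report = validate_model(model, X, y, X_ex, y_ex,
                                lmo_iterations=100, n_scrambles=100, seed=0)
        values = report.to_dict()
        assert all(np.isfinite(v) for v in values.values())
        flags = check_thresholds(report)
        assert flags["r2"] and flags["q2_loo"] and flags["rmse_tr_lt_cv"]

    def test_unmet_threshold_flags_false(self):
        report = ValidationReport(r2=0.3, q2_loo=0.2)
        flags = check_thresholds(report, {"r2": (">=", 0.6), "q2_loo": (">=", 0.5)})
        assert not flags["r2"] and not flags["q2_loo"]
        assert flags["r2_gt_q2"]  # derived condition still evaluated
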