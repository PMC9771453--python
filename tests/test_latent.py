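"""FIML CFA/SEM: gradient correctness, parameter recovery, fit indices,
factor scores, and likelihood invariants."""

import numpy as np
import pandas as pd
import pytest

from cogmaturity import latent
from cogmaturity.latent import (
    MeasurementSpec,
    compute_fit_indices,
    extract_factor_scores,
    fit_cfa,
    fit_sem,
    fiml_loglik,
    mvn_loglik,
)

TABLE_LOADINGS = np.array([0.650, -0.503, -0.913, -0.371, 0.193])
COLS = list("abcde")
ONE_FACTOR = MeasurementSpec(loadings={"F": tuple(COLS)})


def one_factor_sigma(lams=TABLE_LOADINGS):
    return np.outer(lams, lams) + np.diag(1 - lams**2)


def exact_cov_data(Sigma, n, seed=0):
    """Rows whose ML sample covariance equals Sigma exactly (zero mean)."""
    p = Sigma.shape[0]
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    Z -= Z.mean(axis=0)
    C = Z.T @ Z / n
    Z = Z @ np.linalg.inv(np.linalg.cholesky(C)).T @ np.linalg.cholesky(Sigma).T
    return Z


def align_to(reference, estimate):
    """Resolve factor reflection: flip the estimate if it opposes the
    reference loading vector."""
    return estimate if reference @ estimate >= 0 else -estimate


class TestSpecValidation:
    def test_cross_loading_rejected(self):
        with pytest.raises(ValueError, match="two factors"):
            MeasurementSpec(loadings={"F": ("a", "b"), "G": ("b", "c")})

    def test_unknown_residual_covariance_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            MeasurementSpec(loadings={"F": ("a", "b")}, residual_covariances=(("a", "x"),))

    def test_single_indicator_warns(self):
        with pytest.warns(UserWarning, match="single indicator"):
            MeasurementSpec(loadings={"F": ("a",), "G": ("b", "c")})

    def test_serialization_round_trip(self):
        spec = latent.ads_measurement_spec()
        assert MeasurementSpec.from_dict(spec.to_dict()) == spec


class TestGradient:
    @pytest.mark.parametrize("with_missing", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, with_missing):
        rng = np.random.default_rng(12)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=120)
        if with_missing:
            X[rng.random(X.shape) < 0.2] = np.nan
        spec = MeasurementSpec(
            loadings={"F": tuple(COLS)}, residual_covariances=(("a", "b"),)
        )
        struct = latent._Structure(spec)
        patterns, _ = latent._prepare_patterns(X)
        theta = latent._start_values(struct, X) + 0.01 * rng.standard_normal(struct.n_params)
        _, g = latent._fiml_negloglik_grad(theta, struct, patterns)
        for i in range(struct.n_params):
            h = 1e-6 * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fp, _ = latent._fiml_negloglik_grad(tp, struct, patterns)
            fm, _ = latent._fiml_negloglik_grad(tm, struct, patterns)
            assert g[i] == pytest.approx((fp - fm) / (2 * h), rel=1e-4, abs=1e-4)

    def test_sem_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(13)
        spec = MeasurementSpec(loadings={"F": ("a", "b", "c"), "G": ("d", "e")})
        Sigma = one_factor_sigma()
        X = rng.multivariate_normal(np.zeros(5), Sigma, size=100)
        struct = latent._Structure(spec, paths=(("F", "G"),))
        patterns, _ = latent._prepare_patterns(X)
        theta = latent._start_values(struct, X)
        theta[struct.sl_path] = 0.3
        _, g = latent._fiml_negloglik_grad(theta, struct, patterns)
        for i in range(struct.n_params):
            h = 1e-6 * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fp, _ = latent._fiml_negloglik_grad(tp, struct, patterns)
            fm, _ = latent._fiml_negloglik_grad(tm, struct, patterns)
            assert g[i] == pytest.approx((fp - fm) / (2 * h), rel=1e-4, abs=1e-4)


class TestCFARecovery:
    def test_exact_fit_fixed_point(self):
        """Data whose sample covariance equals the model-implied covariance:
        loadings recovered to 1e-6, chi-square ~ 0, CFI = 1, RMSEA = 0."""
        X = exact_cov_data(one_factor_sigma(), n=200, seed=1)
        fit = fit_cfa(ONE_FACTOR, pd.DataFrame(X, columns=COLS), compute_se=False)
        est = align_to(TABLE_LOADINGS, fit.loadings["estimate"].to_numpy())
        np.testing.assert_allclose(est, TABLE_LOADINGS, atol=1e-6)
        assert fit.fit["chi2"] == pytest.approx(0.0, abs=1e-6)
        assert fit.fit["cfi"] == 1.0
        assert fit.fit["rmsea"] == 0.0

    def test_large_sample_recovery_within_tolerance(self):
        rng = np.random.default_rng(2)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=5000)
        fit = fit_cfa(ONE_FACTOR, pd.DataFrame(X, columns=COLS))
        est = align_to(TABLE_LOADINGS, fit.loadings["estimate"].to_numpy())
        np.testing.assert_allclose(est, TABLE_LOADINGS, atol=0.05)
        assert (np.sign(est) == np.sign(TABLE_LOADINGS)).all()
        assert fit.se_available
        assert (fit.loadings["se"] < 0.05).all()

    def test_fiml_under_mcar_close_to_complete_data(self):
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=3000)
        full = fit_cfa(ONE_FACTOR, pd.DataFrame(X, columns=COLS), compute_se=False)
        Xm = X.copy()
        Xm[rng.random(X.shape) < 0.3] = np.nan
        miss = fit_cfa(ONE_FACTOR, pd.DataFrame(Xm, columns=COLS), compute_se=False)
        a = align_to(TABLE_LOADINGS, full.loadings["estimate"].to_numpy())
        b = align_to(TABLE_LOADINGS, miss.loadings["estimate"].to_numpy())
        # MC sd of a loading at n=3000 is ~0.015; allow 2 sds of extra noise
        np.testing.assert_allclose(a, b, atol=0.06)

    def test_complete_data_fiml_equals_mvn_loglik(self):
        rng = np.random.default_rng(4)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=400)
        fit = fit_cfa(ONE_FACTOR, pd.DataFrame(X, columns=COLS), compute_se=False)
        assert fit.loglik == pytest.approx(mvn_loglik(X, fit.mu, fit.Sigma), rel=1e-10)

    def test_likelihood_at_solution_beats_generating_parameters(self):
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=300)
        Xm = X.copy()
        Xm[rng.random(X.shape) < 0.15] = np.nan
        fit = fit_cfa(ONE_FACTOR, pd.DataFrame(Xm, columns=COLS), compute_se=False)
        struct = latent._Structure(ONE_FACTOR)
        theta_true = np.zeros(struct.n_params)
        theta_true[struct.sl_load] = TABLE_LOADINGS
        theta_true[struct.sl_logtheta] = np.log(1 - TABLE_LOADINGS**2)
        assert fit.loglik >= fiml_loglik(theta_true, struct, Xm) - 1e-8

    def test_standardized_solution_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(6)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=800)
        df = pd.DataFrame(X, columns=COLS)
        fit1 = fit_cfa(ONE_FACTOR, df, compute_se=False)
        df2 = df.copy()
        df2["a"] = 7.0 * df2["a"] - 3.0
        df2["c"] = 0.01 * df2["c"] + 100.0
        fit2 = fit_cfa(ONE_FACTOR, df2, compute_se=False)
        s1 = align_to(TABLE_LOADINGS, fit1.loadings["std_estimate"].to_numpy())
        s2 = align_to(TABLE_LOADINGS, fit2.loadings["std_estimate"].to_numpy())
        np.testing.assert_allclose(s1, s2, atol=1e-3)
        assert fit1.fit["chi2"] == pytest.approx(fit2.fit["chi2"], abs=1e-4)

    def test_missing_indicator_column_errors(self):
        with pytest.raises(ValueError, match="missing indicator columns"):
            fit_cfa(ONE_FACTOR, pd.DataFrame({"a": [1.0, 2.0]}))


class TestFitIndices:
    def test_exact_fit_limit(self):
        f = compute_fit_indices(40.0, 40, 500.0, 55, 300)
        assert f["rmsea"] == 0.0
        assert f["cfi"] == 1.0

    def test_closed_form_oracle(self):
        chi2, df, chi2_0, df_0, n = 50.0, 40, 500.0, 55, 300
        f = compute_fit_indices(chi2, df, chi2_0, df_0, n)
        assert f["rmsea"] == pytest.approx(np.sqrt((chi2 - df) / (df * (n - 1))), abs=1e-12)
        assert f["cfi"] == pytest.approx(1 - (chi2 - df) / (chi2_0 - df_0), abs=1e-12)
        assert f["tli"] == pytest.approx(
            ((chi2_0 / df_0) - (chi2 / df)) / ((chi2_0 / df_0) - 1), abs=1e-12
        )

    def test_tli_can_exceed_one_when_chi2_below_df(self):
        f = compute_fit_indices(30.0, 40, 500.0, 55, 300)
        assert f["tli"] > 1.0

    def test_df_zero_reported_undefined(self):
        f = compute_fit_indices(0.0, 0, 100.0, 10, 200)
        assert np.isnan(f["rmsea"]) and np.isnan(f["tli"])


class TestFactorScores:
    def test_single_indicator_identity_limit(self):
        # loading 1, residual ~0: the regression score is the indicator itself
        rng = np.random.default_rng(7)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x})
        fitted = latent.FittedLatentModel(
            spec=MeasurementSpec(loadings={"F": ("a",)}),
            kind="cfa", indicators=["a"], factors=["F"],
            theta=np.zeros(1), mu=np.zeros(1),
            Lambda=np.array([[1.0]]), Theta=np.array([[1e-12]]),
            Psi=np.array([[1.0]]), Sigma=np.array([[1.0 + 1e-12]]),
            loglik=0.0, n_obs=50, n_params=0, fit={},
            loadings=pd.DataFrame(), residual_variances=pd.DataFrame(),
            residual_covariances=pd.DataFrame(), paths=pd.DataFrame(),
            converged=True, n_iter=0, message="",
        )
        scores = extract_factor_scores(fitted, df, standardize=False)
        np.testing.assert_allclose(scores.scores["F"], x, atol=1e-9)

    def test_complete_data_scores_equal_matrix_product(self):
        rng = np.random.default_rng(8)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=300)
        df = pd.DataFrame(X, columns=COLS)
        fit = fit_cfa(ONE_FACTOR, df, compute_se=False)
        scores = extract_factor_scores(fit, df, standardize=False).scores["F"].to_numpy()
        W = fit.Psi @ fit.Lambda.T @ np.linalg.inv(fit.Sigma)
        oracle = (X - fit.mu) @ W.T
        np.testing.assert_allclose(scores, oracle[:, 0], atol=1e-10)

    def test_bartlett_scores_unbiased_weighting(self):
        rng = np.random.default_rng(9)
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=300)
        df = pd.DataFrame(X, columns=COLS)
        fit = fit_cfa(ONE_FACTOR, df, compute_se=False)
        s = extract_factor_scores(fit, df, method="bartlett", standardize=False).scores
        Tinv = np.linalg.inv(fit.Theta)
        W = np.linalg.pinv(fit.Lambda.T @ Tinv @ fit.Lambda) @ fit.Lambda.T @ Tinv
        np.testing.assert_allclose(s["F"], ((X - fit.mu) @ W.T)[:, 0], atol=1e-10)

    def test_score_truth_correlation_at_n1000(self):
        rng = np.random.default_rng(10)
        f = rng.standard_normal(1000)
        X = np.outer(f, TABLE_LOADINGS) + rng.standard_normal((1000, 5)) * np.sqrt(
            1 - TABLE_LOADINGS**2
        )
        df = pd.DataFrame(X, columns=COLS)
        fit = fit_cfa(ONE_FACTOR, df, compute_se=False)
        s = extract_factor_scores(fit, df).scores["F"]
        assert abs(np.corrcoef(s, f)[0, 1]) >= 0.8

    def test_all_indicators_of_factor_missing_gives_missing_score(self):
        rng = np.random.default_rng(11)
        spec = MeasurementSpec(loadings={"F": ("a", "b", "c"), "G": ("d", "e")})
        X = rng.multivariate_normal(np.zeros(5), one_factor_sigma(), size=200)
        X[:10, 3:] = np.nan  # factor G unobserved for the first 10 rows
        df = pd.DataFrame(X, columns=COLS)
        fit = fit_cfa(spec, df, compute_se=False)
        s = extract_factor_scores(fit, df)
        assert s.scores["G"].iloc[:10].isna().all()
        assert s.scores["F"].iloc[:10].notna().all()
        assert s.n_missing["G"] == 10


class TestSEM:
    def _two_factor_spec(self):
        return MeasurementSpec(
            loadings={"F": ("a", "b", "c"), "G": ("d", "e", "f")}
        )

    def _two_factor_sigma(self, path=0.0):
        lamF = np.array([0.8, 0.7, 0.6])
        lamG = np.array([0.75, 0.65, 0.55])
        Lam = np.zeros((6, 2))
        Lam[:3, 0] = lamF
        Lam[3:, 1] = lamG
        B = np.array([[0.0, 0.0], [path, 0.0]])
        A = np.linalg.inv(np.eye(2) - B)
        Psi = A @ A.T
        Theta = np.diag(1 - np.concatenate([lamF, lamG]) ** 2)
        return Lam @ Psi @ Lam.T + Theta

    def test_sem_without_paths_reproduces_cfa(self):
        rng = np.random.default_rng(14)
        Sigma = self._two_factor_sigma(path=0.4)
        X = rng.multivariate_normal(np.zeros(6), Sigma, size=600)
        df = pd.DataFrame(X, columns=list("abcdef"))
        spec = self._two_factor_spec()
        cfa = fit_cfa(spec, df, compute_se=False)
        sem = fit_sem(spec, df, paths=(), disturbance_covariances=(), compute_se=False)
        assert sem.loglik == pytest.approx(cfa.loglik, abs=1e-5)
        np.testing.assert_allclose(np.abs(sem.Psi), np.abs(cfa.Psi), atol=1e-4)

    def test_generating_path_recovered(self):
        rng = np.random.default_rng(15)
        Sigma = self._two_factor_sigma(path=-0.22)
        X = rng.multivariate_normal(np.zeros(6), Sigma, size=5000)
        df = pd.DataFrame(X, columns=list("abcdef"))
        fit = fit_sem(self._two_factor_spec(), df, paths=(("F", "G"),),
                      disturbance_covariances=())
        assert fit.paths["estimate"].iloc[0] == pytest.approx(-0.22, abs=0.06)
        assert fit.paths["z"].iloc[0] < -2

    def test_zero_path_estimated_near_zero(self):
        rng = np.random.default_rng(16)
        Sigma = self._two_factor_sigma(path=0.0)
        X = rng.multivariate_normal(np.zeros(6), Sigma, size=2000)
        df = pd.DataFrame(X, columns=list("abcdef"))
        fit = fit_sem(self._two_factor_spec(), df, paths=(("F", "G"),),
                      disturbance_covariances=())
        assert abs(fit.paths["estimate"].iloc[0]) < 0.08

    def test_cyclic_paths_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            latent._Structure(self._two_factor_spec(), paths=(("F", "G"), ("G", "F")))


class TestEndToEndLoadingSigns:
    def test_fitted_loading_signs_match_generator_for_strong_indicators(self):
        """Simulate -> score -> CFA with the default growth spec: every
        indicator whose generating |loading| >= 0.3 is recovered with the
        generating sign (after resolving each factor's reflection)."""
        import cogmaturity as cm
        from cogmaturity import scoring

        b = cm.generate_cohort(cm.CohortConfig(n_participants=141, seed=31))
        retained, _ = scoring.apply_exclusions(b.cohort)
        raw = scoring.score_bundle(
            cm.CohortBundle(retained, b.trials, b.truth, b.config, b.growth)
        )
        matrix = scoring.build_indicator_matrix(raw)
        fit = fit_cfa(latent.ads_measurement_spec(), matrix, compute_se=False)
        gen = {ind: lam for ind, (fac, lam) in b.growth.loadings.items()}
        table = fit.loadings.set_index("indicator")
        for factor, grp in fit.loadings.groupby("factor"):
            g = np.array([gen[i] for i in grp["indicator"]])
            e = grp["estimate"].to_numpy()
            if g @ e < 0:  # reflection
                e = -e
            strong = np.abs(g) >= 0.3
            assert (np.sign(e[strong]) == np.sign(g[strong])).all(), factor


class TestCovariateAssociation:
    def test_known_slope_recovered(self):
        rng = np.random.default_rng(17)
        x = pd.Series(rng.standard_normal(500), name="age")
        y = pd.Series(0.5 * x + rng.standard_normal(500) * 0.3, name="score")
        out = latent.score_covariate_association(y, x)
        assert out["estimate"] == pytest.approx(0.5, abs=0.05)
        assert out["p"] < 1e-10
        assert out["method"] == "score_on_covariate"
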