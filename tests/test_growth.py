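"""FIML growth model: oracle equivalences, analytic-gradient correctness,
parameter recovery, cluster-robust inference, fit indices, likelihood-ratio
tests and factor scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diffgrowth as dg
from diffgrowth.growth import (
    DEFAULT_TIMES, GrowthModelError, GrowthSpec, MomentsFit, _Layout,
    _ModelData, _loglik_core, _prepare, _score_matrix, factor_scores,
    fit_baseline, fit_growth, fit_indices, fit_saturated, fiml_loglik,
    implied_moments, lrt, measurement_fit, simulate_growth,
)

SPEC_PLAIN = GrowthSpec(outcome="diff", covariates=(),
                        include_age_deviation=False)

THETA_PLAIN = {
    "alpha_I": 0.1, "alpha_S": 0.05,
    "psi_I_I": 1.0, "psi_I_S": 0.2, "psi_S_S": 0.1,
    "theta_w1": 0.6, "theta_w2": 1.2, "theta_w3": 0.9,
}


def _lam():
    return np.column_stack([np.ones(3), np.asarray(DEFAULT_TIMES)])


class TestImpliedMoments:
    def test_deterministic_limit(self):
        th = dict(THETA_PLAIN, psi_I_I=0, psi_I_S=0, psi_S_S=0,
                  theta_w1=0, theta_w2=0, theta_w3=0)
        mu, Sigma = implied_moments(SPEC_PLAIN, th)
        t = np.asarray(DEFAULT_TIMES)
        assert np.allclose(mu, 0.1 + 0.05 * t)
        assert np.allclose(Sigma, 0.0)

    def test_unit_case_hand_algebra(self):
        th = dict(THETA_PLAIN, alpha_I=0, alpha_S=0, psi_I_I=1, psi_I_S=0,
                  psi_S_S=1, theta_w1=1, theta_w2=1, theta_w3=1)
        mu, Sigma = implied_moments(SPEC_PLAIN, th)
        L = _lam()
        assert np.allclose(Sigma, L @ L.T + np.eye(3))
        # entry (3,3): 1*1 + 0*0 + 1 = 2 (time score at age 5 is 0)
        assert Sigma[2, 2] == pytest.approx(2.0)
        assert np.allclose(mu, 0.0)

    def test_matches_simulation_moments(self, rng):
        n = 400_000
        data = simulate_growth(
            n, rng, alpha=(0.1, 0.05), psi=((1.0, 0.2), (0.2, 0.1)),
            theta=(0.6, 1.2, 0.9),
        )
        Y = data[["diff_1", "diff_2", "diff_3"]].to_numpy()
        mu, Sigma = implied_moments(SPEC_PLAIN, THETA_PLAIN)
        mc_se = 3.0 / np.sqrt(n)
        assert np.abs(Y.mean(axis=0) - mu).max() < 4 * mc_se
        assert np.abs(np.cov(Y.T) - Sigma).max() < 6 * mc_se

    def test_wrong_dimension_rejected(self):
        with pytest.raises(GrowthModelError, match="dimension"):
            implied_moments(SPEC_PLAIN, np.zeros(3))


class TestFimlLoglik:
    def test_complete_data_equals_dense_mvn(self, rng):
        data = simulate_growth(200, rng)
        mu, Sigma = implied_moments(SPEC_PLAIN, THETA_PLAIN)
        Y = data[["diff_1", "diff_2", "diff_3"]].to_numpy()
        dense = stats.multivariate_normal(mu, Sigma).logpdf(Y).sum()
        assert fiml_loglik(data, SPEC_PLAIN, THETA_PLAIN) == pytest.approx(
            dense, abs=1e-10 * abs(dense)
        )

    def test_single_wave_child_is_univariate_density(self):
        data = pd.DataFrame({"diff_1": [np.nan], "diff_2": [np.nan],
                             "diff_3": [1.3], "child_id": [0], "mother_id": [0]})
        mu, Sigma = implied_moments(SPEC_PLAIN, THETA_PLAIN)
        expected = stats.norm(mu[2], np.sqrt(Sigma[2, 2])).logpdf(1.3)
        assert fiml_loglik(data, SPEC_PLAIN, THETA_PLAIN) == pytest.approx(expected)

    def test_mixed_patterns_match_brute_force_oracle(self):
        """Five children, assorted missingness; oracle marginalises by
        explicit submatrix inversion per child."""
        Y = np.array([
            [0.5, -0.2, 1.1],
            [np.nan, 0.3, -0.7],
            [0.9, np.nan, np.nan],
            [np.nan, np.nan, 2.0],
            [-1.2, 0.8, np.nan],
        ])
        data = pd.DataFrame(Y, columns=["diff_1", "diff_2", "diff_3"])
        data["child_id"] = range(5)
        data["mother_id"] = range(5)
        mu, Sigma = implied_moments(SPEC_PLAIN, THETA_PLAIN)
        oracle = 0.0
        for i in range(5):
            o = ~np.isnan(Y[i])
            k = o.sum()
            S = Sigma[np.ix_(o, o)]
            r = Y[i, o] - mu[o]
            oracle += -0.5 * (
                k * np.log(2 * np.pi)
                + np.log(np.linalg.det(S))
                + r @ np.linalg.inv(S) @ r
            )
        assert fiml_loglik(data, SPEC_PLAIN, THETA_PLAIN) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_singular_pattern_reported(self):
        th = dict(THETA_PLAIN, psi_I_I=0.0, psi_I_S=0.0, psi_S_S=0.0,
                  theta_w3=0.0)
        data = pd.DataFrame({"diff_1": [0.1], "diff_2": [0.2], "diff_3": [0.3],
                             "child_id": [0], "mother_id": [0]})
        with pytest.raises(GrowthModelError, match="pattern"):
            fiml_loglik(data, SPEC_PLAIN, th)


class TestGradients:
    def _spec_rich(self):
        return GrowthSpec(outcome="diff", covariates=("sex", "parity"),
                          predictors=("x_1",), symptoms=("s_hyp",))

    def _data_rich(self, rng, n=150):
        data = simulate_growth(n, rng, kappa=0.1, age_jitter_sd=0.1)
        data["sex"] = rng.integers(0, 2, n)
        data["parity"] = rng.integers(0, 3, n)
        data["x_1"] = rng.normal(size=n)
        data["s_hyp"] = 0.2 * data["eta_I_true"] + rng.normal(size=n)
        data.loc[rng.choice(n, n // 5, replace=False),
                 ["diff_2", "age_2"]] = np.nan
        data.loc[rng.choice(n, n // 6, replace=False), "s_hyp"] = np.nan
        return data

    @pytest.mark.parametrize("natural", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, rng, natural):
        spec = self._spec_rich()
        data = self._data_rich(rng)
        layout = _Layout(spec, list(spec.covariates) + list(spec.predictors),
                         list(spec.symptoms))
        md = _prepare(data, spec, layout)
        rng2 = np.random.default_rng(5)
        if natural:
            vec = layout.u_to_natural(rng2.normal(0, 0.3, layout.p))
        else:
            vec = rng2.normal(0, 0.3, layout.p)
        ll, g = _loglik_core(vec, layout, md, natural=natural, want_grad=True)
        fd = np.empty(layout.p)
        for i in range(layout.p):
            h = 1e-6 * max(1, abs(vec[i]))
            vp, vm = vec.copy(), vec.copy()
            vp[i] += h
            vm[i] -= h
            fd[i] = (
                _loglik_core(vp, layout, md, natural=natural, want_grad=False)[0]
                - _loglik_core(vm, layout, md, natural=natural, want_grad=False)[0]
            ) / (2 * h)
        assert np.allclose(g, fd, rtol=1e-5, atol=1e-5)

    def test_score_matrix_sums_to_gradient(self, rng):
        spec = self._spec_rich()
        data = self._data_rich(rng)
        layout = _Layout(spec, list(spec.covariates) + list(spec.predictors),
                         list(spec.symptoms))
        md = _prepare(data, spec, layout)
        vec = layout.u_to_natural(np.random.default_rng(5).normal(0, 0.3, layout.p))
        _, g = _loglik_core(vec, layout, md, natural=True, want_grad=True)
        scores = _score_matrix(vec, layout, md)
        assert np.allclose(scores.sum(axis=0), g, rtol=1e-8, atol=1e-8)


class TestFitGrowth:
    def test_parameter_recovery_within_three_se(self, rng):
        n = 20_000
        data = simulate_growth(n, rng, alpha=(0.1, 0.05),
                               psi=((1.0, 0.2), (0.2, 0.1)),
                               theta=(0.6, 1.2, 0.9))
        fit = fit_growth(data, SPEC_PLAIN)
        se = fit.se()
        for name, truth in THETA_PLAIN.items():
            assert abs(fit.estimates[name] - truth) < 3 * se[name], name

    def test_factor_means_satisfy_gls_identity_on_balanced_data(self, rng):
        """With complete balanced data the MLE factor means equal the GLS
        estimate from the wave means at the fitted covariance."""
        data = simulate_growth(3000, rng)
        fit = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        pars = fit.params()
        L = _lam()
        from diffgrowth.growth import _build_sigma
        Sigma = _build_sigma(fit._layout, pars["Psi"], pars["Lam"],
                             pars["theta"], pars["offdiag"])
        ybar = data[["diff_1", "diff_2", "diff_3"]].mean().to_numpy()
        W = np.linalg.inv(Sigma)
        gls = np.linalg.solve(L.T @ W @ L, L.T @ W @ ybar)
        assert np.allclose(pars["alpha"], gls, atol=1e-5)

    def test_doubling_weights_leaves_estimates_unchanged(self, rng):
        data = simulate_growth(800, rng)
        data["w"] = 1.0
        spec = GrowthSpec(outcome="diff", covariates=(), weights="w",
                          include_age_deviation=False)
        f1 = fit_growth(data, spec, compute_vcov=False)
        data["w"] = 2.0
        f2 = fit_growth(data, spec, compute_vcov=False)
        assert np.allclose(f1.estimates, f2.estimates, atol=1e-6)

    def test_child_ordering_invariance(self, rng):
        data = simulate_growth(600, rng)
        data.loc[rng.choice(600, 150, replace=False), ["diff_1", "age_1"]] = np.nan
        f1 = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        shuffled = data.sample(frac=1, random_state=3).reset_index(drop=True)
        f2 = fit_growth(shuffled, SPEC_PLAIN, compute_vcov=False)
        assert np.allclose(f1.estimates, f2.estimates, atol=1e-6)

    def test_affine_covariate_recoding_transforms_coefficient(self, rng):
        n = 2000
        data = simulate_growth(n, rng)
        data["cov"] = rng.normal(size=n)
        data["diff_3"] += 0.3 * data["cov"]
        data["diff_2"] += 0.3 * data["cov"]
        data["diff_1"] += 0.3 * data["cov"]
        spec = GrowthSpec(outcome="diff", covariates=("cov",),
                          include_age_deviation=False)
        f1 = fit_growth(data, spec, compute_vcov=False, gtol=1e-9)
        data2 = data.copy()
        data2["cov"] = 2.0 * data["cov"] + 3.0
        f2 = fit_growth(data2, spec, compute_vcov=False, gtol=1e-9)
        assert f2.estimates["b_cov_I"] == pytest.approx(
            f1.estimates["b_cov_I"] / 2.0, abs=2e-4
        )
        assert f2.estimates["psi_I_I"] == pytest.approx(
            f1.estimates["psi_I_I"], abs=2e-3
        )

    def test_equal_residuals_toggle_is_nested(self, rng):
        data = simulate_growth(1500, rng, theta=(0.9, 0.9, 0.9))
        free = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        eq = fit_growth(
            data, GrowthSpec(outcome="diff", covariates=(),
                             include_age_deviation=False, equal_residuals=True),
            compute_vcov=False,
        )
        res = lrt(free, eq)
        assert res.df == 2
        assert free.loglik >= eq.loglik - 1e-6
        assert res.p > 0.001  # equal-residual truth: no significant decrement


def _clustered_families(rng, n_fam=200):
    """Two children per family sharing half their factor variance."""
    psi_half = np.array([[0.5, 0.1], [0.1, 0.05]])
    fam = rng.multivariate_normal([0, 0.05], psi_half, size=n_fam)
    eta = np.repeat(fam, 2, axis=0) + rng.multivariate_normal(
        [0, 0], psi_half, size=2 * n_fam
    )
    t = np.asarray(DEFAULT_TIMES)
    Y = eta[:, [0]] + eta[:, [1]] * t + rng.standard_normal((2 * n_fam, 3)) * 0.8
    df = pd.DataFrame(Y, columns=["diff_1", "diff_2", "diff_3"])
    df["mother_id"] = np.repeat(np.arange(n_fam), 2)
    df["child_id"] = np.arange(2 * n_fam)
    return df


class TestClusterRobust:
    def test_singleton_clusters_equal_per_child_sandwich(self, rng):
        data = simulate_growth(500, rng)
        f1 = fit_growth(data, SPEC_PLAIN)  # mother_id unique per child here
        data2 = data.copy()
        data2["mother_id"] = data2["child_id"]
        f2 = fit_growth(data2, SPEC_PLAIN)
        assert np.allclose(f1.vcov_cluster, f2.vcov_cluster, rtol=1e-8)

    def test_duplicating_children_within_clusters(self, rng):
        """Duplicate every child in its cluster: point estimates unchanged;
        cluster-robust SEs unchanged up to the small-sample factor."""
        data = _clustered_families(rng, 60)
        f1 = fit_growth(data, GrowthSpec(outcome="diff", covariates=(),
                                         include_age_deviation=False))
        doubled = pd.concat([data, data.assign(child_id=lambda d: d.child_id + 10_000)],
                            ignore_index=True)
        f2 = fit_growth(doubled, GrowthSpec(outcome="diff", covariates=(),
                                            include_age_deviation=False))
        assert np.allclose(f1.estimates, f2.estimates, atol=5e-5)
        assert np.allclose(f1.se(), f2.se(), rtol=0.02)

    def test_cluster_ci_coverage_for_slope_mean(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            df = _clustered_families(rng, 150)
            fit = fit_growth(df, GrowthSpec(outcome="diff", covariates=(),
                                            include_age_deviation=False))
            est = fit.estimates["alpha_S"]
            se = fit.se()["alpha_S"]
            hits += abs(est - 0.05) < 1.96 * se
        coverage = 100 * hits / reps
        assert 92.5 < coverage < 97.5


class TestFitIndices:
    def test_saturated_model_gives_perfect_fit(self, rng):
        data = simulate_growth(4000, rng)
        fit, idx = measurement_fit(data, "diff", compute_vcov=False)
        assert idx.rmsea <= 0.05 and idx.cfi >= 0.95 and idx.srmr < 0.05
        assert idx.df == 1

    def test_srmr_matches_manual_perturbation_oracle(self, rng):
        """Perturb one saturated correlation by delta: SRMR = delta/3
        (9 standardised moment residuals, one nonzero)."""
        data = simulate_growth(2000, rng)
        fit, _ = measurement_fit(data, "diff", compute_vcov=False)
        pars = fit.params()
        from diffgrowth.growth import _build_sigma
        Sigma_m = _build_sigma(fit._layout, pars["Psi"], pars["Lam"],
                               pars["theta"], pars["offdiag"])
        mu_m = pars["Lam"] @ pars["alpha"]
        delta = 0.06
        Sigma_s = Sigma_m.copy()
        bump = delta * np.sqrt(Sigma_m[0, 0] * Sigma_m[1, 1])
        Sigma_s[0, 1] += bump
        Sigma_s[1, 0] += bump
        sat = MomentsFit(mu_m.copy(), Sigma_s, fit.loglik + 1.0, 9, fit.n_children)
        base = fit_baseline(data[["diff_1", "diff_2", "diff_3"]].to_numpy())
        idx = fit_indices(fit, sat, base)
        assert idx.srmr == pytest.approx(delta / 3.0, rel=1e-6)

    def test_index_fit_requires_measurement_model(self, complete_bundle):
        scored, _, _ = complete_bundle
        fit = fit_growth(scored.head(500), GrowthSpec(outcome="diff"),
                         compute_vcov=False)
        sat = fit_saturated(scored.head(500)[["diff_1", "diff_2", "diff_3"]].to_numpy())
        base = fit_baseline(scored.head(500)[["diff_1", "diff_2", "diff_3"]].to_numpy())
        with pytest.raises(GrowthModelError, match="measurement"):
            fit_indices(fit, sat, base)

    def test_em_saturated_agrees_with_complete_closed_form(self, rng):
        Y = simulate_growth(1500, rng)[["diff_1", "diff_2", "diff_3"]].to_numpy()
        full = fit_saturated(Y)
        Y2 = Y.copy()
        Y2[rng.random(1500) < 0.25, 1] = np.nan
        em = fit_saturated(Y2)
        assert em.converged
        assert np.abs(em.mu - full.mu).max() < 0.1
        # EM solution is a stationary point: its loglik beats plugging in
        # the complete-data moments
        naive = Y2.copy()
        from diffgrowth.growth import _mvn_loglik_patterns
        assert em.loglik >= _mvn_loglik_patterns(
            Y2, np.ones(1500), full.mu, full.Sigma
        ) - 1e-6


class TestLRT:
    def test_identical_models_give_zero_statistic(self, rng):
        data = simulate_growth(300, rng)
        f = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        res = lrt(f, f)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_null_size_close_to_nominal(self, rng):
        """Exposure slope paths truly zero: LRT of both vs intercept-only
        rejects at ~5%."""
        rej = 0
        reps = 300
        for _ in range(reps):
            n = 400
            data = simulate_growth(n, rng)
            data["x_1"] = rng.normal(size=n)
            data["diff_3"] += 0.2 * data["x_1"]
            data["diff_2"] += 0.2 * data["x_1"]
            data["diff_1"] += 0.2 * data["x_1"]  # pure intercept effect
            both = fit_growth(
                data, GrowthSpec(outcome="diff", covariates=(),
                                 predictors=("x_1",), include_age_deviation=False),
                compute_vcov=False)
            nested = fit_growth(
                data, GrowthSpec(outcome="diff", covariates=(),
                                 predictors=("x_1",),
                                 predictor_target="intercept_only",
                                 include_age_deviation=False),
                compute_vcov=False)
            rej += lrt(both, nested).p < 0.05
        assert 0.02 < rej / reps < 0.09

    def test_power_against_real_slope_path(self, rng):
        """A genuine slope effect is detected at moderate n."""
        n = 4000
        data = simulate_growth(n, rng)
        data["x_1"] = rng.normal(size=n)
        t = np.asarray(DEFAULT_TIMES)
        for w in range(3):
            data[f"diff_{w + 1}"] += 0.08 * data["x_1"] * t[w]
        both = fit_growth(
            data, GrowthSpec(outcome="diff", covariates=(), predictors=("x_1",),
                             include_age_deviation=False), compute_vcov=False)
        nested = fit_growth(
            data, GrowthSpec(outcome="diff", covariates=(), predictors=("x_1",),
                             predictor_target="intercept_only",
                             include_age_deviation=False), compute_vcov=False)
        assert lrt(both, nested).p < 0.01


class TestFactorScores:
    def test_noiseless_limit_equals_per_child_ols_line(self, rng):
        data = simulate_growth(200, rng, theta=(1e-8, 1e-8, 1e-8))
        fit = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        fs = factor_scores(fit, data)
        L = _lam()
        Y = data[["diff_1", "diff_2", "diff_3"]].to_numpy()
        ols = Y @ L @ np.linalg.inv(L.T @ L)
        assert np.abs(fs[["eta_I", "eta_S"]].to_numpy() - ols).max() < 1e-3

    def test_recovery_correlation_on_synthetic_truth(self, complete_bundle):
        scored, truth, _ = complete_bundle
        fit = fit_growth(scored, GrowthSpec(outcome="diff"), compute_vcov=False)
        fs = factor_scores(fit, scored).merge(
            truth[["child_id", "int_diff_std", "slope_diff_std"]], on="child_id")
        r_i = np.corrcoef(fs.eta_I, fs.int_diff_std)[0, 1]
        r_s = np.corrcoef(fs.eta_S, fs.slope_diff_std)[0, 1]
        assert r_i > 0.7
        assert r_s > 0.55  # slope is identified by only three waves

    def test_single_wave_child_shrinks_toward_conditional_mean(self, rng):
        data = simulate_growth(500, rng)
        data.loc[0, ["diff_1", "diff_2"]] = np.nan  # child 0 seen at wave 3 only
        fit = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        fs = factor_scores(fit, data).set_index("child_id")
        alpha_I = fit.estimates["alpha_I"]
        y3 = data.loc[0, "diff_3"]
        # score lies strictly between the prior mean and the observation
        lo, hi = sorted([alpha_I, y3])
        assert lo < fs.loc[0, "eta_I"] < hi

    def test_bartlett_scores_unshrunken_on_complete_data(self, rng):
        data = simulate_growth(300, rng)
        fit = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        reg = factor_scores(fit, data)
        bart = factor_scores(fit, data, method="bartlett")
        # Bartlett variance exceeds regression-score variance (no shrinkage)
        assert bart.eta_I.var() > reg.eta_I.var()


class TestBivariate:
    def test_reparameterisation_invariance_with_jacobian(self, complete_bundle):
        """Fitting (z_beh, z_emo) and the rotated (diff, tot) data gives
        log-likelihoods differing exactly by N*log 2."""
        scored, _, _ = complete_bundle
        data = scored.head(2500).copy()
        spec_y = GrowthSpec(outcome="bivariate", covariates=(),
                            include_age_deviation=False, cluster="mother_id")
        fit_y = fit_growth(data, spec_y, compute_vcov=False)
        spec_dt = GrowthSpec(outcome="bivariate", covariates=(),
                             include_age_deviation=False, cluster="mother_id",
                             biv_prefixes=("diff", "tot"))
        fit_dt = fit_growth(data, spec_dt, compute_vcov=False)
        n = fit_y.n_children
        # per wave, (diff, tot) = T (z_beh, z_emo) with |det T| = 2, so the
        # density of the rotated data is lower by log 2 per observed wave
        assert fit_y.loglik == pytest.approx(
            fit_dt.loglik + 3 * n * np.log(2.0), abs=1.0
        )

    def test_separate_diff_tot_fits_bound_the_bivariate_likelihood(
            self, complete_bundle):
        scored, _, _ = complete_bundle
        data = scored.head(2500).copy()
        f_diff = fit_growth(data, SPEC_PLAIN, compute_vcov=False)
        f_tot = fit_growth(
            data, GrowthSpec(outcome="tot", covariates=(),
                             include_age_deviation=False), compute_vcov=False)
        fit_y = fit_growth(
            data, GrowthSpec(outcome="bivariate", covariates=(),
                             include_age_deviation=False), compute_vcov=False)
        n = fit_y.n_children
        sep = f_diff.loglik + f_tot.loglik + 3 * n * np.log(2.0)
        gap = fit_y.loglik - sep
        # separate fits impose the 7 diff/tot cross-structure zeros, which
        # hold in the generator: the free fit wins by only ~chi2_7 / 2
        assert gap > -1e-6
        assert gap < 25.0
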