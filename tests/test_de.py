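"""DE engine: gene-wise OLS, empirical-Bayes priors, moderated t, posterior."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from rsikit.containers import EBayesParams
from rsikit.de import (
    GeneFits,
    build_design,
    estimate_ebayes_priors,
    fit_f_dist,
    fit_linear_models,
    lods_posterior,
    make_contrast,
    moderated_stats,
    run_contrast,
    squeeze_var,
)
from rsikit.synthetic import SimulationConfig, generate_counts

from conftest import make_expr


class TestLinearModels:
    def test_two_group_contrast_is_difference_of_means(self, two_group_design):
        design, contrast = two_group_design
        rng = np.random.default_rng(0)
        y = rng.normal(size=(15, 6))
        fits = fit_linear_models(make_expr(y), design, contrast)
        expected = y[:, 3:].mean(axis=1) - y[:, :3].mean(axis=1)
        assert np.allclose(fits.beta_hat, expected, atol=1e-12)
        assert fits.df_residual == 4
        assert fits.u == pytest.approx(1 / 3 + 1 / 3)

    def test_exact_fit_gives_zero_residual_variance(self, two_group_design):
        design, contrast = two_group_design
        y = np.array([[1.0, 1.0, 1.0, 4.0, 4.0, 4.0]])
        fits = fit_linear_models(make_expr(y), design, contrast)
        assert fits.s2[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_brute_force(self):
        rng = np.random.default_rng(1)
        n, p = 9, 3
        x = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        design = pd.DataFrame(x, columns=["intercept", "a", "b"],
                              index=[f"s{j+1}" for j in range(n)])
        c = pd.Series({"intercept": 0.0, "a": 1.0, "b": -0.5})
        y = rng.normal(size=(20, n))
        fits = fit_linear_models(make_expr(y), design, c)
        xtx_inv = np.linalg.inv(x.T @ x)
        cv = c.to_numpy()
        for g in range(20):
            beta = np.linalg.solve(x.T @ x, x.T @ y[g])
            resid = y[g] - x @ beta
            assert abs(fits.beta_hat[g] - cv @ beta) < 1e-10
            assert abs(fits.s2[g] - resid @ resid / (n - p)) < 1e-10
        assert abs(fits.u - cv @ xtx_inv @ cv) < 1e-12

    def test_rank_deficient_design_reports_columns(self):
        design = pd.DataFrame(
            {"intercept": np.ones(4), "x": [1.0, 2, 3, 4], "x2": [2.0, 4, 6, 8]},
            index=[f"s{j+1}" for j in range(4)],
        )
        c = pd.Series({"intercept": 0.0, "x": 1.0, "x2": 0.0})
        with pytest.raises(ValueError, match="x2"):
            fit_linear_models(make_expr(np.ones((3, 4))), design, c)


class TestEBayesPriors:
    def test_scaled_chi2_recovery(self):
        # Monte-Carlo: s2 ~ s0^2 * chi2_d0 / d0 mixed over gene variances
        rng = np.random.default_rng(2)
        d0_true, s0_true, dg = 4.0, 2.0, 10.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(dg, size=5000) / dg
        d0, s0_sq = fit_f_dist(s2, dg)
        assert abs(d0 - d0_true) / d0_true < 0.15
        assert abs(s0_sq - s0_true) / s0_true < 0.05

    def test_identical_variances_take_infinite_branch(self):
        d0, s0_sq = fit_f_dist(np.full(100, 1.7), 6.0)
        assert np.isinf(d0)
        assert s0_sq == pytest.approx(1.7, rel=1e-9)

    def test_p1_recorded_in_output(self, two_group_design):
        design, contrast = two_group_design
        rng = np.random.default_rng(3)
        fits = fit_linear_models(make_expr(rng.normal(size=(50, 6))), design, contrast)
        priors = estimate_ebayes_priors(fits, p1=0.01)
        assert priors.p1 == 0.01

    def test_too_few_genes_errors(self, two_group_design):
        design, contrast = two_group_design
        fits = fit_linear_models(make_expr(np.random.default_rng(4).normal(size=(5, 6))),
                                 design, contrast)
        with pytest.raises(ValueError, match="at least 20"):
            estimate_ebayes_priors(fits)


def _fits(beta, s2, dg, u, n_pad=50):
    """GeneFits with identical padding genes so the pooled-df cap is inert."""
    beta = np.full(n_pad, float(beta))
    s2 = np.full(n_pad, float(s2))
    return GeneFits(
        gene_ids=pd.Index([f"g{i}" for i in range(n_pad)]),
        beta_hat=beta,
        s2=s2,
        df_residual=float(dg),
        u=float(u),
    )


class TestModeratedStats:
    def test_hand_example(self):
        # beta=1, s2=1, d=4, u=1/3, d0=4, s0^2=1 -> s~^2=1, t=sqrt(3), p from t_8
        fits = _fits(1.0, 1.0, 4, 1 / 3)
        priors = EBayesParams(d0=4.0, s0_sq=1.0, p1=0.01, v0=1.0)
        t, p, flagged = moderated_stats(fits, priors)
        assert np.allclose(t, np.sqrt(3.0))
        assert np.allclose(p, 2 * stats.t.sf(np.sqrt(3.0), 8))
        assert not flagged.any()

    def test_d0_zero_limit_equals_classical_t(self, two_group_design):
        design, contrast = two_group_design
        rng = np.random.default_rng(5)
        y = rng.normal(size=(30, 6))
        fits = fit_linear_models(make_expr(y), design, contrast)
        priors = EBayesParams(d0=1e-300, s0_sq=1.0, p1=0.01, v0=1.0)
        t_mod, _, _ = moderated_stats(fits, priors)
        classical = fits.beta_hat / np.sqrt(fits.s2 * fits.u)
        assert np.allclose(t_mod, classical, atol=1e-12)

    def test_d0_infinite_pins_variance_to_prior(self):
        s2 = np.array([0.5, 1.0, 7.0])
        assert np.allclose(squeeze_var(s2, 4.0, np.inf, 2.0), 2.0)

    def test_zero_variance_flagged(self):
        # d0 * s0^2 underflows to zero, so the shrunken variance is exactly 0
        fits = _fits(1.0, 0.0, 4, 1 / 3)
        priors = EBayesParams(d0=1e-300, s0_sq=1e-30, p1=0.01, v0=1.0)
        with pytest.warns(RuntimeWarning, match="zero shrunken variance"):
            t, p, flagged = moderated_stats(fits, priors)
        assert flagged.all()
        assert np.isinf(t).all()
        assert (p == 0).all()


class TestLodsPosterior:
    def test_logistic_identity_and_b_zero(self):
        fits = _fits(0.0, 1.0, 10, 0.33)
        priors = EBayesParams(d0=4.0, s0_sq=1.0, p1=0.01, v0=1.0)
        t = np.linspace(-5, 5, 50)
        b, post = lods_posterior(t, fits, priors)
        assert np.allclose(post, 1 / (1 + np.exp(-b)), atol=1e-12)
        # solve for the t with B = 0: posterior exactly 0.5
        assert post[np.argmin(np.abs(b))] == pytest.approx(0.5, abs=0.2)

    def test_t_zero_posterior_below_prior(self):
        fits = _fits(0.0, 1.0, 10, 0.33)
        priors = EBayesParams(d0=4.0, s0_sq=1.0, p1=0.01, v0=1.0)
        b, post = lods_posterior(np.zeros(50), fits, priors)
        assert (b < np.log(priors.p1 / (1 - priors.p1))).all()
        assert (post < priors.p1).all()

    def test_v0_zero_degenerates_to_prior_odds(self):
        fits = _fits(1.0, 1.0, 10, 0.33)
        priors = EBayesParams(d0=4.0, s0_sq=1.0, p1=0.01, v0=0.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            b, post = lods_posterior(np.full(50, 3.0), fits, priors)
        assert np.allclose(b, np.log(0.01 / 0.99))

    def test_matches_marginal_likelihood_integration(self):
        # independent oracle: B = prior log-odds + log ratio of the marginal
        # likelihoods of (beta_hat, s2), integrating the variance prior out
        dg, d0, u, v0, p1, s0 = 10.0, 4.0, 0.33, 1.0, 0.01, 1.2
        s2 = 0.9
        s_tilde2 = (d0 * s0 + dg * s2) / (d0 + dg)
        t_obs = 3.0
        beta = t_obs * np.sqrt(s_tilde2 * u)

        def marginal(de: bool) -> float:
            var_beta = lambda sig2: sig2 * (u + (v0 if de else 0.0))

            def integrand(sig2):
                f_beta = stats.norm.pdf(beta, 0.0, np.sqrt(var_beta(sig2)))
                f_s2 = dg / sig2 * stats.chi2.pdf(dg * s2 / sig2, dg)
                prior = stats.chi2.pdf(d0 * s0 / sig2, d0) * d0 * s0 / sig2**2
                return f_beta * f_s2 * prior

            val, _ = integrate.quad(integrand, 1e-6, 200.0, limit=400)
            return val

        oracle = np.log(p1 / (1 - p1)) + np.log(marginal(True) / marginal(False))
        fits = _fits(beta, s2, dg, u)
        priors = EBayesParams(d0=d0, s0_sq=s0, p1=p1, v0=v0)
        t, _, _ = moderated_stats(fits, priors)
        b, _ = lods_posterior(t, fits, priors)
        assert b[0] == pytest.approx(oracle, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 20.0), min_size=2, max_size=8, unique=True))
    def test_posterior_strictly_increasing_in_abs_t(self, t_values):
        t = np.array(sorted(t_values))
        if (np.diff(t) < 1e-6).any():  # avoid float-resolution plateaus
            t = np.linspace(0, 20, len(t))
        fits = _fits(1.0, 1.0, 8, 0.4, n_pad=len(t))
        priors = EBayesParams(d0=5.0, s0_sq=1.0, p1=0.01, v0=2.0)
        b, post = lods_posterior(t, fits, priors)
        assert (np.diff(post) > 0).all()


class TestLimmaReference:
    """Frozen outputs of the reference Bioconductor implementation (limma
    lmFit + eBayes, proportion 0.01) on two seeded fixtures; one hits the
    finite-d0 prior, the other the degenerate d0 = inf branch."""

    def _run(self, y):
        expr = make_expr(y)
        design = pd.DataFrame({"intercept": 1.0, "group": [0, 0, 0, 1, 1, 1]},
                              index=expr.sample_ids)
        contrast = pd.Series({"intercept": 0.0, "group": 1.0})
        fits = fit_linear_models(expr, design, contrast)
        priors = estimate_ebayes_priors(fits, p1=0.01)
        t, p, _ = moderated_stats(fits, priors)
        b, _ = lods_posterior(t, fits, priors)
        return fits, priors, t, p, b

    def test_finite_d0_fixture(self):
        rng = np.random.default_rng(42)
        g, n = 80, 6
        s2 = 0.8 * 4 / rng.chisquare(4, size=g)
        y = rng.normal(8.0, 1.0, size=(g, 1)) + rng.normal(0, np.sqrt(s2)[:, None], size=(g, n))
        signs = rng.choice([-1.0, 1.0], size=g)
        is_de = rng.random(g) < 0.2
        y[:, 3:] += np.where(is_de, signs * rng.uniform(1.5, 3.0, size=g), 0.0)[:, None]
        fits, priors, t, p, b = self._run(y)
        assert priors.d0 == pytest.approx(4.41007001123, rel=1e-9)
        assert priors.s0_sq == pytest.approx(0.833844284344, rel=1e-9)
        assert priors.v0 == pytest.approx(19.1882349024, rel=1e-9)
        assert np.allclose(t[:6], [0.143995433126, -2.28556000788, 2.71386956564,
                                   0.62332045466, 3.30504286291, 0.487274749602], atol=1e-9)
        assert np.allclose(p[:6], [0.888895077912, 0.0500811722142, 0.0253240527812,
                                   0.549601535724, 0.0100514400136, 0.638511372264], atol=1e-9)
        assert np.allclose(b[:6], [-6.28088154072, -4.1160701133, -3.46893554082,
                                   -6.08687880204, -2.57643417166, -6.16554192667], atol=1e-9)

    def test_degenerate_d0_fixture(self):
        rng = np.random.default_rng(42)
        g, n = 60, 6
        y = rng.normal(8.0, 1.0, size=(g, n))
        signs = rng.choice([-1.0, 1.0], size=g)
        is_de = rng.random(g) < 0.2
        y[:, 3:] += np.where(is_de, signs * rng.uniform(1.5, 3.0, size=g), 0.0)[:, None]
        fits, priors, t, p, b = self._run(y)
        assert np.isinf(priors.d0)
        assert priors.s0_sq == pytest.approx(0.836153369666, rel=1e-9)
        assert priors.v0 == pytest.approx(19.135245495, rel=1e-9)
        assert np.allclose(t[:6], [-1.03928207651, 0.450632905993, -1.38857867517,
                                   -0.114552275441, -1.65673079667, -0.13028153463], atol=1e-9)
        assert np.allclose(p[:6], [0.299719447717, 0.652660980289, 0.166248257947,
                                   0.908895785005, 0.0988806116911, 0.896452819106], atol=1e-9)
        assert np.allclose(b[:6], [-5.76886990792, -6.19262500665, -5.35912360464,
                                   -6.28440143724, -4.96456675841, -6.28254073632], atol=1e-9)


class TestRunContrast:
    def test_posterior_equals_logistic_b_everywhere(self, small_study):
        res = run_contrast(small_study.counts, ("TMES", "static2D"))
        b = res.table["B"].to_numpy()
        assert np.allclose(res.table["posterior"], 1 / (1 + np.exp(-b)), atol=1e-12)

    def test_missing_condition_errors(self, small_study):
        with pytest.raises(ValueError, match="spheroid"):
            run_contrast(small_study.counts, ("spheroid", "static2D"))

    def test_planted_lfc_recovery(self):
        cfg = SimulationConfig(n_genes=2000, effect_size_range=(2.0, 4.0), seed=10)
        study = generate_counts(cfg)
        res = run_contrast(study.counts, ("TMES", "static2D"))
        truth = study.truth.lfc_contrast1.loc[res.gene_ids]
        err = (res.table["lfc"] - truth).abs()
        eff = truth != 0
        assert err[eff].median() < 0.3
        # counting noise dominates at low abundance; well-expressed genes
        # recover the planted effect tightly
        high = study.truth.baseline_log2.loc[res.gene_ids] >= 7
        assert err[eff & high].median() < 0.25

    def test_null_posteriors_small(self):
        cfg = SimulationConfig(n_genes=2000, class_proportions={"null": 1.0}, seed=11)
        study = generate_counts(cfg)
        res = run_contrast(study.counts, ("TMES", "static2D"))
        assert res.table["posterior"].median() < 2 * res.priors.p1

    def test_strong_effects_get_high_posterior(self):
        cfg = SimulationConfig(n_genes=2000, effect_size_range=(2.0, 4.0), seed=12)
        study = generate_counts(cfg)
        res = run_contrast(study.counts, ("TMES", "static2D"))
        eff = study.truth.lfc_contrast1.loc[res.gene_ids] != 0
        assert res.table.loc[eff.to_numpy(), "posterior"].median() > 0.95


def test_build_design_and_contrast_roundtrip(small_study):
    design = build_design(small_study.counts.samples)
    assert "intercept" in design.columns
    c = make_contrast(design, "TMES", "static2D")
    assert c["condition[TMES]"] == 1.0
    c2 = make_contrast(design, "TMES", "xenograft")
    assert c2["condition[TMES]"] == 1.0 and c2["condition[xenograft]"] == -1.0
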