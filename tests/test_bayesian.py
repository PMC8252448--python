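import numpy as np
import pandas as pd
import pytest
from scipy import stats

from earlylate import (
    MCMCSettings,
    Phase2Priors,
    PopulationParams,
    TrialDesign,
    TwoTrialDataset,
    derive_phase2_priors,
    estimate_eta,
    fit_bayesian_sr_phase2,
    fit_bdr,
    fit_dr,
    fit_sr,
    simulate_trial,
    two_step_bfdr,
)
from earlylate.bayesian import DIFFUSE_PHASE2_PRIORS, PosteriorResult, split_rhat

LIGHT = MCMCSettings(chains=2, draws=1000, warmup=400, seed=None)


def _pair(params, design, seed, effects=None):
    rng = np.random.default_rng(seed)
    e2 = effects.get(2) if effects else (params.bx, params.by)
    e3 = effects.get(3) if effects else (params.bx, params.by)
    frames = [
        simulate_trial(2, e2, params, design, rng),
        simulate_trial(3, e3, params, design, rng),
    ]
    return TwoTrialDataset(records=pd.concat(frames, ignore_index=True))


class TestPhase2Gibbs:
    def test_posterior_mean_matches_ols_at_large_n(self):
        p = PopulationParams(bx=0.6, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=10_000, N3=52)
        ds = _pair(p, d, 1)
        post = fit_bayesian_sr_phase2(ds.phase2, LIGHT, rng=np.random.default_rng(2))
        ph2 = ds.phase2
        ols_bx = (
            ph2.loc[ph2.t == 1, "x"].mean() - ph2.loc[ph2.t == 0, "x"].mean()
        )
        assert abs(post.flat("bx").mean() - ols_bx) < 0.02

    def test_sigma_fixed_conjugate_oracle(self):
        """With sigma_x^2 (near-)fixed by a concentrated prior, the posterior
        of (ax, bx) is the closed-form conjugate normal."""
        p = PopulationParams(bx=0.4, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=200, N3=52)
        ds = _pair(p, d, 3)
        sig2 = 1.7
        tight = Phase2Priors(
            mu_ah=0.0, sigma2_ah=100.0, mu_bh=0.0, sigma2_bh=100.0,
            alpha_h=1e8, beta_h=(1e8 + 1) * sig2,
        )
        post = fit_bayesian_sr_phase2(
            ds.phase2, MCMCSettings(chains=2, draws=4000, warmup=500),
            priors=tight, rng=np.random.default_rng(4),
        )
        t = ds.phase2["t"].to_numpy(float)
        x = ds.phase2["x"].to_numpy(float)
        X = np.column_stack([np.ones_like(t), t])
        prec = X.T @ X / sig2 + np.diag([0.01, 0.01])
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ x / sig2)
        draws = np.column_stack([post.flat("ax"), post.flat("bx")])
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.02)
        np.testing.assert_allclose(draws.std(axis=0, ddof=1), np.sqrt(np.diag(cov)), rtol=0.1)

    def test_prior_only_recovers_stated_priors(self):
        empty = pd.DataFrame({"trial": [], "t": [], "x": []})
        post = fit_bayesian_sr_phase2(
            empty, MCMCSettings(chains=2, draws=4000, warmup=200),
            rng=np.random.default_rng(5), allow_empty=True,
        )
        bx = post.flat("bx")
        assert abs(bx.std(ddof=1) - 10.0) < 3 * 10.0 / np.sqrt(2 * bx.size)
        # sigma_x^2 draws follow the IG(1, 1) prior
        ks = stats.kstest(post.flat("sigma2_x"), stats.invgamma(a=1, scale=1).cdf)
        assert ks.pvalue > 0.001

    def test_empty_arm_rejected_by_default(self):
        df = pd.DataFrame({"trial": [2, 2], "t": [1, 1], "x": [0.1, 0.2]})
        with pytest.raises(ValueError):
            fit_bayesian_sr_phase2(df, LIGHT)


class TestDerivedPriors:
    def test_invgamma_moment_matching_self_consistency(self):
        rng = np.random.default_rng(6)
        draws = stats.invgamma(a=3, scale=2).rvs(size=(4, 250_000), random_state=rng)
        post = PosteriorResult(
            draws={"ax": np.zeros((4, 1000)), "bx": rng.normal(size=(4, 1000)), "sigma2_x": draws},
            posterior_mean_by=np.nan, cri_lower=0, cri_upper=0,
            prob_by_positive=np.nan, decision=False, rhat={}, ess={},
        )
        pri = derive_phase2_priors(post)
        assert pri.alpha_h == pytest.approx(3.0, rel=0.02)
        assert pri.beta_h == pytest.approx(2.0, rel=0.02)

    def test_gamma_family_option(self):
        rng = np.random.default_rng(7)
        draws = stats.gamma(a=5, scale=0.5).rvs(size=(2, 100_000), random_state=rng)
        post = PosteriorResult(
            draws={"ax": np.zeros((2, 1000)), "bx": rng.normal(size=(2, 1000)), "sigma2_x": draws},
            posterior_mean_by=np.nan, cri_lower=0, cri_upper=0,
            prob_by_positive=np.nan, decision=False, rhat={}, ess={},
        )
        pri = derive_phase2_priors(post, sigma_family="gamma")
        assert pri.alpha_h == pytest.approx(5.0, rel=0.05)
        assert pri.beta_h == pytest.approx(2.0, rel=0.05)  # rate = 1/scale

    def test_constant_draws_trigger_degenerate_warning(self):
        post = PosteriorResult(
            draws={
                "ax": np.zeros((2, 1000)),
                "bx": np.full((2, 1000), 0.5),
                "sigma2_x": np.full((2, 1000), 1.0) + np.random.default_rng(0).normal(0, 1e-3, (2, 1000)) ** 2,
            },
            posterior_mean_by=np.nan, cri_lower=0, cri_upper=0,
            prob_by_positive=np.nan, decision=False, rhat={}, ess={},
        )
        with pytest.warns(RuntimeWarning, match="degenerate"):
            derive_phase2_priors(post)

    def test_too_few_draws_rejected(self):
        post = PosteriorResult(
            draws={"ax": np.zeros((1, 10)), "bx": np.zeros((1, 10)), "sigma2_x": np.ones((1, 10))},
            posterior_mean_by=np.nan, cri_lower=0, cri_upper=0,
            prob_by_positive=np.nan, decision=False, rhat={}, ess={},
        )
        with pytest.raises(ValueError):
            derive_phase2_priors(post)


class TestEta:
    def test_agreement_limit(self):
        p = PopulationParams(bx=0.6, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=2000, N3=2000, alloc3=(1, 1))
        etas = [estimate_eta(_pair(p, d, s).phase2, _pair(p, d, s).phase3).eta_hat for s in (1, 2, 3)]
        assert np.median(etas) > 0.8

    def test_conflict_limit(self):
        p = PopulationParams(bx=0.0, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=2000, N3=2000, alloc3=(1, 1))
        etas = []
        for s in (1, 2, 3):
            ds = _pair(p, d, s, effects={2: (0.0, 0.0), 3: (2.0, 0.0)})
            etas.append(estimate_eta(ds.phase2, ds.phase3).eta_hat)
        assert max(etas) < 0.1

    def test_grid_minimum_matches_dense_grid(self, small_dataset):
        est = estimate_eta(small_dataset.phase2, small_dataset.phase3)
        dense = estimate_eta(
            small_dataset.phase2,
            small_dataset.phase3,
            grid=np.arange(0.001, 1.0 + 1e-9, 0.001),
            refine=False,
        )
        assert abs(est.eta_hat - dense.eta_hat) <= 0.01

    def test_profile_shape(self, small_dataset):
        est = estimate_eta(small_dataset.phase2, small_dataset.phase3)
        assert list(est.profile.columns) == ["eta", "neg2_log_marginal"]
        assert len(est.profile) == 100
        k = est.profile["neg2_log_marginal"].idxmin()
        assert est.profile.loc[k, "neg2_log_marginal"] >= -2e308  # finite
        assert 0 < est.eta_hat <= 1

    def test_empty_input_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            estimate_eta(small_dataset.phase2.iloc[:0], small_dataset.phase3)


class TestBDRSampler:
    def test_decoupled_variant_matches_frequentist_sr(self):
        p = PopulationParams(bx=0.4, by=0.6, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=67, N3=2000, alloc3=(1, 1))
        ds = _pair(p, d, 8)
        res = fit_bdr(
            ds, DIFFUSE_PHASE2_PRIORS, settings=LIGHT,
            rho_prior_halfwidth=0.01, rng=np.random.default_rng(9),
        )
        sr = fit_sr(ds, d)
        assert abs(res.posterior_mean_by - sr.by_hat) < 0.03

    def test_rho_fixed_flat_priors_matches_dr(self):
        p = PopulationParams(bx=0.4, by=0.6, rho=0.9, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=1000, N3=1000, alloc3=(1, 1))
        ds = _pair(p, d, 11)
        s = MCMCSettings(chains=2, draws=1200, warmup=400)
        post2 = fit_bayesian_sr_phase2(ds.phase2, s, rng=np.random.default_rng(12))
        priors = derive_phase2_priors(post2)
        res = fit_bdr(ds, priors, eta=1.0, settings=s, rho_fixed=0.9, rng=np.random.default_rng(13))
        dr = fit_dr(ds, d)
        assert abs(res.posterior_mean_by - dr.by_hat) < 0.02

    def test_probability_is_fraction_of_positive_draws(self, small_dataset):
        res = fit_bdr(
            small_dataset, DIFFUSE_PHASE2_PRIORS, settings=LIGHT, rng=np.random.default_rng(14)
        )
        assert res.prob_by_positive == np.mean(res.flat("by") > 0)
        assert res.decision == (res.prob_by_positive > res.omega_post)
        assert np.all(np.abs(res.flat("rho")) <= 1.0)

    def test_same_seed_identical_draws(self, small_dataset):
        a = fit_bdr(small_dataset, DIFFUSE_PHASE2_PRIORS, settings=LIGHT, rng=np.random.default_rng(15))
        b = fit_bdr(small_dataset, DIFFUSE_PHASE2_PRIORS, settings=LIGHT, rng=np.random.default_rng(15))
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_prior_only_recovery(self):
        ph2_only = TwoTrialDataset(
            records=pd.DataFrame(
                {"trial": [2, 2], "t": [0, 1], "x": [0.0, 0.1], "y": [np.nan, np.nan]}
            )
        )
        res = fit_bdr(
            ph2_only, DIFFUSE_PHASE2_PRIORS,
            settings=MCMCSettings(chains=2, draws=4000, warmup=300),
            rng=np.random.default_rng(16),
        )
        by = res.flat("by")
        rho = res.flat("rho")
        assert abs(by.std(ddof=1) - 10.0) < 3 * 10.0 / np.sqrt(2 * by.size)
        assert abs(rho.mean()) < 0.05
        assert rho.var(ddof=1) == pytest.approx(1.0 / 3.0, abs=0.05)  # U(-1, 1)

    def test_eta_to_zero_approaches_flat_prior_posterior(self):
        p = PopulationParams(bx=0.4, by=0.6, rho=0.9, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=500, N3=2000, alloc3=(1, 1))
        ds = _pair(p, d, 17)
        s = MCMCSettings(chains=2, draws=1500, warmup=400)
        post2 = fit_bayesian_sr_phase2(ds.phase2, s, rng=np.random.default_rng(18))
        priors = derive_phase2_priors(post2)
        tiny = fit_bdr(ds, priors, eta=1e-4, settings=s, rng=np.random.default_rng(19))
        flat = fit_bdr(ds, DIFFUSE_PHASE2_PRIORS, settings=s, rng=np.random.default_rng(20))
        ks = stats.ks_2samp(tiny.flat("by"), flat.flat("by"))
        assert ks.statistic < 0.05

    def test_parameter_recovery_coverage(self):
        p = PopulationParams(ax=0.2, bx=0.3, ay=-0.1, by=0.5, rho=0.6, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=8, N3=300, alloc3=(1, 1))
        s = MCMCSettings(chains=2, draws=500, warmup=250)
        covered = 0
        reps = 60
        for r in range(reps):
            ds = _pair(p, d, 100 + r)
            res = fit_bdr(ds, DIFFUSE_PHASE2_PRIORS, settings=s, rng=np.random.default_rng(200 + r))
            covered += res.cri_lower <= p.by <= res.cri_upper
        assert 0.85 <= covered / reps <= 1.0

    def test_invalid_eta_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            fit_bdr(small_dataset, DIFFUSE_PHASE2_PRIORS, eta=1.5, settings=LIGHT)


class TestTwoStep:
    def test_pipeline_artifacts_and_replay(self, small_dataset, design):
        res1 = two_step_bfdr(small_dataset, design, settings=LIGHT, rng=np.random.default_rng(21))
        res2 = two_step_bfdr(small_dataset, design, settings=LIGHT, rng=np.random.default_rng(21))
        assert res1.posterior_mean_by == res2.posterior_mean_by
        assert 0 < res1.extras["eta_hat"] <= 1
        assert isinstance(res1.extras["priors"], Phase2Priors)
        assert len(res1.extras["eta_profile"]) == 100

    def test_agreement_gives_borrowing_gain(self):
        p = PopulationParams(bx=0.6, by=0.6, rho=0.9, tau_x=0.0, tau_y=0.0)
        d = TrialDesign(N2=2000, N3=2000, alloc3=(1, 1))
        ds = _pair(p, d, 22)
        s = MCMCSettings(chains=2, draws=1200, warmup=400)
        res = two_step_bfdr(ds, d, settings=s, rng=np.random.default_rng(23))
        bsr = fit_bdr(
            ds, DIFFUSE_PHASE2_PRIORS, settings=s,
            rho_prior_halfwidth=0.01, rng=np.random.default_rng(24),
        )
        assert res.extras["eta_hat"] > 0.8
        assert (res.cri_upper - res.cri_lower) < (bsr.cri_upper - bsr.cri_lower)


def test_split_rhat_detects_disagreeing_chains():
    rng = np.random.default_rng(0)
    good = rng.normal(size=(4, 500))
    bad = good + np.arange(4)[:, None] * 3.0
    assert split_rhat(good) < 1.02
    assert split_rhat(bad) > 1.5
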