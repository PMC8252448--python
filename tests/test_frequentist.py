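import numpy as np
import pandas as pd
import pytest
from scipy import stats

from earlylate import (
    CorrectedDoubleRegression,
    DoubleRegression,
    PopulationParams,
    SingleRegression,
    TrialDesign,
    TwoTrialDataset,
    analytic_mse,
    bias_terms,
    bias_terms_from_params,
    fit_dr,
    fit_drc,
    fit_sr,
    ols_fit,
    simulate_conditional_pair,
    simulate_trial,
)
from earlylate.frequentist import _inverse_mills


def _unconditional_pair(params, design, seed):
    rng = np.random.default_rng(seed)
    frames = [
        simulate_trial(2, (params.bx, params.by), params, design, rng),
        simulate_trial(3, (params.bx, params.by), params, design, rng),
    ]
    return TwoTrialDataset(records=pd.concat(frames, ignore_index=True))


class TestEstimators:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_dr_decomposition_identity(self, null_params, design, seed):
        ds = simulate_conditional_pair(null_params, design, seed)
        r = fit_dr(ds, design)
        assert r.by_hat == pytest.approx(r.b0_hat + r.gamma_hat * r.bx_hat, abs=1e-12)

    def test_dr_equals_two_component_ols_fits(self, small_dataset, design):
        r = fit_dr(small_dataset, design)
        recs = small_dataset.records
        ph3 = small_dataset.phase3
        fx = ols_fit(recs["x"].to_numpy(), [recs["t"].to_numpy()], ["t"])
        fy = ols_fit(ph3["y"].to_numpy(), [ph3["t"].to_numpy(), ph3["x"].to_numpy()], ["t", "x"])
        assert r.bx_hat == pytest.approx(fx.params["t"], abs=1e-12)
        assert r.b0_hat == pytest.approx(fy.params["t"], abs=1e-12)
        assert r.gamma_hat == pytest.approx(fy.params["x"], abs=1e-12)
        expected_var = (
            fy.cov.loc["t", "t"]
            + r.gamma_hat**2 * fx.cov.loc["t", "t"]
            + r.bx_hat**2 * fy.cov.loc["x", "x"]
            + 2 * r.bx_hat * fy.cov.loc["t", "x"]
        )
        assert r.var_by == pytest.approx(expected_var, rel=1e-12)

    def test_sr_equals_ols_subproblem(self, small_dataset, design):
        r = fit_sr(small_dataset, design)
        ph3 = small_dataset.phase3
        fit = ols_fit(ph3["y"].to_numpy(), [ph3["t"].to_numpy()], ["t"])
        assert r.by_hat == pytest.approx(fit.params["t"], abs=1e-12)
        assert r.var_by == pytest.approx(fit.cov.loc["t", "t"], rel=1e-12)

    def test_perfect_signal_rejects(self, design):
        t = np.repeat([0, 1], 26).astype(float)
        rng = np.random.default_rng(0)
        y = t + 0.001 * rng.standard_normal(52)
        x = rng.standard_normal(52)
        recs = pd.concat(
            [
                pd.DataFrame({"trial": 2, "t": [0, 0, 1, 1], "x": rng.standard_normal(4), "y": np.nan}),
                pd.DataFrame({"trial": 3, "t": t.astype(int), "x": x, "y": y}),
            ],
            ignore_index=True,
        )
        r = fit_sr(TwoTrialDataset(records=recs), design)
        assert r.by_hat == pytest.approx(1.0, abs=0.01)
        assert r.p_one_sided < 1e-10 and r.reject

    def test_rho_zero_dr_close_to_sr(self, design):
        p = PopulationParams(rho=0.0, tau_x=0.0, tau_y=0.0)
        big = TrialDesign(N2=2000, N3=2000, alloc3=(1, 1))
        ds = _unconditional_pair(p, big, 12)
        dr, sr = fit_dr(ds, big), fit_sr(ds, big)
        # gamma_hat ~ 0 so the borrowed term vanishes up to MC noise
        assert abs(dr.by_hat - sr.by_hat) < 0.05
        assert abs(dr.gamma_hat) < 0.05

    def test_estimator_classes_expose_sklearn_params(self, small_dataset):
        est = DoubleRegression(alpha3=0.1)
        assert est.get_params() == {"alpha3": 0.1}
        est.set_params(alpha3=0.05).fit(small_dataset)
        assert hasattr(est, "by_hat_") and est.ci_[0] <= est.by_hat_ <= est.ci_[1]
        sr = SingleRegression().fit(small_dataset)
        assert sr.result_.method == "sr"


class TestBiasAlgebra:
    def test_rho_zero_bias_is_exactly_zero(self, design):
        t = bias_terms(design, mu_x2=0, mu_x=0, sigma_x2=1, sigma_x=1, sigma_y=1, rho=0.0, gamma=0.0)
        assert t.bias == 0.0

    def test_median_go_threshold_standard_normal_values(self, design):
        t = bias_terms(
            design, mu_x2=0.0, mu_x=0.0, sigma_x2=1, sigma_x=1, sigma_y=1, rho=0.9, gamma=0.9,
            alpha2=0.5,
        )
        assert t.omega_trunc == pytest.approx(0.0, abs=1e-12)
        assert t.lam == pytest.approx(0.7978845608, abs=1e-6)

    def test_terms_satisfy_definitions(self, design):
        t = bias_terms(
            design, mu_x2=0.1, mu_x=0.05, sigma_x2=1.2, sigma_x=1.1, sigma_y=0.9, rho=0.7,
            gamma=0.57, alpha2=0.05,
        )
        se2 = 1.2 / np.sqrt(design.n2 / 2)
        assert t.lam > 0
        assert t.zeta < 0  # upper truncation always shrinks the variance
        assert t.A == pytest.approx(se2 * t.lam, rel=1e-12)
        assert t.sigma_x_prime**2 == pytest.approx(1.1**2 + t.D, rel=1e-12)
        assert t.sigma_y_prime**2 == pytest.approx(0.9**2 + 0.57**2 * t.D, rel=1e-12)
        assert t.mse >= t.bias**2

    def test_inverse_mills_extreme_omega_finite(self):
        lam = _inverse_mills(45.0)
        assert np.isfinite(lam)
        assert lam == pytest.approx(45.0 + 1 / 45.0, rel=1e-3)

    def test_mse_collapses_to_plain_variance_without_correlation(self, design):
        p = PopulationParams(rho=0.0, tau_x=0.0, tau_y=0.0)
        assert analytic_mse(p, design) == pytest.approx(2.0 / design.n3, rel=1e-12)

    def test_bias_increases_with_rho(self, design):
        biases = [
            bias_terms_from_params(
                PopulationParams(rho=r, tau_x=0.0, tau_y=0.0), design, alpha2=0.05
            ).bias
            for r in (0.0, 0.3, 0.6, 0.9)
        ]
        assert np.all(np.diff(biases) > 0)

    def test_bias_decreases_with_sample_size_at_fixed_split(self):
        # scaling both trials keeps the selected trial's weight w2 fixed, so
        # the bias shrinks like the Phase II standard error (~ 1/sqrt(n2));
        # at fixed N3 the weight w2 grows with N2 and monotonicity is lost
        p = PopulationParams(tau_x=0.0, tau_y=0.0)
        biases = [
            bias_terms_from_params(p, TrialDesign(N2=40 * k, N3=52 * k), alpha2=0.05).bias
            for k in (1, 2, 4, 8)
        ]
        assert np.all(np.diff(biases) < 0)

    def test_analytic_bias_matches_rejection_sampling_oracle(self, null_params, design):
        """Brute-force selection oracle at one grid point: the mean DR error
        over conditional replicates equals the analytic bias within 3 MC SE."""
        d = design.replace(alpha2=0.05)
        rng = np.random.default_rng(2718)
        errs = np.array(
            [fit_dr(simulate_conditional_pair(null_params, d, rng), d).by_hat for _ in range(4000)]
        )
        t = bias_terms_from_params(null_params, d, alpha2=0.05)
        mc_se = errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean() - t.bias) < 3 * mc_se


class TestCorrectedDR:
    def test_correction_decomposition(self, small_dataset, design):
        r = fit_drc(small_dataset, design)
        assert r.by_corrected == pytest.approx(r.dr.by_hat - r.bias_terms.bias, abs=1e-12)

    def test_oracle_plugin_subtracts_analytic_bias(self, small_dataset, design, null_params):
        r = fit_drc(small_dataset, design, plugin="oracle", oracle_params=null_params)
        expected = bias_terms_from_params(null_params, design, alpha2=design.alpha2).bias
        assert r.bias_terms.bias == pytest.approx(expected, rel=1e-12)

    def test_near_zero_gamma_leaves_dr_unchanged(self):
        p = PopulationParams(rho=0.0, tau_x=0.0, tau_y=0.0)
        big = TrialDesign(N2=400, N3=400, alloc3=(1, 1))
        ds = _unconditional_pair(p, big, 77)
        drc = fit_drc(ds, big)
        dr = fit_dr(ds, big)
        assert abs(drc.by_corrected - dr.by_hat) < 0.02

    def test_corrected_variance_term_option(self, small_dataset, design):
        r3 = fit_drc(small_dataset, design, variance_term="n3")
        r2 = fit_drc(small_dataset, design, variance_term="n2")
        # n2 > n3 in the default design, so the n2 variant is tighter
        assert r2.var_corrected < r3.var_corrected

    def test_unknown_plugin_rejected(self, small_dataset, design):
        with pytest.raises(ValueError):
            fit_drc(small_dataset, design, plugin="nope")

    def test_drc_interval_centred_on_corrected_estimate(self, small_dataset, design):
        r = fit_drc(small_dataset, design)
        assert r.ci_lower <= r.by_corrected <= r.ci_upper
        width = r.ci_upper - r.ci_lower
        assert width == pytest.approx(2 * stats.norm.ppf(0.975) * np.sqrt(r.var_corrected), rel=1e-9)


class TestBiasAlgebraProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        mu_x2=st.floats(-1.5, 1.5),
        sigma=st.floats(0.2, 3.0),
        rho=st.floats(-0.99, 0.99),
        alpha2=st.floats(0.01, 0.5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariants_hold_across_parameter_space(self, mu_x2, sigma, rho, alpha2):
        d = TrialDesign(alpha2=alpha2)
        gamma = rho  # sigma_y = sigma_x so gamma == rho
        t = bias_terms(
            d, mu_x2=mu_x2, mu_x=mu_x2 / 2, sigma_x2=sigma, sigma_x=sigma,
            sigma_y=sigma, rho=rho, gamma=gamma, alpha2=alpha2,
        )
        assert t.lam > 0
        assert -1 < t.zeta < 0
        assert t.A == pytest.approx(sigma / np.sqrt(d.n2 / 2) * t.lam, rel=1e-9)
        assert t.mse >= t.bias**2
        # the bias carries the sign of the outcome correlation
        assert np.sign(t.bias) == np.sign(rho) or t.bias == 0.0
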