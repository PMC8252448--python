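"""Frequentist estimators of the late-phase treatment effect.

Three estimators are provided, all as scikit-learn-style estimator classes
with thin functional wrappers:

``SingleRegression`` (SR)
    Regression of y on treatment using Phase III patients only; ignores the
    biomarker and the Phase II trial entirely.

``DoubleRegression`` (DR)
    Combines a regression of x on treatment over all N patients with a
    regression of y on (x, treatment) over the N3 Phase III patients:

        by_hat = b0_hat + gamma_hat * bx_hat

    with delta-method variance
    ``var(b0) + gamma^2 var(bx) + bx^2 var(gamma) + 2 bx cov(b0, gamma)``.
    Borrowing the selected (truncated) Phase II biomarker data makes DR
    biased upward after a positive Phase II "go" decision.

``CorrectedDoubleRegression`` (DRC)
    Subtracts the analytic selection bias (inverse-Mills-ratio form, see
    :func:`bias_terms`) from the DR estimate and deflates its variance.

Hypothesis tests are one-sided (H0: by <= 0), rejecting when
``by_hat / sqrt(var) > z_{1 - alpha3}``; intervals are central two-sided 95%
z-intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .dataset import TwoTrialDataset
from .ols import RegressionFit, ols_fit
from .params import PopulationParams, TrialDesign

_EPS = 1e-12
_Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------
@dataclass
class DRResult:
    """Late-phase effect estimate with test and interval.

    For the single regression the component estimates (b0_hat, gamma_hat,
    bx_hat, ...) are NaN.
    """

    method: str
    by_hat: float
    var_by: float
    ci_lower: float
    ci_upper: float
    p_one_sided: float
    reject: bool
    b0_hat: float = np.nan
    gamma_hat: float = np.nan
    bx_hat: float = np.nan
    sy2_hat: float = np.nan
    rho_hat: float = np.nan

    @property
    def ci_width(self) -> float:
        return self.ci_upper - self.ci_lower

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "by_hat": self.by_hat,
            "var_by": self.var_by,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_one_sided": self.p_one_sided,
            "reject": bool(self.reject),
            "b0_hat": self.b0_hat,
            "gamma_hat": self.gamma_hat,
            "bx_hat": self.bx_hat,
            "sy2_hat": self.sy2_hat,
            "rho_hat": self.rho_hat,
        }


@dataclass
class BiasCorrectionTerms:
    """Ingredients of the analytic selection-bias and MSE expressions."""

    z_go: float
    mu_x2: float
    mu_x: float
    sigma_x2: float
    omega_trunc: float
    lam: float
    A: float
    zeta: float
    D: float
    sigma_x_prime: float
    sigma_y_prime: float
    bias: float
    var_by: float
    mse: float
    floored: bool = False


@dataclass
class DRCResult:
    """Bias-corrected double-regression result."""

    by_corrected: float
    var_corrected: float
    ci_lower: float
    ci_upper: float
    p_one_sided: float
    reject: bool
    bias_terms: BiasCorrectionTerms
    dr: DRResult
    variance_floored: bool = False

    @property
    def ci_width(self) -> float:
        return self.ci_upper - self.ci_lower

    def to_dict(self) -> dict:
        d = self.dr.to_dict()
        d.update(
            {
                "method": "drc",
                "by_hat": self.by_corrected,
                "var_by": self.var_corrected,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_one_sided": self.p_one_sided,
                "reject": bool(self.reject),
                "bias_estimate": self.bias_terms.bias,
                "variance_floored": self.variance_floored,
            }
        )
        return d


# ---------------------------------------------------------------------------
# analytic truncation algebra
# ---------------------------------------------------------------------------
def _inverse_mills(omega: float) -> float:
    """phi(omega) / (1 - Phi(omega)), with an asymptotic branch for large omega."""
    sf = stats.norm.sf(omega)
    if sf > 1e-300:
        return float(stats.norm.pdf(omega) / sf)
    # upper-tail asymptotics: lambda(w) ~ w + 1/w - 2/w^3
    return float(omega + 1.0 / omega - 2.0 / omega**3)


def bias_terms(
    design: TrialDesign,
    *,
    mu_x2: float,
    mu_x: float,
    sigma_x2: float,
    sigma_x: float,
    sigma_y: float,
    rho: float,
    gamma: float,
    alpha2: Optional[float] = None,
) -> BiasCorrectionTerms:
    """Analytic bias and MSE of the DR estimate under Phase II selection.

    The Phase II effect estimate ``bx2_hat`` has standard error
    ``SE2 = sigma_x2 / sqrt(n2/2)`` (per-arm convention ``n2 = N2/2``); a
    "go" at level alpha2 truncates it to ``bx2_hat > z_{1-alpha2} * SE2``.
    With the standardized truncation point
    ``omega = z_{1-alpha2} - mu_x2 / SE2`` and inverse Mills ratio
    ``lam = phi(omega)/(1 - Phi(omega))`` the truncated mean shift is
    ``A = SE2 * lam`` and the variance excess factor ``zeta = omega*lam -
    lam**2`` (always negative: truncation reduces spread).  The selection
    inflates the pooled biomarker variance by

        D = w2 * (SE2^2 * zeta + A^2 (1 - w2^2 - w3^2) + 2 A (mu_x2 - mu_x))

    giving inflated SDs ``sigma_x'^2 = sigma_x^2 + D`` and
    ``sigma_y'^2 = sigma_y^2 + gamma^2 D``, and finally

        bias = sigma_y' * w2 * rho * lam * sigma_x2 / (sigma_x' * sqrt(n2/2))
        var  = 2 * sigma_y'^2 * ((1 - rho^2)/n3 + rho^2/n)
        mse  = bias^2 + var.
    """
    if sigma_x2 <= 0 or sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("sigma values must be > 0")
    alpha2 = design.alpha2 if alpha2 is None else alpha2
    if not 0 < alpha2 < 1:
        raise ValueError(f"alpha2 must lie in (0, 1), got {alpha2}")
    z_go = float(stats.norm.ppf(1.0 - alpha2))
    se2 = sigma_x2 / np.sqrt(design.n2 / 2.0)
    omega = z_go - mu_x2 / se2
    lam = _inverse_mills(omega)
    A = se2 * lam
    zeta = omega * lam - lam * lam
    w2, w3 = design.w2, design.w3
    D = w2 * (se2**2 * zeta + A**2 * (1.0 - w2**2 - w3**2) + 2.0 * A * (mu_x2 - mu_x))
    floored = False
    sx2_prime = sigma_x**2 + D
    sy2_prime = sigma_y**2 + gamma**2 * D
    if sx2_prime <= _EPS or sy2_prime <= _EPS:
        warnings.warn("selection-inflated variance floored at eps", RuntimeWarning)
        floored = True
        sx2_prime = max(sx2_prime, _EPS)
        sy2_prime = max(sy2_prime, _EPS)
    sigma_x_prime = float(np.sqrt(sx2_prime))
    sigma_y_prime = float(np.sqrt(sy2_prime))
    bias = sigma_y_prime * w2 * rho * lam * sigma_x2 / (sigma_x_prime * np.sqrt(design.n2 / 2.0))
    var_by = 2.0 * sy2_prime * ((1.0 - rho**2) / design.n3 + rho**2 / design.n)
    return BiasCorrectionTerms(
        z_go=z_go,
        mu_x2=mu_x2,
        mu_x=mu_x,
        sigma_x2=sigma_x2,
        omega_trunc=float(omega),
        lam=float(lam),
        A=float(A),
        zeta=float(zeta),
        D=float(D),
        sigma_x_prime=sigma_x_prime,
        sigma_y_prime=sigma_y_prime,
        bias=float(bias),
        var_by=float(var_by),
        mse=float(bias**2 + var_by),
        floored=floored,
    )


def bias_terms_from_params(
    params: PopulationParams,
    design: TrialDesign,
    alpha2: Optional[float] = None,
    heterogeneity: str = "outcome",
    mu_x2: Optional[float] = None,
    mu_x: Optional[float] = None,
) -> BiasCorrectionTerms:
    """Analytic-mode bias terms computed from true generative parameters."""
    from .simulate import _marginal_moments  # local import to avoid cycle

    sd_x, sd_y, corr = _marginal_moments(params, heterogeneity)
    gamma = corr * sd_y / sd_x
    return bias_terms(
        design,
        mu_x2=params.bx if mu_x2 is None else mu_x2,
        mu_x=params.bx if mu_x is None else mu_x,
        sigma_x2=sd_x,
        sigma_x=sd_x,
        sigma_y=sd_y,
        rho=corr,
        gamma=gamma,
        alpha2=alpha2,
    )


def analytic_mse(
    params: PopulationParams,
    design: TrialDesign,
    alpha2: Optional[float] = None,
    heterogeneity: str = "outcome",
) -> float:
    """Approximate MSE of the DR estimate under Phase II selection."""
    return bias_terms_from_params(params, design, alpha2, heterogeneity).mse


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------
def _test_and_interval(by_hat: float, var_by: float, alpha3: float):
    se = np.sqrt(var_by)
    if se > 0:
        z = by_hat / se
        p = float(stats.norm.sf(z))
    else:
        p = 0.0 if by_hat > 0 else 1.0
    reject = p < alpha3 if se > 0 else by_hat > 0
    return (
        float(by_hat - _Z95 * se),
        float(by_hat + _Z95 * se),
        p,
        bool(reject),
    )


class SingleRegression(BaseEstimator):
    """Phase-III-only regression of y on treatment (the SR analysis).

    Parameters
    ----------
    alpha3 : float
        One-sided significance level of the late-phase test.

    Attributes (after ``fit``)
    --------------------------
    by_hat_, var_by_, ci_, p_one_sided_, reject_, result_
    """

    def __init__(self, alpha3: float = 0.05):
        self.alpha3 = alpha3

    def fit(self, dataset: TwoTrialDataset) -> "SingleRegression":
        ph3 = dataset.phase3
        if len(ph3) == 0:
            raise ValueError("no Phase III records with observed y")
        fit = ols_fit(ph3["y"].to_numpy(), [ph3["t"].to_numpy()], ["t"])
        by_hat = float(fit.params["t"])
        var_by = float(fit.cov.loc["t", "t"])
        lo, hi, p, rej = _test_and_interval(by_hat, var_by, self.alpha3)
        self.fit_y_ = fit
        self.by_hat_ = by_hat
        self.var_by_ = var_by
        self.ci_ = (lo, hi)
        self.p_one_sided_ = p
        self.reject_ = rej
        self.result_ = DRResult(
            method="sr",
            by_hat=by_hat,
            var_by=var_by,
            ci_lower=lo,
            ci_upper=hi,
            p_one_sided=p,
            reject=rej,
        )
        return self


class DoubleRegression(BaseEstimator):
    """Double regression: biomarker regression on all N patients combined
    with the conditional late-phase regression on Phase III patients."""

    def __init__(self, alpha3: float = 0.05):
        self.alpha3 = alpha3

    def fit(self, dataset: TwoTrialDataset) -> "DoubleRegression":
        recs = dataset.records
        ph3 = dataset.phase3
        if len(ph3) == 0:
            raise ValueError("no Phase III records with observed y")
        fit_x = ols_fit(recs["x"].to_numpy(), [recs["t"].to_numpy()], ["t"])
        fit_y = ols_fit(
            ph3["y"].to_numpy(),
            [ph3["t"].to_numpy(), ph3["x"].to_numpy()],
            ["t", "x"],
        )
        bx_hat = float(fit_x.params["t"])
        b0_hat = float(fit_y.params["t"])
        gamma_hat = float(fit_y.params["x"])
        by_hat = b0_hat + gamma_hat * bx_hat
        var_by = (
            float(fit_y.cov.loc["t", "t"])
            + gamma_hat**2 * float(fit_x.cov.loc["t", "t"])
            + bx_hat**2 * float(fit_y.cov.loc["x", "x"])
            + 2.0 * bx_hat * float(fit_y.cov.loc["t", "x"])
        )
        sx2 = fit_x.resid_variance
        s02 = fit_y.resid_variance
        sy2 = s02 + gamma_hat**2 * sx2
        rho_hat = float(np.clip(gamma_hat * np.sqrt(sx2 / sy2), -1.0, 1.0)) if sy2 > 0 else 0.0
        lo, hi, p, rej = _test_and_interval(by_hat, var_by, self.alpha3)
        self.fit_x_ = fit_x
        self.fit_y_ = fit_y
        self.by_hat_ = by_hat
        self.var_by_ = var_by
        self.ci_ = (lo, hi)
        self.p_one_sided_ = p
        self.reject_ = rej
        self.result_ = DRResult(
            method="dr",
            by_hat=by_hat,
            var_by=var_by,
            ci_lower=lo,
            ci_upper=hi,
            p_one_sided=p,
            reject=rej,
            b0_hat=b0_hat,
            gamma_hat=gamma_hat,
            bx_hat=bx_hat,
            sy2_hat=sy2,
            rho_hat=rho_hat,
        )
        return self


class CorrectedDoubleRegression(BaseEstimator):
    """Bias-corrected double regression (DRC).

    Runs the DR fit, builds plug-in bias-correction terms, subtracts the
    estimated selection bias and deflates the variance:

        by' = by_hat - bias_hat
        var' = 2 (sy2_hat - gamma_hat^2 * D_hat)
               * ((1 - rho_hat^2)/n3 + rho_hat^2/n)

    Parameters
    ----------
    alpha2 : float
        Alpha level of the Phase II go decision (must be known to correct).
    alpha3 : float
        One-sided significance level of the late-phase test.
    plugin : {"pooled", "phase2", "oracle"}
        Estimate of the Phase II biomarker effect mean mu_x2 entering the
        truncation point: the pooled all-N slope bx_hat ("pooled", default),
        the Phase-II-only slope bx2_hat ("phase2"), or true generative
        values ("oracle", requires ``oracle_params``).
    variance_term : {"n3", "n2"}
        Which per-arm size divides the (1 - rho^2) term of the corrected
        variance; ``"n3"`` keeps the corrected variance consistent with the
        analytic MSE decomposition.
    oracle_params : PopulationParams, optional
        True generative parameters for ``plugin="oracle"``.
    """

    def __init__(
        self,
        alpha2: float = 0.05,
        alpha3: float = 0.05,
        plugin: str = "pooled",
        variance_term: str = "n3",
        oracle_params: Optional[PopulationParams] = None,
        oracle_heterogeneity: str = "outcome",
    ):
        self.alpha2 = alpha2
        self.alpha3 = alpha3
        self.plugin = plugin
        self.variance_term = variance_term
        self.oracle_params = oracle_params
        self.oracle_heterogeneity = oracle_heterogeneity

    def fit(self, dataset: TwoTrialDataset) -> "CorrectedDoubleRegression":
        if self.plugin not in ("pooled", "phase2", "oracle"):
            raise ValueError(f"unknown plugin {self.plugin!r}")
        if self.variance_term not in ("n3", "n2"):
            raise ValueError(f"variance_term must be 'n3' or 'n2', got {self.variance_term!r}")
        dr_est = DoubleRegression(alpha3=self.alpha3).fit(dataset)
        dr = dr_est.result_
        design = TrialDesign(
            N2=int((dataset.records["trial"] == 2).sum()),
            N3=int((dataset.records["trial"] == 3).sum()),
            alpha2=self.alpha2,
            alpha3=self.alpha3,
        )
        sx = float(np.sqrt(dr_est.fit_x_.resid_variance))
        sy = float(np.sqrt(dr.sy2_hat))
        if self.plugin == "oracle":
            if self.oracle_params is None:
                raise ValueError("plugin='oracle' requires oracle_params")
            terms = bias_terms_from_params(
                self.oracle_params,
                design,
                alpha2=self.alpha2,
                heterogeneity=self.oracle_heterogeneity,
            )
        else:
            if self.plugin == "phase2":
                ph2 = dataset.phase2
                fit_x2 = ols_fit(ph2["x"].to_numpy(), [ph2["t"].to_numpy()], ["t"])
                mu_x2 = float(fit_x2.params["t"])
            else:
                mu_x2 = dr.bx_hat
            terms = bias_terms(
                design,
                mu_x2=mu_x2,
                mu_x=dr.bx_hat,
                sigma_x2=sx,
                sigma_x=sx,
                sigma_y=sy,
                rho=dr.rho_hat,
                gamma=dr.gamma_hat,
                alpha2=self.alpha2,
            )
        by_corr = dr.by_hat - terms.bias
        n_var = design.n3 if self.variance_term == "n3" else design.n2
        core = dr.sy2_hat - dr.gamma_hat**2 * terms.D
        floored = False
        if core <= _EPS:
            warnings.warn("corrected variance floored at eps", RuntimeWarning)
            core = _EPS
            floored = True
        var_corr = 2.0 * core * ((1.0 - dr.rho_hat**2) / n_var + dr.rho_hat**2 / design.n)
        lo, hi, p, rej = _test_and_interval(by_corr, var_corr, self.alpha3)
        self.dr_ = dr
        self.bias_terms_ = terms
        self.by_hat_ = float(by_corr)
        self.var_by_ = float(var_corr)
        self.ci_ = (lo, hi)
        self.p_one_sided_ = p
        self.reject_ = rej
        self.result_ = DRCResult(
            by_corrected=float(by_corr),
            var_corrected=float(var_corr),
            ci_lower=lo,
            ci_upper=hi,
            p_one_sided=p,
            reject=rej,
            bias_terms=terms,
            dr=dr,
            variance_floored=floored,
        )
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------
def fit_sr(dataset: TwoTrialDataset, design: TrialDesign) -> DRResult:
    """Single regression of the Phase III late-phase outcome on treatment."""
    return SingleRegression(alpha3=design.alpha3).fit(dataset).result_


def fit_dr(dataset: TwoTrialDataset, design: TrialDesign) -> DRResult:
    """Double regression combining both trials' biomarker data."""
    return DoubleRegression(alpha3=design.alpha3).fit(dataset).result_


def fit_drc(
    dataset: TwoTrialDataset,
    design: TrialDesign,
    alpha2: Optional[float] = None,
    **kwargs,
) -> DRCResult:
    """Bias-corrected double regression at the known Phase II alpha level."""
    est = CorrectedDoubleRegression(
        alpha2=design.alpha2 if alpha2 is None else alpha2,
        alpha3=design.alpha3,
        **kwargs,
    )
    return est.fit(dataset).result_
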