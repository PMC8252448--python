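"""Two-trial simulator with a truncation-based Phase II "go" decision.

A Phase III trial is only run (and therefore only observed) after a positive
Phase II readout on the early-phase outcome.  Conditioning on that decision
truncates the distribution of the Phase II treatment-effect estimate, which
is the root of the decision-induced bias the analysis methods address.  The
simulator realizes the conditional (truncated) distribution by rejection
sampling: fresh Phase II trials are generated until the standardized
early-phase difference exceeds the normal quantile ``z_{1-alpha2}``.

Between-trial heterogeneity
---------------------------
Two mechanisms for the heterogeneity SDs ``tau_x, tau_y`` are supported:

``"outcome"`` (default)
    Each patient's (x, y) pair receives independent extra noise with SDs
    ``tau_x, tau_y``; marginally the outcome variances become
    ``sigma_x**2 + tau_x**2`` and ``sigma_y**2 + tau_y**2`` while the
    covariance ``rho*sigma_x*sigma_y`` is unchanged.  This is the mechanism
    that reproduces the reference operating characteristics (e.g. the
    single-regression interval width grows by the factor
    ``sqrt(1 + tau_y**2 / sigma_y**2)`` as ``tau_y`` rises).

``"effect"``
    Classical trial-level random effects: trial k receives treatment effects
    ``bx_k ~ N(bx, tau_x**2)``, ``by_k ~ N(by, tau_y**2)`` drawn once per
    trial, with the patient-level covariance left unchanged.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TwoTrialDataset
from .errors import ConvergenceError, DegenerateDataError
from .params import PopulationParams, TrialDesign

HETEROGENEITY_MODES = ("outcome", "effect")


def draw_trial_effects(
    params: PopulationParams,
    n_trials: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw per-trial treatment-effect pairs (bx_k, by_k).

    Trial k receives ``bx_k ~ N(bx, tau_x**2)`` and ``by_k ~ N(by, tau_y**2)``
    independently across trials and outcomes.  With ``tau_x = tau_y = 0`` the
    common effects are returned exactly.

    Returns an array of shape ``(n_trials, 2)``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(rng)
    out = np.empty((n_trials, 2))
    out[:, 0] = params.bx
    out[:, 1] = params.by
    if params.tau_x > 0:
        out[:, 0] += params.tau_x * rng.standard_normal(n_trials)
    if params.tau_y > 0:
        out[:, 1] += params.tau_y * rng.standard_normal(n_trials)
    return out


def _marginal_moments(params: PopulationParams, heterogeneity: str) -> tuple[float, float, float]:
    """(sd_x, sd_y, corr) of the patient-level residual distribution."""
    if heterogeneity not in HETEROGENEITY_MODES:
        raise ValueError(f"heterogeneity must be one of {HETEROGENEITY_MODES}, got {heterogeneity!r}")
    cov = params.rho * params.sigma_x * params.sigma_y
    if heterogeneity == "outcome":
        sd_x = float(np.hypot(params.sigma_x, params.tau_x))
        sd_y = float(np.hypot(params.sigma_y, params.tau_y))
    else:
        sd_x, sd_y = params.sigma_x, params.sigma_y
    return sd_x, sd_y, cov / (sd_x * sd_y)


def _treatment_vector(design: TrialDesign, trial: int) -> np.ndarray:
    n_c, n_e = design.arm_sizes(trial)
    return np.repeat([0.0, 1.0], [n_c, n_e])


def _simulate_xy(
    t: np.ndarray,
    effects: Sequence[float],
    params: PopulationParams,
    sd_x: float,
    sd_y: float,
    corr: float,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``size`` replicate trials at once; returns x, y of shape (size, len(t))."""
    bx_k, by_k = effects
    n = t.size
    zx = rng.standard_normal((size, n))
    zy = rng.standard_normal((size, n))
    x = params.ax + bx_k * t + sd_x * zx
    y = params.ay + by_k * t + sd_y * (corr * zx + np.sqrt(1.0 - corr * corr) * zy)
    return x, y


def simulate_trial(
    trial_id: int,
    effects: Sequence[float],
    params: PopulationParams,
    design: TrialDesign,
    rng: np.random.Generator | int,
    heterogeneity: str = "outcome",
) -> pd.DataFrame:
    """Simulate one trial; Phase II (trial_id=2) y values are masked to NaN.

    ``effects`` is the realized (bx_k, by_k) pair for this trial — pass the
    population values directly for a homogeneous simulation, or a row from
    :func:`draw_trial_effects` for trial-level random effects.
    """
    if trial_id not in (2, 3):
        raise ValueError(f"trial_id must be 2 or 3, got {trial_id}")
    if not np.all(np.isfinite(effects)):
        raise ValueError(f"effects must be finite, got {effects}")
    rng = np.random.default_rng(rng)
    sd_x, sd_y, corr = _marginal_moments(params, heterogeneity)
    t = _treatment_vector(design, trial_id)
    x, y = _simulate_xy(t, effects, params, sd_x, sd_y, corr, rng)
    df = pd.DataFrame({"trial": trial_id, "t": t.astype(int), "x": x[0], "y": y[0]})
    if trial_id == 2:
        df["y"] = np.nan
    return df


def phase2_z_statistic(phase2_records: pd.DataFrame) -> float:
    """Standardized early-phase treatment difference of the Phase II trial.

    Returns ``(mean_x_e - mean_x_c) / sqrt(s2 * (1/n_e + 1/n_c))`` where
    ``s2`` is the pooled within-arm variance estimate.
    """
    t = phase2_records["t"].to_numpy()
    x = phase2_records["x"].to_numpy(dtype=float)
    xc, xe = x[t == 0], x[t == 1]
    if xc.size == 0 or xe.size == 0:
        raise ValueError("both treatment arms must be non-empty")
    n = xc.size + xe.size
    ssq = np.sum((xc - xc.mean()) ** 2) + np.sum((xe - xe.mean()) ** 2)
    if ssq == 0.0 and n > 2:
        raise DegenerateDataError("zero within-arm variance: z statistic is degenerate")
    s2 = ssq / (n - 2)
    return float((xe.mean() - xc.mean()) / np.sqrt(s2 * (1.0 / xc.size + 1.0 / xe.size)))


def _batch_z(x: np.ndarray, n_c: int) -> np.ndarray:
    """Pooled-variance z statistics for a (B, N) batch; first n_c columns are control."""
    xc, xe = x[:, :n_c], x[:, n_c:]
    n_e = xe.shape[1]
    mc, me = xc.mean(axis=1), xe.mean(axis=1)
    ssq = ((xc - mc[:, None]) ** 2).sum(axis=1) + ((xe - me[:, None]) ** 2).sum(axis=1)
    s2 = ssq / (xc.shape[1] + n_e - 2)
    return (me - mc) / np.sqrt(s2 * (1.0 / n_c + 1.0 / n_e))


def simulate_conditional_pair(
    params: PopulationParams,
    design: TrialDesign,
    rng: np.random.Generator | int,
    heterogeneity: str = "outcome",
    effects_override: Mapping[int, Sequence[float]] | None = None,
    max_attempts: int = 10**6,
    _batch: int = 32,
) -> TwoTrialDataset:
    """Simulate one (Phase II, Phase III) pair conditional on a Phase II "go".

    Fresh Phase II trials (with fresh trial effects when
    ``heterogeneity="effect"``) are rejected until the pooled-variance z
    statistic of the early-phase outcome exceeds ``z_{1 - alpha2}``; a single
    Phase III trial is then simulated.  This realizes the truncated Phase II
    distribution exactly, by rejection sampling.

    ``effects_override`` maps trial ids to fixed (bx_k, by_k) pairs and
    bypasses the random effect draws for those trials (used e.g. for
    scenarios with systematically different trial populations).
    """
    rng = np.random.default_rng(rng)
    z_go = stats.norm.ppf(1.0 - design.alpha2)
    sd_x, sd_y, corr = _marginal_moments(params, heterogeneity)
    effects_override = dict(effects_override or {})

    t2 = _treatment_vector(design, 2)
    n_c2 = int(np.sum(t2 == 0))
    random_fx = heterogeneity == "effect" and 2 not in effects_override

    attempts = 0
    accepted = None
    while accepted is None:
        if attempts >= max_attempts:
            raise ConvergenceError(
                f"no Phase II 'go' within {max_attempts} attempts (alpha2={design.alpha2})"
            )
        batch = min(_batch, max_attempts - attempts)
        if random_fx:
            fx2 = draw_trial_effects(params, batch, rng)
        else:
            e2 = effects_override.get(2, (params.bx, params.by))
            fx2 = np.tile(np.asarray(e2, dtype=float), (batch, 1))
        # vectorized batch of candidate Phase II trials
        zx = rng.standard_normal((batch, t2.size))
        x2 = params.ax + fx2[:, :1] * t2 + sd_x * zx
        z = _batch_z(x2, n_c2)
        hits = np.nonzero(z > z_go)[0]
        if hits.size:
            i = int(hits[0])
            attempts += i
            accepted = (x2[i], tuple(fx2[i]))
        else:
            attempts += batch

    x2_acc, effects2 = accepted
    df2 = pd.DataFrame({"trial": 2, "t": t2.astype(int), "x": x2_acc, "y": np.nan})

    if 3 in effects_override:
        effects3 = tuple(np.asarray(effects_override[3], dtype=float))
    elif heterogeneity == "effect":
        effects3 = tuple(draw_trial_effects(params, 1, rng)[0])
    else:
        effects3 = (params.bx, params.by)
    df3 = pd.DataFrame(
        {
            "trial": 3,
            "t": _treatment_vector(design, 3).astype(int),
        }
    )
    x3, y3 = _simulate_xy(
        df3["t"].to_numpy(dtype=float), effects3, params, sd_x, sd_y, corr, rng
    )
    df3["x"], df3["y"] = x3[0], y3[0]

    return TwoTrialDataset(
        records=pd.concat([df2, df3], ignore_index=True),
        realized_effects={2: tuple(effects2), 3: tuple(effects3)},
        go_attempts=attempts,
    )
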