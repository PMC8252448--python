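"""Replicated operating-characteristics simulation for the two-trial setting.

For each replicate a conditional (Phase II "go") trial pair is simulated and
analysed by each requested method; per (method, alpha2) cell the engine
aggregates the mean late-phase effect estimate, the one-sided rejection rate
(type I error under null scenarios, power otherwise), 95% interval coverage
of the true late-phase effect, and the mean interval width — together with
Monte Carlo standard errors so comparisons can be tolerance-aware.

The built-in :data:`SCENARIOS` registry holds the benchmark scenarios:
null (I, with variants by correlation and heterogeneity), common alternative
(II), heterogeneous trial populations (III: no effect in Phase II, 0.2 in
Phase III) and a late-phase-only effect (IV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bayesian import DIFFUSE_PHASE2_PRIORS, MCMCSettings, fit_bdr, two_step_bfdr
from .dataset import TwoTrialDataset
from .frequentist import fit_dr, fit_drc, fit_sr
from .params import PopulationParams, TrialDesign
from .simulate import simulate_conditional_pair

logger = logging.getLogger(__name__)

FREQUENTIST_METHODS = ("sr", "dr", "drc")
BAYESIAN_METHODS = ("bsr", "bdr", "bfdr")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: generative truth, design and run sizes.

    ``n_reps`` applies to the frequentist methods; the MCMC-based methods
    default to the (smaller) ``n_reps_bayes`` replicate count with reduced
    sampler settings — scale both up for publication-grade runs.
    ``true_by`` is the estimand used for coverage; it defaults to the
    generative ``by`` (for heterogeneous-population scenarios like III it
    must be set explicitly to the Phase III trial's effect).
    """

    scenario_id: str = "Ia"
    params: PopulationParams = PopulationParams()
    design: TrialDesign = TrialDesign()
    alpha2_list: tuple[float, ...] = (0.05, 0.1, 0.2)
    n_reps: int = 10_000
    n_reps_bayes: int = 1_000
    master_seed: int = 1
    methods: tuple[str, ...] = FREQUENTIST_METHODS
    heterogeneity: str = "outcome"
    effects_override: Optional[Mapping[int, tuple[float, float]]] = None
    true_by: Optional[float] = None
    drc_plugin: str = "pooled"
    drc_variance_term: str = "n3"
    mcmc: MCMCSettings = MCMCSettings().lighter()
    max_failure_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_reps < 1 or self.n_reps_bayes < 1:
            raise ValueError("replicate counts must be >= 1")
        for a in self.alpha2_list:
            if not 0 < a < 1:
                raise ValueError(f"alpha2 values must lie in (0, 1), got {a}")
        unknown = set(self.methods) - set(FREQUENTIST_METHODS) - set(BAYESIAN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def estimand(self) -> float:
        return self.params.by if self.true_by is None else self.true_by

    def replace(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)


def _scenario(sid: str, **kw) -> ScenarioConfig:
    param_kw = {k: kw.pop(k) for k in list(kw) if k in {f.name for f in fields(PopulationParams)}}
    return ScenarioConfig(scenario_id=sid, params=PopulationParams(**param_kw), **kw)


#: Benchmark scenarios (rho=0.9, tau_x=tau_y=0.01, sigma=1 unless noted).
SCENARIOS: dict[str, ScenarioConfig] = {
    "Ia": _scenario("Ia"),
    "Ib": _scenario("Ib", rho=0.5),
    "Ic": _scenario("Ic", tau_x=0.3, tau_y=0.3),
    "Id": _scenario("Id", rho=0.5, tau_x=0.3, tau_y=0.3),
    "IIa": _scenario("IIa", bx=0.6, by=0.6),
    "IIb": _scenario("IIb", bx=0.6, by=0.6, tau_x=0.3, tau_y=0.3),
    "III": _scenario(
        "III",
        tau_x=0.3,
        tau_y=0.3,
        effects_override={2: (0.0, 0.0), 3: (0.2, 0.2)},
        true_by=0.2,
    ),
    "IV": _scenario("IV", bx=0.0, by=0.6, tau_x=0.3, tau_y=0.3),
}

TABLE_SCENARIOS = {3: ("Ia", "Ib", "Ic", "Id"), 4: ("IIa", "IIb", "III", "IV")}


@dataclass
class OperatingCharacteristics:
    """Aggregated per-(method, alpha2) simulation summaries."""

    scenario_id: str
    table: pd.DataFrame
    n_failures: dict = field(default_factory=dict)

    def cell(self, method: str, alpha2: float) -> pd.Series:
        m = self.table[(self.table["method"] == method) & (np.isclose(self.table["alpha2"], alpha2))]
        if len(m) != 1:
            raise KeyError(f"no unique cell for ({method}, {alpha2})")
        return m.iloc[0]


def _fit_one(
    method: str,
    dataset: TwoTrialDataset,
    design: TrialDesign,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[float, bool, float, float]:
    """(estimate, reject, ci_lower, ci_upper) of one method on one dataset."""
    if method == "sr":
        r = fit_sr(dataset, design)
        return r.by_hat, r.reject, r.ci_lower, r.ci_upper
    if method == "dr":
        r = fit_dr(dataset, design)
        return r.by_hat, r.reject, r.ci_lower, r.ci_upper
    if method == "drc":
        r = fit_drc(
            dataset,
            design,
            plugin=config.drc_plugin,
            variance_term=config.drc_variance_term,
            oracle_params=config.params if config.drc_plugin == "oracle" else None,
            oracle_heterogeneity=config.heterogeneity,
        )
        return r.by_corrected, r.reject, r.ci_lower, r.ci_upper
    if method == "bsr":
        r = fit_bdr(
            dataset,
            DIFFUSE_PHASE2_PRIORS,
            settings=config.mcmc,
            rho_prior_halfwidth=0.01,
            omega_post=design.omega_post,
            rng=rng,
        )
    elif method == "bdr":
        r = fit_bdr(
            dataset,
            DIFFUSE_PHASE2_PRIORS,
            settings=config.mcmc,
            omega_post=design.omega_post,
            rng=rng,
        )
    elif method == "bfdr":
        r = two_step_bfdr(dataset, design, settings=config.mcmc, rng=rng)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown method {method!r}")
    return r.posterior_mean_by, r.decision, r.cri_lower, r.cri_upper


def run_scenario(
    config: ScenarioConfig,
    progress: Optional[Callable[[int, int], None]] = None,
) -> OperatingCharacteristics:
    """Run all (method, alpha2) cells of one scenario.

    Replicate datasets are driven by substreams derived from
    ``master_seed`` and the (alpha2, replicate) indices, so every method
    sees the same simulated trial pairs and cells are reproducible
    independently of which other cells run.
    """
    freq = [m for m in config.methods if m in FREQUENTIST_METHODS]
    bayes = [m for m in config.methods if m in BAYESIAN_METHODS]
    rows = []
    failures: dict[str, int] = {m: 0 for m in config.methods}

    for ai, alpha2 in enumerate(config.alpha2_list):
        design = config.design.replace(alpha2=alpha2)
        n_total = max(config.n_reps if freq else 0, config.n_reps_bayes if bayes else 0)
        acc: dict[str, dict[str, list]] = {
            m: {"est": [], "rej": [], "cov": [], "width": []} for m in config.methods
        }
        for r in range(n_total):
            ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(ai, r))
            data_rng, mcmc_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
            dataset = simulate_conditional_pair(
                config.params,
                design,
                data_rng,
                heterogeneity=config.heterogeneity,
                effects_override=config.effects_override,
            )
            todo = [m for m in freq if r < config.n_reps] + [
                m for m in bayes if r < config.n_reps_bayes
            ]
            for m in todo:
                try:
                    est, rej, lo, hi = _fit_one(m, dataset, design, config, mcmc_rng)
                except Exception as exc:  # noqa: BLE001 - aggregate & re-check below
                    failures[m] += 1
                    logger.warning("replicate %d method %s failed: %s", r, m, exc)
                    continue
                acc[m]["est"].append(est)
                acc[m]["rej"].append(rej)
                acc[m]["cov"].append(lo <= config.estimand <= hi)
                acc[m]["width"].append(hi - lo)
            if progress is not None and (r + 1) % 500 == 0:
                progress(r + 1, n_total)

        for m in config.methods:
            wanted = config.n_reps if m in FREQUENTIST_METHODS else config.n_reps_bayes
            if failures[m] > config.max_failure_rate * wanted:
                raise RuntimeError(
                    f"method {m!r} failed on {failures[m]}/{wanted} replicates "
                    f"(> {config.max_failure_rate:.0%}) in scenario {config.scenario_id}"
                )
            est = np.asarray(acc[m]["est"], dtype=float)
            rej = np.asarray(acc[m]["rej"], dtype=float)
            cov = np.asarray(acc[m]["cov"], dtype=float)
            width = np.asarray(acc[m]["width"], dtype=float)
            n_ok = est.size
            p_rej, p_cov = rej.mean(), cov.mean()
            rows.append(
                {
                    "scenario": config.scenario_id,
                    "method": m,
                    "alpha2": alpha2,
                    "mean_estimate": est.mean(),
                    "rejection_rate": p_rej,
                    "coverage_95": p_cov,
                    "mean_ci_width": width.mean(),
                    "n_reps": n_ok,
                    "mc_se_mean": est.std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else np.nan,
                    "mc_se_rate": np.sqrt(p_rej * (1 - p_rej) / n_ok),
                    "mc_se_coverage": np.sqrt(p_cov * (1 - p_cov) / n_ok),
                }
            )

    return OperatingCharacteristics(
        scenario_id=config.scenario_id,
        table=pd.DataFrame(rows),
        n_failures=failures,
    )


def reproduce_table(
    which: int,
    n_reps: int = 10_000,
    n_reps_bayes: int = 1_000,
    seed: int = 1,
    methods: Sequence[str] = FREQUENTIST_METHODS,
    scenarios: Optional[Sequence[str]] = None,
    mcmc: Optional[MCMCSettings] = None,
) -> pd.DataFrame:
    """Recompute the benchmark operating-characteristics table (3 or 4).

    Returns one row per (scenario, method, alpha2) cell with Monte Carlo
    standard errors; byte-identical for identical seeds.
    """
    if which not in TABLE_SCENARIOS:
        raise ValueError(f"which must be 3 or 4, got {which}")
    sids = tuple(scenarios) if scenarios is not None else TABLE_SCENARIOS[which]
    parts = []
    for sid in sids:
        cfg = SCENARIOS[sid].replace(
            n_reps=n_reps,
            n_reps_bayes=n_reps_bayes,
            master_seed=seed,
            methods=tuple(methods),
        )
        if mcmc is not None:
            cfg = cfg.replace(mcmc=mcmc)
        parts.append(run_scenario(cfg).table)
    return pd.concat(parts, ignore_index=True)


def power_curves(
    effect_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)),
    splits: Mapping[str, tuple[int, int]] = {"1:1": (60, 60), "1:2": (40, 80)},
    rho_list: Sequence[float] = (0.1, 0.9),
    n_reps: int = 10_000,
    seed: int = 1,
    alpha2: float = 0.1,
    methods: Sequence[str] = ("sr", "dr"),
) -> pd.DataFrame:
    """Conditional power curves over a grid of common effects by = bx.

    The default setup splits N = 120 patients between the trials as 1:1 or
    1:2 (equal arms within each trial), with sigma_x = sigma_y = 1, no
    between-trial variation, and a Phase II go at alpha2 = 0.1.
    """
    if len(effect_grid) == 0:
        raise ValueError("effect grid must be non-empty")
    rows = []
    for split_name, (N2, N3) in splits.items():
        design = TrialDesign(N2=N2, N3=N3, alloc2=(1, 1), alloc3=(1, 1), alpha2=alpha2)
        for rho in rho_list:
            for b in effect_grid:
                cfg = ScenarioConfig(
                    scenario_id=f"fig2-{split_name}-rho{rho}-b{b}",
                    params=PopulationParams(bx=b, by=b, rho=rho, tau_x=0.0, tau_y=0.0),
                    design=design,
                    alpha2_list=(alpha2,),
                    n_reps=n_reps,
                    master_seed=seed,
                    methods=tuple(methods),
                )
                oc = run_scenario(cfg)
                for m in methods:
                    cell = oc.cell(m, alpha2)
                    rows.append(
                        {
                            "split": split_name,
                            "rho": rho,
                            "effect": b,
                            "method": m,
                            "rejection_rate": cell["rejection_rate"],
                            "mc_se_rate": cell["mc_se_rate"],
                            "n_reps": cell["n_reps"],
                        }
                    )
    return pd.DataFrame(rows)
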