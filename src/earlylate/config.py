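"""Configuration files, result serialization and run manifests.

Scenario configurations are YAML mappings mirroring the
:class:`~earlylate.params.PopulationParams`, :class:`~earlylate.params.TrialDesign`
and :class:`~earlylate.study.ScenarioConfig` field names, e.g.::

    scenario_id: IIa
    params: {bx: 0.6, by: 0.6, rho: 0.9, tau_x: 0.01, tau_y: 0.01}
    design: {N2: 67, N3: 52, alloc3: [1, 2]}
    alpha2_list: [0.05, 0.1, 0.2]
    n_reps: 10000
    master_seed: 1
    methods: [sr, dr, drc]

An empty file yields the default null-scenario configuration
(rho = 0.9, tau_x = tau_y = 0.01, sigma_x = sigma_y = 1, alpha3 = 0.05).
Unknown keys are rejected with an explicit listing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .bayesian import MCMCSettings
from .params import PopulationParams, TrialDesign
from .study import ScenarioConfig

_PARAM_KEYS = {f.name for f in dataclasses.fields(PopulationParams)}
_DESIGN_KEYS = {f.name for f in dataclasses.fields(TrialDesign)}
_MCMC_KEYS = {f.name for f in dataclasses.fields(MCMCSettings)}
_TOP_KEYS = {
    "scenario_id",
    "params",
    "design",
    "alpha2_list",
    "n_reps",
    "n_reps_bayes",
    "master_seed",
    "methods",
    "heterogeneity",
    "effects_override",
    "true_by",
    "drc_plugin",
    "drc_variance_term",
    "mcmc",
}


def _check_keys(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {unknown}")


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse and validate a scenario configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: Mapping) -> ScenarioConfig:
    _check_keys(raw, _TOP_KEYS, "config")
    kwargs: dict = {}
    if "params" in raw:
        _check_keys(raw["params"], _PARAM_KEYS, "params")
        kwargs["params"] = PopulationParams(**raw["params"])
    if "design" in raw:
        d = dict(raw["design"])
        _check_keys(d, _DESIGN_KEYS, "design")
        for k in ("alloc2", "alloc3"):
            if k in d:
                d[k] = tuple(d[k])
        kwargs["design"] = TrialDesign(**d)
    if "mcmc" in raw:
        _check_keys(raw["mcmc"], _MCMC_KEYS, "mcmc")
        kwargs["mcmc"] = MCMCSettings(**raw["mcmc"])
    if "effects_override" in raw and raw["effects_override"] is not None:
        kwargs["effects_override"] = {
            int(k): tuple(map(float, v)) for k, v in raw["effects_override"].items()
        }
    if "alpha2_list" in raw:
        kwargs["alpha2_list"] = tuple(raw["alpha2_list"])
    if "methods" in raw:
        kwargs["methods"] = tuple(raw["methods"])
    for key in (
        "scenario_id",
        "n_reps",
        "n_reps_bayes",
        "master_seed",
        "heterogeneity",
        "true_by",
        "drc_plugin",
        "drc_variance_term",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return ScenarioConfig(**kwargs)


def config_to_dict(config: ScenarioConfig) -> dict:
    """Normalized plain-dict form of a configuration (YAML/JSON friendly)."""
    out = {
        "scenario_id": config.scenario_id,
        "params": dataclasses.asdict(config.params),
        "design": {
            **dataclasses.asdict(config.design),
            "alloc2": list(config.design.alloc2),
            "alloc3": list(config.design.alloc3),
        },
        "alpha2_list": list(config.alpha2_list),
        "n_reps": config.n_reps,
        "n_reps_bayes": config.n_reps_bayes,
        "master_seed": config.master_seed,
        "methods": list(config.methods),
        "heterogeneity": config.heterogeneity,
        "effects_override": (
            {int(k): list(v) for k, v in config.effects_override.items()}
            if config.effects_override
            else None
        ),
        "true_by": config.true_by,
        "drc_plugin": config.drc_plugin,
        "drc_variance_term": config.drc_variance_term,
        "mcmc": dataclasses.asdict(config.mcmc),
    }
    return out


def dump_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


# ---------------------------------------------------------------------------
# results + manifest
# ---------------------------------------------------------------------------
@dataclass
class RunManifest:
    """Provenance record of one command-line run."""

    command: str
    seed: Optional[int]
    config: Optional[dict] = None
    version: str = ""
    outputs: list = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def record(self, path: str | Path, kind: str) -> None:
        self.outputs.append({"path": str(path), "kind": kind})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _round_sig(x, digits: int = 6):
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x) or x == 0:
            return float(x)
        return float(f"{x:.{digits}g}")
    return x


def write_results(
    results: "pd.DataFrame | Mapping",
    path: str | Path,
    fmt: str = "csv",
    manifest: Optional[RunManifest] = None,
) -> dict:
    """Serialize a result table/mapping deterministically.

    Columns keep their existing order, floats are written at 6 significant
    digits, and two writes of the same results are byte-identical.
    """
    path = Path(path)
    if fmt not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if fmt == "csv":
            df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
        else:
            records = [
                {k: _round_sig(v) for k, v in row.items()} for row in df.to_dict("records")
            ]
            path.write_text(json.dumps(records, indent=2, sort_keys=False) + "\n")
    else:
        payload = {k: _round_sig(v) for k, v in dict(results).items()}
        if fmt == "csv":
            pd.DataFrame([payload]).to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
        else:
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    entry = {"path": str(path), "kind": fmt}
    if manifest is not None:
        manifest.record(path, fmt)
    return entry
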