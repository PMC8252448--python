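"""Patient-level container for one Phase II + Phase III trial pair.

The canonical in-memory representation is a :class:`pandas.DataFrame` with
columns ``trial`` (2 or 3), ``t`` (treatment indicator 0/1), ``x`` (early-phase
response) and ``y`` (late-phase response, NaN for every Phase II patient —
the late-phase outcome is never observed in the Phase II trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ["trial", "t", "x", "y"]


@dataclass
class TwoTrialDataset:
    """Records of both trials plus generation diagnostics.

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``trial, t, x, y``; ``y`` is NaN exactly for trial-2 rows.
    realized_effects : dict
        Per-trial realized treatment-effect pairs ``{trial: (bx_k, by_k)}``
        used during generation (diagnostics only; empty for imported data).
    go_attempts : int
        Number of Phase II simulations discarded before a "go" decision
        (0 for unconditional or imported data).
    """

    records: pd.DataFrame
    realized_effects: dict = field(default_factory=dict)
    go_attempts: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        self.records = self.records[COLUMNS].reset_index(drop=True)
        trials = set(self.records["trial"].unique())
        if not trials <= {2, 3}:
            raise ValueError(f"trial column may only contain 2 and 3, got {sorted(trials)}")
        mask2 = self.records["trial"] == 2
        if not self.records.loc[mask2, "y"].isna().all():
            raise ValueError("y must be missing for every Phase II (trial=2) record")
        if self.records.loc[~mask2, "y"].isna().any():
            raise ValueError("y must be observed for every Phase III (trial=3) record")
        if self.go_attempts < 0:
            raise ValueError("go_attempts must be >= 0")

    # -- convenient views ---------------------------------------------------
    @property
    def phase2(self) -> pd.DataFrame:
        """Phase II records; the y column is dropped so downstream code can
        never read the masked late-phase outcome."""
        return self.records.loc[self.records["trial"] == 2, ["trial", "t", "x"]]

    @property
    def phase3(self) -> pd.DataFrame:
        return self.records.loc[self.records["trial"] == 3]

    @property
    def n_patients(self) -> int:
        return len(self.records)

    # -- plain-text round trip ----------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write ``trial,t,x,y`` CSV; missing y encoded as an empty field."""
        out = self.records.copy()
        out["trial"] = out["trial"].astype(int)
        out["t"] = out["t"].astype(int)
        out.to_csv(path, index=False, float_format="%.10g", na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TwoTrialDataset":
        df = pd.read_csv(path, header=0)
        df["trial"] = df["trial"].astype(int)
        df["t"] = df["t"].astype(int)
        df["x"] = df["x"].astype(float)
        df["y"] = pd.to_numeric(df["y"], errors="coerce")
        return cls(records=df)


def stack_trials(frames: list[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(frames, ignore_index=True)


def arm_arrays(df: pd.DataFrame, column: str = "x") -> tuple[np.ndarray, np.ndarray]:
    """(control, experimental) value arrays of ``column``."""
    t = df["t"].to_numpy()
    v = df[column].to_numpy(dtype=float)
    return v[t == 0], v[t == 1]
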