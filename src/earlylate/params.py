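"""Population parameters and trial-design descriptions for the two-trial setting.

The generative model is a bivariate normal for the early-phase (biomarker)
response ``x`` and the late-phase clinical response ``y`` of each patient:

    (x, y) ~ BVN( (ax + bx*t, ay + by*t),  Sigma )

with treatment indicator ``t`` in {0, 1} and

    Sigma = [[sigma_x**2,              rho*sigma_x*sigma_y],
             [rho*sigma_x*sigma_y,     sigma_y**2         ]].

``tau_x`` and ``tau_y`` are between-trial heterogeneity standard deviations
on the early- and late-phase outcomes (see :mod:`earlylate.simulate` for the
two supported heterogeneity mechanisms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields


@dataclass(frozen=True)
class PopulationParams:
    """True generative parameters of the bivariate-normal patient model.

    Parameters
    ----------
    ax, ay : float
        Control-arm intercepts (mean response under control) of the early-
        and late-phase outcomes, in outcome units.
    bx, by : float
        True treatment effects on the early- and late-phase outcomes.
    sigma_x, sigma_y : float
        Within-trial residual standard deviations, strictly positive.
    rho : float
        Within-patient correlation of the (x, y) residuals, in [-1, 1].
    tau_x, tau_y : float
        Between-trial heterogeneity SDs (>= 0) of the early- and late-phase
        outcomes.
    """

    ax: float = 0.0
    bx: float = 0.0
    ay: float = 0.0
    by: float = 0.0
    sigma_x: float = 1.0
    sigma_y: float = 1.0
    rho: float = 0.9
    tau_x: float = 0.01
    tau_y: float = 0.01

    def __post_init__(self) -> None:
        if not self.sigma_x > 0:
            raise ValueError(f"sigma_x must be > 0, got {self.sigma_x}")
        if not self.sigma_y > 0:
            raise ValueError(f"sigma_y must be > 0, got {self.sigma_y}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.tau_x < 0:
            raise ValueError(f"tau_x must be >= 0, got {self.tau_x}")
        if self.tau_y < 0:
            raise ValueError(f"tau_y must be >= 0, got {self.tau_y}")

    @property
    def gamma(self) -> float:
        """Slope of y on x in the conditional model, rho * sigma_y / sigma_x."""
        return self.rho * self.sigma_y / self.sigma_x

    def replace(self, **changes) -> "PopulationParams":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(changes)
        return PopulationParams(**current)


def _split_arms(total: int, control_ratio: float, experimental_ratio: float) -> tuple[int, int]:
    """Largest-remainder rounding of ``total`` into control/experimental arms."""
    denom = control_ratio + experimental_ratio
    exact_c = total * control_ratio / denom
    exact_e = total * experimental_ratio / denom
    n_c, n_e = math.floor(exact_c), math.floor(exact_e)
    # ties go to the control arm (e.g. 67 patients at 1:1 -> 34 control, 33 experimental)
    remainders = [(exact_c - n_c, 1, "c"), (exact_e - n_e, 0, "e")]
    remainders.sort(reverse=True)
    short = total - n_c - n_e
    for _, _, arm in remainders[:short]:
        if arm == "c":
            n_c += 1
        else:
            n_e += 1
    return n_c, n_e


@dataclass(frozen=True)
class TrialDesign:
    """Sample sizes, allocation ratios and decision thresholds of both trials.

    Defaults follow the migalastat (Fabry disease) development program that
    motivates the methods: a Phase II trial of 67 patients with roughly 1:1
    allocation and a Phase III trial of 52 patients with 1:2
    control:experimental allocation.

    Notes
    -----
    The analytical machinery works on the per-arm convention
    ``n_k = N_k / 2`` regardless of the realized allocation, with
    ``n = n2 + n3`` and trial weights ``w2 = n2 / n``, ``w3 = n3 / n``.
    """

    N2: int = 67
    N3: int = 52
    alloc2: tuple[float, float] = (1.0, 1.0)
    alloc3: tuple[float, float] = (1.0, 2.0)
    alpha2: float = 0.05
    alpha3: float = 0.05
    omega_post: float = 0.95

    def __post_init__(self) -> None:
        for name, N in (("N2", self.N2), ("N3", self.N3)):
            if N < 4:
                raise ValueError(f"{name} must be >= 4, got {N}")
        for name, a in (("alpha2", self.alpha2), ("alpha3", self.alpha3)):
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if not 0 < self.omega_post < 1:
            raise ValueError(f"omega_post must lie in (0, 1), got {self.omega_post}")
        for name, alloc in (("alloc2", self.alloc2), ("alloc3", self.alloc3)):
            if len(alloc) != 2 or alloc[0] <= 0 or alloc[1] <= 0:
                raise ValueError(f"{name} must be a pair of positive ratios, got {alloc}")

    # -- per-arm convention -------------------------------------------------
    @property
    def n2(self) -> float:
        return self.N2 / 2

    @property
    def n3(self) -> float:
        return self.N3 / 2

    @property
    def n(self) -> float:
        return self.n2 + self.n3

    @property
    def w2(self) -> float:
        return self.n2 / self.n

    @property
    def w3(self) -> float:
        return self.n3 / self.n

    # -- realized arm sizes -------------------------------------------------
    def arm_sizes(self, trial: int) -> tuple[int, int]:
        """(control, experimental) patient counts for ``trial`` in {2, 3}."""
        if trial == 2:
            return _split_arms(self.N2, *self.alloc2)
        if trial == 3:
            return _split_arms(self.N3, *self.alloc3)
        raise ValueError(f"trial must be 2 or 3, got {trial}")

    def replace(self, **changes) -> "TrialDesign":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(changes)
        return TrialDesign(**current)
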