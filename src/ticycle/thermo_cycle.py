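"""Thermodynamic-cycle ddG with error propagation and convergence reporting.

Alchemical legs (native -> modified) computed in three contexts close a
thermodynamic cycle with the physical processes of dimerization and
folding:

    ddG_dimerization = dG_dim - 2 dG_mono      (homodimer: two monomers)
    ddG_folding      = dG_mono - dG_unf

Positive values mean the modification destabilizes the dimer (monomer).
Legs are treated as statistically independent, so sigmas add in
quadrature with the squared stoichiometric coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ti_core import FreeEnergyEstimate, LambdaPointEstimate
from .units import R_GAS

__all__ = [
    "CycleLegs",
    "DdgResult",
    "ConvergenceReport",
    "ddg_dimerization",
    "ddg_folding",
    "classify",
    "population_ratio_shift",
    "thermal_reference",
    "convergence_report",
    "cycle_result",
]


@dataclass(frozen=True)
class CycleLegs:
    """The three alchemical legs of one modification's cycle."""

    dg_dimer: FreeEnergyEstimate | None = None
    dg_monomer: FreeEnergyEstimate | None = None
    dg_unfolded: FreeEnergyEstimate | None = None
    temperature: float = 300.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def ddg_dimerization(legs: CycleLegs) -> tuple[float, float]:
    """Change in dimerization free energy: dG_dim - 2 dG_mono.

    sigma = sqrt(sigma_dim^2 + 4 sigma_mono^2); positive = dimer
    destabilized by the modification.
    """
    if legs.dg_dimer is None or legs.dg_monomer is None:
        raise ValueError("dimerization ddG needs both dimer and monomer legs")
    ddg = legs.dg_dimer.delta_g - 2.0 * legs.dg_monomer.delta_g
    sigma = float(np.sqrt(legs.dg_dimer.sigma**2 + 4.0 * legs.dg_monomer.sigma**2))
    return ddg, sigma


def ddg_folding(legs: CycleLegs) -> tuple[float, float]:
    """Change in folding free energy: dG_mono - dG_unf.

    sigma = sqrt(sigma_mono^2 + sigma_unf^2); positive = monomer
    destabilized.
    """
    if legs.dg_monomer is None or legs.dg_unfolded is None:
        raise ValueError("folding ddG needs both monomer and unfolded legs")
    ddg = legs.dg_monomer.delta_g - legs.dg_unfolded.delta_g
    sigma = float(np.sqrt(legs.dg_monomer.sigma**2 + legs.dg_unfolded.sigma**2))
    return ddg, sigma


def classify(ddg: float, sigma: float, multiplier: float = 1.0) -> str:
    """Label an effect: insignificant when |ddG| <= multiplier * sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if abs(ddg) <= multiplier * sigma:
        return "insignificant"
    return "destabilizing" if ddg > 0 else "stabilizing"


@dataclass(frozen=True)
class DdgResult:
    """ddG of dimerization and folding with propagated errors and labels."""

    ddg_dimerization: float
    sigma_dimerization: float
    ddg_folding: float
    sigma_folding: float
    class_dimerization: str
    class_folding: str

    def to_dict(self) -> dict:
        return {
            "ddg_dimerization_kj_mol": self.ddg_dimerization,
            "sigma_dimerization_kj_mol": self.sigma_dimerization,
            "class_dimerization": self.class_dimerization,
            "ddg_folding_kj_mol": self.ddg_folding,
            "sigma_folding_kj_mol": self.sigma_folding,
            "class_folding": self.class_folding,
        }


def cycle_result(legs: CycleLegs, multiplier: float = 1.0) -> DdgResult:
    """Both cycle ddGs with classification (needs all three legs)."""
    dd, sd = ddg_dimerization(legs)
    df, sf = ddg_folding(legs)
    return DdgResult(
        ddg_dimerization=dd,
        sigma_dimerization=sd,
        ddg_folding=df,
        sigma_folding=sf,
        class_dimerization=classify(dd, sd, multiplier),
        class_folding=classify(df, sf, multiplier),
    )


def population_ratio_shift(ddg: float, temperature: float = 300.0) -> float:
    """Fold-change of the unfolded:folded population ratio, exp(ddG/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(ddg / (R_GAS * temperature)))


def thermal_reference(temperature: float = 300.0) -> float:
    """2RT in kJ/mol, the yardstick for acceptable per-lambda error."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return 2.0 * R_GAS * temperature


@dataclass(frozen=True)
class ConvergenceReport:
    """Distribution of per-lambda SEMs against error thresholds."""

    n_points: int
    mean_sem: float
    fraction_below: dict  # threshold -> fraction of SEMs below it
    thermal_reference: float
    per_system_unconverged: dict  # system name -> bool

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "mean_sem_kj_mol": self.mean_sem,
            "fraction_below": {str(k): v for k, v in self.fraction_below.items()},
            "thermal_reference_2rt_kj_mol": self.thermal_reference,
            "per_system_unconverged": dict(self.per_system_unconverged),
        }


def convergence_report(
    points: Sequence[LambdaPointEstimate] | Mapping[str, Sequence[LambdaPointEstimate]],
    thresholds: Sequence[float] = (10.0, 20.0),
    temperature: float = 300.0,
    unconverged_fraction: float = 0.2,
    unconverged_threshold: float = 20.0,
) -> ConvergenceReport:
    """Summarize per-lambda statistical errors across one or more systems.

    A system is flagged unconverged when more than ``unconverged_fraction``
    of its SEMs exceed ``unconverged_threshold`` kJ/mol (the exclusion rule
    for systems whose sampling did not converge).
    """
    if isinstance(points, Mapping):
        systems = {name: list(pts) for name, pts in points.items()}
    else:
        systems = {"all": list(points)}
    all_points = [p for pts in systems.values() for p in pts]
    if not all_points:
        raise ValueError("convergence report needs at least one lambda point")
    sems = np.array([p.sem for p in all_points])
    fraction_below = {
        float(t): float(np.mean(sems < t)) for t in thresholds
    }
    flags = {}
    for name, pts in systems.items():
        if not pts:
            raise ValueError(f"system {name!r} has no lambda points")
        s = np.array([p.sem for p in pts])
        flags[name] = bool(np.mean(s > unconverged_threshold) > unconverged_fraction)
    return ConvergenceReport(
        n_points=len(all_points),
        mean_sem=float(np.mean(sems)),
        fraction_below=fraction_below,
        thermal_reference=thermal_reference(temperature),
        per_system_unconverged=flags,
    )
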