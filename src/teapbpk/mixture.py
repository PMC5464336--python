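"""Ternary catechin-mixture simulation and EGCg-equivalent dosimetry.

The mixture model links the single-catechin models under a no-interaction
assumption: each member is integrated independently against the shared
physiology, so by construction every member's curve equals its solo
simulation (superposition). Mixture-level dosimetry converts per-catechin
concentrations or doses into EGCg equivalents with inhibitory equivalence
factors (IEFs) derived from EROD-inhibition IC50s, and the dose-response
summary regresses plasma EGCg equivalents on the administered
EGCg-equivalent dose.

Note the IEF convention is IEF_i = IC50_i / IC50_EGCg — a *larger* weight
for a *less* potent EROD inhibitor, the opposite of the usual potency
normalization. It is kept because it is the convention behind the
published equivalence factors (1.00, 0.85, 0.45, 2.21 for EGCg, EGC, ECg,
EC); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import DoseEvent, SimulationResult, SolverSettings, load_model, simulate
from .errors import DomainError, LookupError_
from .params import load_catechin_physchem

REFERENCE_CATECHIN = "EGCg"


def ief_from_ic50(ic50_i: float, ic50_ref: float) -> float:
    """Inhibitory equivalence factor: IC50_i / IC50_reference."""
    if ic50_i <= 0 or ic50_ref <= 0:
        raise DomainError("IC50 values must be positive")
    return ic50_i / ic50_ref


@dataclass(frozen=True)
class IEFTable:
    """Per-catechin inhibitory equivalence factors; the reference catechin
    (EGCg) is pinned at exactly 1.00."""

    values: dict[str, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise DomainError("equivalence factors must be positive")
        if self.values.get(REFERENCE_CATECHIN) != 1.00:
            raise DomainError(f"{REFERENCE_CATECHIN} must carry IEF 1.00")

    def __getitem__(self, catechin_id: str) -> float:
        try:
            return self.values[catechin_id]
        except KeyError:
            raise LookupError_(
                f"no equivalence factor for {catechin_id!r}; "
                f"known: {sorted(self.values)}"
            ) from None

    @classmethod
    def from_ic50(cls, ic50: dict[str, float]) -> "IEFTable":
        ref = ic50[REFERENCE_CATECHIN]
        vals = {k: ief_from_ic50(v, ref) for k, v in ic50.items()}
        vals[REFERENCE_CATECHIN] = 1.00
        return cls(vals)


def default_ief_table() -> IEFTable:
    """IEFs from the packaged EROD IC50s (EGCg as reference), rounded to
    the two decimals at which the factors were published and applied
    (1.00, 0.45, 0.85, 2.21 for EGCg, ECg, EGC, EC)."""
    ic50 = {c: load_catechin_physchem(c).ic50_erod
            for c in ("EGCg", "ECg", "EGC", "EC")}
    table = IEFTable.from_ic50(ic50)
    return IEFTable({k: round(v, 2) for k, v in table.values.items()})


def tcm_equivalent(values: dict[str, float], ief: IEFTable | None = None) -> float:
    """EGCg-equivalent sum of per-catechin concentrations or doses:
    sum_i C_i * IEF_i."""
    ief = ief or default_ief_table()
    return float(sum(c * ief[k] for k, c in values.items()))


@dataclass(frozen=True)
class MixtureScenario:
    """A co-administered catechin mixture for one subject."""

    species_id: str
    BW: float
    members: tuple  # of (catechin_id, dose_mg_per_kg, study_id)

    def __post_init__(self):
        if len(self.members) == 0:
            raise DomainError("a mixture needs at least one member")
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise DomainError("member catechins must be distinct")
        if any(m[1] < 0 for m in self.members):
            raise DomainError("doses must be non-negative")
        if self.BW <= 0:
            raise DomainError("body weight must be positive")


def simulate_mixture(
    scenario: MixtureScenario,
    t_end: float,
    output_step: float = 0.05,
    solver: SolverSettings | None = None,
) -> dict[str, SimulationResult]:
    """Integrate every member independently (no pharmacokinetic
    interaction); results keyed by catechin."""
    results: dict[str, SimulationResult] = {}
    for catechin_id, dose, study_id in scenario.members:
        model = load_model(catechin_id, scenario.species_id, scenario.BW, study_id)
        results[catechin_id] = simulate(
            model, DoseEvent(catechin_id, dose), t_end, output_step, solver
        )
    return results


@dataclass(frozen=True)
class DoseResponsePoint:
    """One study's (administered EGCg-equivalent dose, plasma
    EGCg-equivalent concentration) pair."""

    administered_dose_metric: float  # mg EGCg equivalents / kg
    plasma_tcm: float  # ug EGCg equivalents / mL
    label: str = ""

    def __post_init__(self):
        if self.administered_dose_metric < 0 or self.plasma_tcm < 0:
            raise DomainError("dose metric and plasma level must be non-negative")


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # ug/mL per mg/kg
    intercept: float
    r_squared: float
    stderr_slope: float
    n: int


def dose_response_regression(
    points: list[DoseResponsePoint] | tuple[DoseResponsePoint, ...],
) -> RegressionResult:
    """Ordinary least squares of plasma EGCg equivalents on the
    administered EGCg-equivalent dose (intercept estimated, not forced
    through the origin)."""
    if len(points) < 3:
        raise DomainError("need at least three points for the regression")
    x = np.array([p.administered_dose_metric for p in points])
    y = np.array([p.plasma_tcm for p in points])
    if np.ptp(x) == 0:
        raise DomainError("administered doses have zero spread")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        stderr_slope=float(fit.stderr),
        n=len(points),
    )


def mixture_cmax_dosimetry(
    results: dict[str, SimulationResult],
    ief: IEFTable | None = None,
) -> dict[str, float]:
    """Peak plasma concentration per member plus the EGCg-equivalent total
    (the concentration-additivity dose surrogate)."""
    peaks = {k: float(np.max(r.plasma)) for k, r in results.items()}
    peaks["tcm_equivalent"] = tcm_equivalent(
        {k: v for k, v in peaks.items() if k != "tcm_equivalent"}, ief
    )
    return peaks


__all__ = [
    "REFERENCE_CATECHIN", "IEFTable", "MixtureScenario", "DoseResponsePoint",
    "RegressionResult", "ief_from_ic50", "default_ief_table", "tcm_equivalent",
    "simulate_mixture", "dose_response_regression", "mixture_cmax_dosimetry",
]
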