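"""Flow-limited PBPK engine for a single catechin.

The body is described by 13 perfusion-limited tissue compartments (lung,
arterial and venous blood, liver, gut tissue, spleen, kidney, muscle, skin,
adipose, bone, brain, heart, rest of body) plus bookkeeping pools for the
gut lumen, the enterohepatic loop and cumulative excretion. All kinetics
are first order, so the system is linear in the dose.

Right-hand side, in amounts (ug), concentrations C_i = A_i / V_i:

* non-eliminating perfused tissue t:  dA_t/dt = Q_t (C_art - C_t / P_t)
* lung (receives total venous return, vents to arterial blood):
  dA_lg/dt = CO (C_ven - C_lg / P_lg);  dA_art/dt = CO (C_lg / P_lg - C_art)
* venous blood collects every tissue's venous outflow:
  dA_ven/dt = sum_t Q_t C_t / P_t + Q_h C_lv / P_lv - CO C_ven
* portal architecture: gut tissue and spleen drain into the liver; the
  hepatic artery carries the liver's listed (total hepatic) flow minus the
  portal contributions, and the liver drains to venous blood at the total
  hepatic flow Q_h
* oral dose: at t = tlag the absorbable fraction F*D enters a lumen pool
  draining into gut tissue at k_a; the remaining (1-F)*D enters a second
  lumen pool draining to feces at k_f, so mass is conserved exactly
* enterohepatic loop: the liver secretes at biliary clearance CL_b into a
  single first-order bile transit stage with rate 1/R_t; the distal pool it
  feeds is either reabsorbed into gut tissue (k_ra) or lost to feces (k_f)
* clearances reference plasma concentration: biliary flux =
  CL_b (C_lv/P_lv)/BLPLR, renal flux = CL_r (C_kd/P_kd)/BLPLR (to urine)

The single blood volume of the physiology tables is split one third
arterial, two thirds venous, the conventional PBPK partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConsistencyError, DomainError, IntegrationError
from .params import (
    CatechinPhysChem,
    CatechinPKParams,
    ScaledPKParams,
    SpeciesPhysiology,
    load_catechin_physchem,
    load_pk_params,
    load_species_physiology,
    validate_physiology,
)
from .partition import PartitionSet, load_partition_set

#: full state layout: 14 tissue/blood slots, 2 lumen pools, bile transit,
#: distal recycle pool, and the two cumulative excretion pools
STATE_NAMES = (
    "lung", "arterial", "venous", "liver", "gut", "spleen", "kidney",
    "muscle", "skin", "adipose", "bone", "brain", "heart", "rest_of_body",
    "lumen_absorbable", "lumen_nonabsorbable", "bile", "recycle",
    "urine", "feces",
)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
#: perfused tissues that drain straight to venous blood
_SIMPLE = ("kidney", "muscle", "skin", "adipose", "bone", "brain", "heart",
           "rest_of_body")


@dataclass(frozen=True)
class DoseEvent:
    """A single oral bolus, in mg per kg body weight."""

    catechin_id: str
    dose: float
    route: str = "oral"
    time: float = 0.0

    def __post_init__(self):
        if self.dose < 0:
            raise DomainError("dose must be non-negative")
        if self.route != "oral":
            raise DomainError("only the oral route is modelled")
        if self.time < 0:
            raise DomainError("dose time must be non-negative")


@dataclass(frozen=True)
class SolverSettings:
    """Integration contract: stiff-capable solver, tight tolerances."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf


@dataclass(frozen=True)
class ModelSpec:
    """Assembled single-catechin model: physiology, chemistry, BW-scaled
    kinetics and partitioning, ready for integration."""

    physiology: SpeciesPhysiology
    physchem: CatechinPhysChem
    pk: CatechinPKParams
    scaled: ScaledPKParams
    partitions: PartitionSet

    @property
    def catechin_id(self) -> str:
        return self.physchem.catechin_id

    @property
    def species_id(self) -> str:
        return self.physiology.species_id


def build_model(
    physiology: SpeciesPhysiology,
    physchem: CatechinPhysChem,
    pk: CatechinPKParams,
    partitions: PartitionSet,
) -> ModelSpec:
    """Assemble and cross-validate the model components.

    All pieces must refer to the same catechin and species, the physiology
    must pass its balance audit, and every perfused compartment (plus lung)
    needs a partition coefficient.
    """
    if not (physchem.catechin_id == pk.catechin_id == partitions.catechin_id):
        raise ConsistencyError(
            "catechin tags disagree: "
            f"physchem={physchem.catechin_id!r}, pk={pk.catechin_id!r}, "
            f"partitions={partitions.catechin_id!r}"
        )
    if physiology.species_id != pk.species_id:
        raise ConsistencyError(
            f"species tags disagree: physiology={physiology.species_id!r}, "
            f"pk={pk.species_id!r}"
        )
    report = validate_physiology(physiology)
    if not report.passed:
        raise DomainError("physiology fails validation: " + "; ".join(report.messages))
    needed = set(_SIMPLE) | {"liver", "gut", "spleen", "lung"}
    missing = needed - set(partitions.values)
    if missing:
        raise DomainError(f"partition coefficients missing for {sorted(missing)}")
    return ModelSpec(
        physiology=physiology,
        physchem=physchem,
        pk=pk,
        scaled=pk.scaled(physiology.BW),
        partitions=partitions,
    )


def load_model(
    catechin_id: str,
    species_id: str,
    BW: float,
    study_id: str | None = None,
    pk_overrides: dict[str, float] | None = None,
) -> ModelSpec:
    """Convenience constructor from the packaged parameter tables."""
    return build_model(
        load_species_physiology(species_id, BW),
        load_catechin_physchem(catechin_id),
        load_pk_params(catechin_id, species_id, study_id, pk_overrides),
        load_partition_set(catechin_id, species_id),
    )


def _make_rhs(model: ModelSpec) -> Callable[[float, np.ndarray], np.ndarray]:
    phys = model.physiology
    p = model.scaled
    P = model.partitions
    blplr = model.physchem.BLPLR

    co = phys.cardiac_output
    v_blood = phys.volume("blood")
    v_art, v_ven = v_blood / 3.0, 2.0 * v_blood / 3.0
    v_lung = phys.volume("lung")
    p_lung = P["lung"]

    q_simple = np.array([phys.flow(t) for t in _SIMPLE])
    v_simple = np.array([phys.volume(t) for t in _SIMPLE])
    p_simple = np.array([P[t] for t in _SIMPLE])
    i_simple = np.array([_IDX[t] for t in _SIMPLE])

    q_gut, v_gut, p_gut = phys.flow("gut"), phys.volume("gut"), P["gut"]
    q_sp, v_sp, p_sp = phys.flow("spleen"), phys.volume("spleen"), P["spleen"]
    q_h, v_lv, p_lv = phys.flow("liver"), phys.volume("liver"), P["liver"]
    q_ha = phys.hepatic_artery_flow

    cl_b, cl_r = p.CL_b, p.CL_r
    k_a, k_ra, k_f = p.k_a, p.k_ra, p.k_f
    k_bile = 1.0 / p.R_t if p.R_t > 0 else None
    i_kd = _SIMPLE.index("kidney")

    LG, ART, VEN, LV, GT, SP = (_IDX[n] for n in
                                ("lung", "arterial", "venous", "liver", "gut", "spleen"))
    LA, LN, BI, RC, UR, FE = (_IDX[n] for n in
                              ("lumen_absorbable", "lumen_nonabsorbable",
                               "bile", "recycle", "urine", "feces"))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        c_art = y[ART] / v_art
        c_ven = y[VEN] / v_ven
        c_lg_out = y[LG] / v_lung / p_lung
        c_simple_out = y[i_simple] / v_simple / p_simple
        c_gut_out = y[GT] / v_gut / p_gut
        c_sp_out = y[SP] / v_sp / p_sp
        c_lv_out = y[LV] / v_lv / p_lv

        renal = cl_r * c_simple_out[i_kd] / blplr
        biliary = cl_b * c_lv_out / blplr

        dy[LG] = co * (c_ven - c_lg_out)
        dy[ART] = co * (c_lg_out - c_art)
        dy[VEN] = (q_simple @ c_simple_out) + q_h * c_lv_out - co * c_ven
        dy[i_simple] = q_simple * (c_art - c_simple_out)
        dy[_IDX["kidney"]] -= renal
        dy[GT] = q_gut * (c_art - c_gut_out) + k_a * y[LA] + k_ra * y[RC]
        dy[SP] = q_sp * (c_art - c_sp_out)
        dy[LV] = (q_ha * c_art + q_gut * c_gut_out + q_sp * c_sp_out
                  - q_h * c_lv_out - biliary)
        dy[LA] = -k_a * y[LA]
        dy[LN] = -k_f * y[LN]
        if k_bile is None:  # instantaneous bile transit
            dy[BI] = 0.0
            bile_out = biliary
        else:
            dy[BI] = biliary - k_bile * y[BI]
            bile_out = k_bile * y[BI]
        dy[RC] = bile_out - (k_ra + k_f) * y[RC]
        dy[UR] = renal
        dy[FE] = k_f * (y[LN] + y[RC])
        return dy

    return rhs


@dataclass
class SimulationResult:
    """Densely sampled trajectory of one catechin.

    ``amounts`` is (n_states, n_times) in ug, row order ``STATE_NAMES``.
    Concentrations are ug/mL (== mg/L); plasma is venous blood divided by
    the blood:plasma ratio.
    """

    times: np.ndarray
    amounts: np.ndarray
    model: ModelSpec
    dose_ug: float
    state_names: Sequence[str] = STATE_NAMES
    _volumes: dict = field(default_factory=dict, repr=False)

    def amount(self, name: str) -> np.ndarray:
        return self.amounts[_IDX[name]]

    def _volume(self, name: str) -> float:
        phys = self.model.physiology
        if name == "arterial":
            return phys.volume("blood") / 3.0
        if name == "venous":
            return 2.0 * phys.volume("blood") / 3.0
        return phys.volume(name)

    def concentration(self, name: str) -> np.ndarray:
        """Compartment concentration in ug/mL (amount / litres / 1000)."""
        return self.amount(name) / self._volume(name) / 1000.0

    @property
    def plasma(self) -> np.ndarray:
        """Plasma concentration: venous blood / BLPLR, ug/mL."""
        return self.concentration("venous") / self.model.physchem.BLPLR

    @property
    def urine(self) -> np.ndarray:
        return self.amount("urine")

    @property
    def feces(self) -> np.ndarray:
        return self.amount("feces")

    def to_frame(self):
        """Tidy table: time_h, per-compartment concentrations (ug/mL),
        plasma, and cumulative urine/feces amounts (ug)."""
        import pandas as pd

        data = {"time_h": self.times}
        for name in STATE_NAMES[:14]:
            data[name] = self.concentration(name)
        data["plasma"] = self.plasma
        data["urine_cum"] = self.urine
        data["feces_cum"] = self.feces
        return pd.DataFrame(data)


def simulate(
    model: ModelSpec,
    dose: DoseEvent,
    t_end: float,
    output_step: float = 0.05,
    solver: SolverSettings | None = None,
    output_times: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate a single oral bolus from t = 0 to ``t_end`` hours.

    The dose D = dose * BW * 1000 ug enters the lumen pools at
    t = dose.time + tlag, split F*D absorbable / (1-F)*D non-absorbable;
    every output time before that instant reports zeros. ``output_times``
    (strictly increasing, within [0, t_end]) overrides the regular
    ``output_step`` grid.
    """
    if t_end <= 0:
        raise DomainError("t_end must be positive")
    if output_step <= 0:
        raise DomainError("output_step must be positive")
    if dose.catechin_id != model.catechin_id:
        raise ConsistencyError(
            f"dose is for {dose.catechin_id!r} but model is {model.catechin_id!r}"
        )
    solver = solver or SolverSettings()

    if output_times is not None:
        times = np.asarray(output_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise DomainError("output_times must be non-empty and increasing")
        if times[0] < 0 or times[-1] > t_end + 1e-12:
            raise DomainError("output_times must lie within [0, t_end]")
    else:
        n = int(round(t_end / output_step))
        times = np.linspace(0.0, n * output_step, n + 1)
        if times[-1] < t_end - 1e-12:
            times = np.append(times, t_end)
    amounts = np.zeros((len(STATE_NAMES), times.size))

    D = dose.dose * model.physiology.BW * 1000.0
    t0 = dose.time + model.scaled.tlag
    active = times > t0 + 1e-12
    if D == 0.0 or not active.any():
        return SimulationResult(times, amounts, model, D)

    y0 = np.zeros(len(STATE_NAMES))
    y0[_IDX["lumen_absorbable"]] = model.scaled.F * D
    y0[_IDX["lumen_nonabsorbable"]] = (1.0 - model.scaled.F) * D

    sol = solve_ivp(
        _make_rhs(model),
        (t0, times[-1]),
        y0,
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
        t_eval=times[active],
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE solver failed: {sol.message}",
            diagnostics={"status": sol.status, "nfev": sol.nfev,
                         "last_t": sol.t[-1] if sol.t.size else t0},
        )
    amounts[:, active] = sol.y
    # states at exactly t0 (dose instant): lumen pools already filled
    at_t0 = np.isclose(times, t0, rtol=0.0, atol=1e-12)
    amounts[:, at_t0] = y0[:, None]
    return SimulationResult(times, amounts, model, D)


def plasma_series(result: SimulationResult) -> np.ndarray:
    """Plasma concentration series (ug/mL): venous blood / BLPLR."""
    return result.plasma


def cmax(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Maximum of a sampled series and the earliest time attaining it."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("empty series has no maximum")
    i = int(np.argmax(values))
    return float(values[i]), float(times[i])


def auc(times: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under a sampled series over its observed span."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise DomainError("need at least two points for a trapezoidal area")
    if np.any(np.diff(times) <= 0):
        raise DomainError("times must be strictly increasing")
    return float(np.trapezoid(values, times))


def mass_balance(result: SimulationResult, dose: DoseEvent) -> float:
    """Maximum relative mass-balance residual over the output grid.

    Only times at or after the absorption lag are audited (the dose has not
    entered the system before then); a zero dose audits to zero.
    """
    D = result.dose_ug
    if D == 0:
        return 0.0
    t0 = dose.time + result.model.scaled.tlag
    active = result.times >= t0 - 1e-12
    total = result.amounts[:, active].sum(axis=0)
    return float(np.max(np.abs(total - D)) / D)


__all__ = [
    "STATE_NAMES", "DoseEvent", "SolverSettings", "ModelSpec",
    "SimulationResult", "build_model", "load_model", "simulate",
    "plasma_series", "cmax", "auc", "mass_balance",
]
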