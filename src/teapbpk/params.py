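"""Parameter registry: packaged physicochemical, physiological and
pharmacokinetic tables, plus the allometric scaling equations.

All quantities are normalized on load to a single unit system — hours,
litres, micrograms, kilograms. The rat pharmacokinetic table is printed in
per-minute and millilitre units and is converted on load (x60 for rates and
residence times, x60/1000 for clearances); the stored CSV keeps the printed
numbers so it stays diffable against the publication.

Allometric conventions (BW in kg):

* cardiac output        CO   = co_coefficient * BW^0.75      [L/h]
* first-order rates     k    = k_c  * BW^-0.3                [1/h]
* clearances            CL   = CL_c * BW^0.66                [L/h]

The liver's listed blood-flow fraction is *total* hepatic flow; the
hepatic-artery share is the listed liver fraction minus the gut and spleen
fractions, which is the only reading under which the perfusion fractions
balance to 100 % of cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import DomainError, LookupError_, ParameterNotPublishedError

CATECHINS = ("EGCg", "ECg", "EGC", "EC")
SPECIES = ("rat", "human")

#: perfused compartments in canonical order (liver flow = total hepatic)
PERFUSED = (
    "liver", "gut", "spleen", "kidney", "muscle", "skin",
    "adipose", "bone", "brain", "heart", "rest_of_body",
)
#: compartments with a volume but no individual perfusion entry
UNPERFUSED = ("lung", "blood")

#: default parameter-variant study per catechin and species
DEFAULT_STUDY = {
    ("EGCg", "rat"): "zhu2000",
    ("ECg", "rat"): "zhu2000",
    ("EC", "rat"): "zhu2000",
    ("EGCg", "human"): "chow2001",
    ("EGC", "human"): "chow2003",
    ("EC", "human"): "chow2003",
}

#: printed range of the rat EGCg bioavailability factor across source studies
RAT_EGCG_F_RANGE = (0.0003, 0.038)


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("teapbpk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@dataclass(frozen=True)
class CatechinPhysChem:
    """Per-catechin physicochemical record.

    ``P_ow`` and ``D_vow`` are linear-scale octanol:water and vegetable
    oil:water coefficients; ``f_up``/``f_ut`` are unbound fractions in
    plasma and tissue; ``BLPLR`` is the blood:plasma concentration ratio;
    ``ic50_erod`` is the EROD-inhibition IC50 in umol/L.
    """

    catechin_id: str
    P_ow: float
    pKa: float
    D_vow: float
    f_up: float
    f_ut: float
    BLPLR: float
    ic50_erod: float

    def __post_init__(self):
        for name in ("P_ow", "pKa", "D_vow", "f_up", "f_ut", "BLPLR", "ic50_erod"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if not (0 < self.f_up <= 1 and 0 < self.f_ut <= 1):
            raise DomainError("f_up and f_ut must lie in (0, 1]")


@dataclass(frozen=True)
class TissueComposition:
    """Fractional weights of neutral fat, phospholipids and water."""

    compartment_id: str
    V_n: float
    V_ph: float
    V_w: float

    def __post_init__(self):
        for name in ("V_n", "V_ph", "V_w"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.V_n + self.V_ph + self.V_w > 1 + 1e-12:
            raise DomainError("composition fractions exceed unity")


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Body weight, cardiac output and per-compartment volumes/flows.

    ``tissue_volume_fraction`` is % of body weight, ``tissue_flow_fraction``
    is % of cardiac output (liver entry = total hepatic flow). Absolute
    volumes assume unit tissue density (1 g/mL), so % BW converts directly
    to litres.
    """

    species_id: str
    BW: float
    co_coefficient: float
    tissue_volume_fraction: dict[str, float]
    tissue_flow_fraction: dict[str, float]
    gut_lumen_volume: float
    hematocrit: float = 0.37

    @property
    def cardiac_output(self) -> float:
        return cardiac_output(self.co_coefficient, self.BW)

    def volume(self, compartment: str) -> float:
        """Absolute compartment volume in litres."""
        try:
            return self.tissue_volume_fraction[compartment] / 100.0 * self.BW
        except KeyError:
            raise LookupError_(
                f"unknown compartment {compartment!r}; known: "
                f"{sorted(self.tissue_volume_fraction)}"
            ) from None

    def flow(self, compartment: str) -> float:
        """Absolute compartment blood flow in L/h."""
        try:
            frac = self.tissue_flow_fraction[compartment]
        except KeyError:
            raise LookupError_(
                f"compartment {compartment!r} has no perfusion entry; "
                f"known: {sorted(self.tissue_flow_fraction)}"
            ) from None
        return frac / 100.0 * self.cardiac_output

    @property
    def hepatic_artery_flow(self) -> float:
        """Hepatic-artery flow = total hepatic minus portal (gut + spleen)."""
        return self.flow("liver") - self.flow("gut") - self.flow("spleen")


@dataclass(frozen=True)
class CatechinPKParams:
    """Absorption/recirculation/clearance coefficients for one catechin,
    species and source study, in hour/litre units.

    Rate coefficients (``k_ac``, ``k_rac``, ``k_fc``) carry units
    1/h * kg^0.3 and scale as ``k_c * BW^-0.3``; clearance coefficients
    (``CL_bc``, ``CL_rc``; L/h * kg^-0.66) scale as ``CL_c * BW^0.66``.
    ``F`` is the empirical bioavailability factor of the oral-absorption
    description, not classical absolute bioavailability.
    """

    catechin_id: str
    species_id: str
    study_id: str
    k_ac: float
    F: float
    tlag: float
    R_t: float
    k_rac: float
    k_fc: float
    CL_bc: float
    CL_rc: float

    def __post_init__(self):
        for name in ("k_ac", "F", "tlag", "R_t", "k_rac", "k_fc", "CL_bc", "CL_rc"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.F > 1:
            raise DomainError("bioavailability factor F cannot exceed 1")

    def scaled(self, BW: float) -> "ScaledPKParams":
        """Body-weight specific rates (1/h) and clearances (L/h)."""
        return ScaledPKParams(
            catechin_id=self.catechin_id,
            species_id=self.species_id,
            study_id=self.study_id,
            k_a=scale_rate_constant(self.k_ac, BW),
            k_ra=scale_rate_constant(self.k_rac, BW),
            k_f=scale_rate_constant(self.k_fc, BW),
            CL_b=scale_clearance(self.CL_bc, BW),
            CL_r=scale_clearance(self.CL_rc, BW),
            F=self.F,
            tlag=self.tlag,
            R_t=self.R_t,
        )


@dataclass(frozen=True)
class ScaledPKParams:
    """BW-specific pharmacokinetic parameters (1/h, L/h, h)."""

    catechin_id: str
    species_id: str
    study_id: str
    k_a: float
    k_ra: float
    k_f: float
    CL_b: float
    CL_r: float
    F: float
    tlag: float
    R_t: float


# ---------------------------------------------------------------------------
# allometric scaling


def cardiac_output(co_coefficient: float, BW: float) -> float:
    """Cardiac output CO = co_coefficient * BW^0.75, in L/h."""
    if co_coefficient <= 0 or BW <= 0:
        raise DomainError("cardiac output arguments must be positive")
    return co_coefficient * BW**0.75


def scale_rate_constant(k_c: float, BW: float) -> float:
    """First-order rate k = k_c * BW^-0.3, in 1/h."""
    if k_c < 0:
        raise DomainError("rate coefficient must be non-negative")
    if BW <= 0:
        raise DomainError("body weight must be positive")
    return k_c * BW**-0.3


def scale_clearance(CL_c: float, BW: float) -> float:
    """Clearance CL = CL_c * BW^0.66 (units follow the coefficient)."""
    if CL_c < 0:
        raise DomainError("clearance coefficient must be non-negative")
    if BW <= 0:
        raise DomainError("body weight must be positive")
    return CL_c * BW**0.66


# ---------------------------------------------------------------------------
# loaders


def load_catechin_physchem(catechin_id: str) -> CatechinPhysChem:
    """Packaged physicochemical record for one of the four catechins."""
    df = _read_table("catechin_physchem.csv")
    row = df[df.catechin_id == catechin_id]
    if row.empty:
        raise LookupError_(
            f"unknown catechin {catechin_id!r}; valid ids: {list(df.catechin_id)}"
        )
    r = row.iloc[0]
    return CatechinPhysChem(
        catechin_id=catechin_id, P_ow=r.P_ow, pKa=r.pKa, D_vow=r.D_vow,
        f_up=r.f_up, f_ut=r.f_ut, BLPLR=r.BLPLR, ic50_erod=r.ic50_erod,
    )


def load_species_physiology(species_id: str, BW: float) -> SpeciesPhysiology:
    """Packaged physiology with absolute volumes/flows for the given BW."""
    if BW <= 0:
        raise DomainError("body weight must be positive")
    meta = _read_table("species.csv")
    mrow = meta[meta.species_id == species_id]
    if mrow.empty:
        raise LookupError_(
            f"unknown species {species_id!r}; valid ids: {list(meta.species_id)}"
        )
    m = mrow.iloc[0]
    df = _read_table(f"physiology_{species_id}.csv")
    volumes = dict(zip(df.compartment, df.volume_pct_bw))
    flows = {
        c: f for c, f in zip(df.compartment, df.flow_pct_co) if pd.notna(f)
    }
    return SpeciesPhysiology(
        species_id=species_id,
        BW=float(BW),
        co_coefficient=float(m.co_coefficient),
        tissue_volume_fraction=volumes,
        tissue_flow_fraction=flows,
        gut_lumen_volume=float(m.gut_lumen_volume_l),
        hematocrit=float(m.hematocrit),
    )


_RAT_RATE_COLS = ("k_ac", "k_rac", "k_fc")  # printed 1/min -> 1/h


def load_pk_params(
    catechin_id: str,
    species_id: str,
    study_id: str | None = None,
    overrides: dict[str, float] | None = None,
) -> CatechinPKParams:
    """Pharmacokinetic parameters, normalized to hours and litres.

    EGC in rats and ECg in humans were never parameterized; requesting them
    raises :class:`ParameterNotPublishedError` unless ``overrides`` supplies
    a complete parameter set. ``overrides`` may also replace individual
    fields of a published set (values in hour/litre units).
    """
    if catechin_id not in CATECHINS:
        raise LookupError_(
            f"unknown catechin {catechin_id!r}; valid ids: {list(CATECHINS)}"
        )
    if species_id not in SPECIES:
        raise LookupError_(
            f"unknown species {species_id!r}; valid ids: {list(SPECIES)}"
        )
    df = _read_table(f"pk_{species_id}.csv")
    sub = df[df.catechin_id == catechin_id]
    if sub.empty:
        if overrides and _FIELDS <= set(overrides):
            return CatechinPKParams(
                catechin_id=catechin_id, species_id=species_id,
                study_id=study_id or "user", **{f: overrides[f] for f in _FIELDS},
            )
        raise ParameterNotPublishedError(
            f"pharmacokinetic parameters for {catechin_id} in {species_id} "
            "were never published; supply a full overrides dict to proceed"
        )
    study = study_id or DEFAULT_STUDY[(catechin_id, species_id)]
    row = sub[sub.study_id == study]
    if row.empty:
        raise LookupError_(
            f"no study {study!r} for {catechin_id}/{species_id}; "
            f"available: {list(sub.study_id)}"
        )
    r = row.iloc[0]
    vals = {f: float(r[f]) for f in _FIELDS}
    if species_id == "rat":  # printed per-minute / mL -> per-hour / L
        for f in _RAT_RATE_COLS:
            vals[f] *= 60.0
        vals["tlag"] /= 60.0
        vals["R_t"] /= 60.0
        vals["CL_bc"] *= 60.0 / 1000.0
        vals["CL_rc"] *= 60.0 / 1000.0
    if overrides:
        unknown = set(overrides) - _FIELDS
        if unknown:
            raise LookupError_(f"unknown override fields {sorted(unknown)}")
        vals.update(overrides)
    return CatechinPKParams(
        catechin_id=catechin_id, species_id=species_id, study_id=study, **vals
    )


_FIELDS = {"k_ac", "F", "tlag", "R_t", "k_rac", "k_fc", "CL_bc", "CL_rc"}


def load_tissue_compositions() -> dict[str, TissueComposition]:
    """Literature-sourced tissue compositions, keyed by compartment
    (including the ``plasma`` reference phase)."""
    df = _read_table("tissue_composition.csv")
    return {
        r.compartment: TissueComposition(r.compartment, r.V_n, r.V_ph, r.V_w)
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Outcome of the physiology balance audit; failures are carried, not
    raised."""

    species_id: str
    volume_sum_pct_bw: float
    volume_check: bool
    perfusion_balance_pct_co: float
    perfusion_check: bool
    positivity_check: bool
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.volume_check and self.perfusion_check and self.positivity_check


def validate_physiology(phys: SpeciesPhysiology) -> ValidationReport:
    """Audit the volume-sum and perfusion-balance conventions.

    Volume fractions (blood included) must total 100 % BW within 0.5;
    flow fractions minus the portal contributions (gut, spleen — already
    inside the liver's total-hepatic entry) must total 100 % CO within 0.1.
    """
    messages: list[str] = []
    vol_sum = sum(phys.tissue_volume_fraction.values())
    vol_ok = abs(vol_sum - 100.0) <= 0.5
    if not vol_ok:
        messages.append(f"tissue volumes sum to {vol_sum:.2f} % BW, not 100")
    flow_sum = sum(phys.tissue_flow_fraction.values())
    balance = flow_sum - phys.tissue_flow_fraction.get("gut", 0.0) \
        - phys.tissue_flow_fraction.get("spleen", 0.0)
    flow_ok = abs(balance - 100.0) <= 0.1
    if not flow_ok:
        messages.append(
            f"perfusion balance is {balance:.2f} % CO (flows minus portal), not 100"
        )
    pos_ok = (
        phys.BW > 0
        and phys.gut_lumen_volume > 0
        and 0 < phys.hematocrit < 1
        and all(v >= 0 for v in phys.tissue_volume_fraction.values())
        and all(f >= 0 for f in phys.tissue_flow_fraction.values())
        and phys.hepatic_artery_flow >= 0
    )
    if not pos_ok:
        messages.append("negative or degenerate physiological quantity")
    return ValidationReport(
        species_id=phys.species_id,
        volume_sum_pct_bw=vol_sum,
        volume_check=vol_ok,
        perfusion_balance_pct_co=balance,
        perfusion_check=flow_ok,
        positivity_check=pos_ok,
        messages=messages,
    )


__all__ = [
    "CATECHINS", "SPECIES", "PERFUSED", "UNPERFUSED", "DEFAULT_STUDY",
    "RAT_EGCG_F_RANGE", "CatechinPhysChem", "TissueComposition",
    "SpeciesPhysiology", "CatechinPKParams", "ScaledPKParams",
    "cardiac_output", "scale_rate_constant", "scale_clearance",
    "load_catechin_physchem", "load_species_physiology", "load_pk_params",
    "load_tissue_compositions", "validate_physiology", "ValidationReport",
]
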