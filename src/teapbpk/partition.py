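"""Tissue-composition partitioning chemistry.

Tissue:blood partition coefficients are predicted from fractional tissue
composition (neutral fat, phospholipids, water) following the
Poulin-Theil approach. Catechins are treated as monoprotic acids (the
relevant pKa values are phenolic), so the ionization correction uses the
acid form of the Henderson-Hasselbalch equation. The oil:water conversion
uses the published regression log D = 1.115 log P_ow - 1.35 applied to the
non-ionized species.

The packaged partition-coefficient tables remain the canonical simulator
input; the equations here are the alternative, composition-driven path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, LookupError_
from .params import (
    CatechinPhysChem,
    TissueComposition,
    _read_table,
    load_tissue_compositions,
)

REST_OF_BODY_PC = 1.00


def nonionized_fraction(pKa: float, pH: float) -> float:
    """Fraction of a monoprotic acid in the non-ionized form at ``pH``:
    1 / (1 + 10^(pH - pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def vegetable_oil_water_D(P_ow: float, pKa: float, pH: float = 7.4) -> float:
    """Vegetable-oil:water distribution coefficient at ``pH``.

    The non-ionized partitioning is converted from octanol:water via
    10^(1.115 log10(P_ow) - 1.35) and weighted by the non-ionized
    fraction. Reproduces the packaged D_vow values within 1 %.
    """
    if P_ow <= 0:
        raise DomainError("P_ow must be positive")
    p_vow = 10.0 ** (1.115 * math.log10(P_ow) - 1.35)
    return p_vow * nonionized_fraction(pKa, pH)


def unbound_tissue_fraction(f_up: float) -> float:
    """Unbound tissue fraction from the unbound plasma fraction:
    f_ut = 1 / [1 + ((1 - f_up)/f_up) * 0.5]."""
    if not 0 < f_up <= 1:
        raise DomainError("f_up must lie in (0, 1]")
    return 1.0 / (1.0 + ((1.0 - f_up) / f_up) * 0.5)


def blood_plasma_ratio(P_e: float, P_p: float, hematocrit: float = 0.37) -> float:
    """Blood:plasma ratio from erythrocyte and plasma partitioning:
    (hct * P_e + (1 - hct) * P_p) / P_p."""
    if P_p <= 0:
        raise DomainError("plasma partitioning P_p must be positive")
    if P_e < 0:
        raise DomainError("erythrocyte partitioning P_e must be non-negative")
    if not 0 < hematocrit < 1:
        raise DomainError("hematocrit must lie in (0, 1)")
    return (hematocrit * P_e + (1.0 - hematocrit) * P_p) / P_p


def _lipid_water_term(lipophilicity: float, comp: TissueComposition) -> float:
    return lipophilicity * (comp.V_n + 0.3 * comp.V_ph) + (comp.V_w + 0.7 * comp.V_ph)


def pc_nonadipose(
    P_ow: float,
    tissue: TissueComposition,
    plasma: TissueComposition,
    f_up: float,
    f_ut: float,
    BLPLR: float,
) -> float:
    """Non-adipose tissue:blood partition coefficient:

    [P_ow (V_nt + 0.3 V_pht) + (V_wt + 0.7 V_pht)] /
    [P_ow (V_np + 0.3 V_php) + (V_wp + 0.7 V_php)] * f_up / (f_ut * BLPLR)
    """
    if BLPLR <= 0:
        raise DomainError("BLPLR must be positive")
    den = _lipid_water_term(P_ow, plasma)
    if den == 0:
        raise DomainError("degenerate plasma composition: zero denominator")
    return _lipid_water_term(P_ow, tissue) / den * (f_up / (f_ut * BLPLR))


def pc_adipose(
    D_vow: float,
    tissue: TissueComposition,
    plasma: TissueComposition,
    f_up: float,
    BLPLR: float,
) -> float:
    """Adipose tissue:blood partition coefficient; as the non-adipose form
    but driven by D_vow (ionized + non-ionized partitioning into oil) and
    without the tissue-binding term."""
    if BLPLR <= 0:
        raise DomainError("BLPLR must be positive")
    den = _lipid_water_term(D_vow, plasma)
    if den == 0:
        raise DomainError("degenerate plasma composition: zero denominator")
    return _lipid_water_term(D_vow, tissue) / den * (f_up / BLPLR)


@dataclass(frozen=True)
class PartitionSet:
    """Per-compartment tissue:blood partition coefficients for one
    catechin; rest_of_body is pinned at 1.00 by convention.

    ``pin_rest=False`` lifts the rest-of-body pin; it exists solely so a
    sensitivity analysis can perturb that coefficient like any other.
    """

    catechin_id: str
    species_id: str
    values: dict[str, float]
    pin_rest: bool = True

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise DomainError("partition coefficients must be positive")
        if self.pin_rest and self.values.get("rest_of_body") != REST_OF_BODY_PC:
            raise DomainError("rest_of_body partition coefficient must be 1.00")

    def __getitem__(self, compartment: str) -> float:
        try:
            return self.values[compartment]
        except KeyError:
            raise LookupError_(
                f"no partition coefficient for {compartment!r}; "
                f"known: {sorted(self.values)}"
            ) from None


def load_partition_set(catechin_id: str, species_id: str) -> PartitionSet:
    """Packaged (canonical) partition coefficients for a catechin/species."""
    df = _read_table(f"partition_{species_id}.csv")
    if catechin_id not in df.columns:
        raise LookupError_(
            f"no packaged partition coefficients for {catechin_id!r} in "
            f"{species_id}; available: {[c for c in df.columns if c != 'compartment']}"
        )
    return PartitionSet(
        catechin_id, species_id, dict(zip(df.compartment, df[catechin_id]))
    )


def predict_partition_set(
    physchem: CatechinPhysChem,
    species_id: str,
    compositions: dict[str, TissueComposition] | None = None,
) -> PartitionSet:
    """Composition-driven alternative to the packaged tables.

    Uses the adipose equation for adipose and the non-adipose equation
    elsewhere; rest_of_body stays at 1.00. Best-effort: the exact
    compositions behind the packaged tables are not published, so per-
    compartment deviations of tens of percent are expected.
    """
    comps = compositions or load_tissue_compositions()
    plasma = comps["plasma"]
    values: dict[str, float] = {}
    for name, comp in comps.items():
        if name == "plasma":
            continue
        if name == "rest_of_body":
            values[name] = REST_OF_BODY_PC
        elif name == "adipose":
            values[name] = pc_adipose(
                physchem.D_vow, comp, plasma, physchem.f_up, physchem.BLPLR
            )
        else:
            values[name] = pc_nonadipose(
                physchem.P_ow, comp, plasma,
                physchem.f_up, physchem.f_ut, physchem.BLPLR,
            )
    return PartitionSet(physchem.catechin_id, species_id, values)


__all__ = [
    "REST_OF_BODY_PC", "PartitionSet", "nonionized_fraction",
    "vegetable_oil_water_D", "unbound_tissue_fraction", "blood_plasma_ratio",
    "pc_nonadipose", "pc_adipose", "load_partition_set", "predict_partition_set",
]
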