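"""Tissue-to-plasma partitioning (Poulin-Theil) and steady-state volume.

Kp for each perfusion-limited tissue is predicted from tissue composition
(water / neutral lipid / phospholipid fractional volumes) and the compound's
octanol-water partition coefficient, then multiplied by a uniform empirical
Kp scalar.  Adipose uses the vegetable-oil surrogate partition coefficient
and no tissue-binding correction; all other tissues use the standard
dilution relation for the unbound fraction in tissue homogenate,

    fu_t = 1 / (1 + 0.5 * (1 - fu_p) / fu_p).

Vss sums plasma, erythrocyte (from B/P and hematocrit) and Kp-weighted
tissue volumes, normalised by body weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

from .compound import CompoundParameters
from .config import load_yaml
from .errors import ConfigurationError, InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .population import IndividualPhysiology

__all__ = ["TissueComposition", "load_tissue_compositions", "kp_poulin_theil", "build_kp_map", "vss_from_kp"]

#: Fractional dilution of interstitial/cell binding proteins relative to
#: plasma assumed by the tissue-composition method.
TISSUE_BINDING_DILUTION = 0.5


@dataclass(frozen=True)
class TissueComposition:
    """Fractional volumes of water, neutral lipid and phospholipid."""

    tissue_id: str
    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float

    def __post_init__(self):
        for f in (self.f_water, self.f_neutral_lipid, self.f_phospholipid):
            if f < 0:
                raise InvalidInputError(f"{self.tissue_id}: negative composition fraction")
        if self.f_water + self.f_neutral_lipid + self.f_phospholipid > 1.0 + 1e-9:
            raise InvalidInputError(f"{self.tissue_id}: composition fractions exceed 1")


def load_tissue_compositions(source: str | dict = "tissue_composition.yaml") -> dict[str, TissueComposition]:
    doc = load_yaml(source)
    return {
        tid: TissueComposition(tid, float(v["f_water"]), float(v["f_neutral_lipid"]), float(v["f_phospholipid"]))
        for tid, v in doc.items()
    }


def _fu_tissue(fu_plasma: float) -> float:
    return 1.0 / (1.0 + TISSUE_BINDING_DILUTION * (1.0 - fu_plasma) / fu_plasma)


def kp_poulin_theil(
    compound: CompoundParameters,
    tissue: TissueComposition,
    plasma: TissueComposition,
) -> float:
    """Tissue:plasma partition coefficient of one tissue (includes kp_scalar).

    Non-adipose tissues use P = 10^logP with the fu_p/fu_t binding
    correction; adipose uses the vegetable-oil:water surrogate
    log P_vo:w = 1.115 logP - 1.35 and fu_t = 1.
    """
    adipose = tissue.tissue_id == "adipose"
    if adipose:
        p = 10.0 ** (1.115 * compound.log_p - 1.35)
        fu_ratio = compound.fu_plasma
    else:
        p = 10.0 ** compound.log_p
        fu_ratio = compound.fu_plasma / _fu_tissue(compound.fu_plasma)

    def lipid_water(c: TissueComposition) -> float:
        return p * (c.f_neutral_lipid + 0.3 * c.f_phospholipid) + (c.f_water + 0.7 * c.f_phospholipid)

    denom = lipid_water(plasma)
    if denom <= 0:
        raise ConfigurationError("degenerate plasma composition: zero lipid+water volume")
    return compound.kp_scalar * lipid_water(tissue) / denom * fu_ratio


def build_kp_map(
    compound: CompoundParameters,
    compositions: Mapping[str, TissueComposition] | None = None,
) -> dict[str, float]:
    """Kp for every tissue in the composition table (plasma excluded)."""
    comps = dict(compositions) if compositions is not None else load_tissue_compositions()
    try:
        plasma = comps.pop("plasma")
    except KeyError:
        raise ConfigurationError("composition table lacks a 'plasma' entry") from None
    return {tid: kp_poulin_theil(compound, c, plasma) for tid, c in comps.items()}


def vss_from_kp(
    kp_map: Mapping[str, float],
    physiology: "IndividualPhysiology",
    compound: CompoundParameters,
) -> float:
    """Steady-state volume of distribution in L/kg.

    Vss = [V_plasma + sum_t Kp_t V_t + Kp_rbc V_rbc] / body weight, with the
    erythrocyte partition coefficient derived from B/P and hematocrit.
    """
    hct = physiology.hematocrit
    v_blood = physiology.organ_volumes["blood"]
    v_plasma = v_blood * (1.0 - hct)
    v_rbc = v_blood * hct
    kp_rbc = max((compound.blood_to_plasma - (1.0 - hct)) / hct, 0.0)
    total = v_plasma + kp_rbc * v_rbc
    for tid, vol in physiology.organ_volumes.items():
        if tid == "blood":
            continue
        if tid not in kp_map:
            raise ConfigurationError(f"kp_map lacks tissue {tid!r}")
        total += kp_map[tid] * vol
    return total / physiology.body_weight
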