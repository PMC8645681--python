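"""Saturable metabolic clearance, renal filtration and DDI mechanisms.

Whole-organ Vmax is scaled from microsomal kinetics via MPPGL and liver
weight.  Three interaction mechanisms act on the victim's clearance:

* competitive inhibition -- the unbound perpetrator concentration raises the
  apparent Km by (1 + Iu/Ki) instantaneously;
* mechanism-based inactivation -- first-order enzyme loss at
  kinact * Iu / (KI + Iu) acting on a turnover state;
* induction -- enzyme synthesis multiplied by 1 + IndMax * Iu / (IndC50 + Iu).

The perpetrator itself is a one-compartment oral forcing function
(superposition over its dosing calendar), not a state of the victim ODE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .compound import EnzymeKinetics
from .config import load_yaml, perpetrator_path
from .errors import ConfigurationError, InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .population import IndividualPhysiology

__all__ = [
    "InteractionTerms",
    "PerpetratorModel",
    "EnzymeState",
    "scale_vmax_to_organ",
    "metabolic_rate",
    "enzyme_turnover_rhs",
    "renal_clearance",
    "perpetrator_concentration",
]

#: Default first-order degradation constants of the enzyme pools, 1/h.
KDEG_LIVER_DEFAULT = {"CYP3A4": 0.0193, "CYP3A5": 0.0193, "CYP2D6": 0.0136}
KDEG_GUT_CYP3A4 = 0.029


@dataclass(frozen=True)
class InteractionTerms:
    """Interaction constants of one perpetrator on one enzyme.

    All concentrations are unbound and in uM.  Absent mechanisms are None.
    """

    ki: float | None = None          # competitive inhibition constant
    kinact: float | None = None      # maximal inactivation rate, 1/h
    ki_app: float | None = None      # inactivator concentration at half kinact
    ind_max: float | None = None     # maximal fold-increase in synthesis
    ind_c50: float | None = None     # inducer concentration at half IndMax

    def __post_init__(self):
        if (self.kinact is None) != (self.ki_app is None):
            raise ConfigurationError("kinact and ki_app must be given together")
        if (self.ind_max is None) != (self.ind_c50 is None):
            raise ConfigurationError("ind_max and ind_c50 must be given together")
        for v in (self.ki, self.kinact, self.ki_app, self.ind_max, self.ind_c50):
            if v is not None and v <= 0:
                raise ConfigurationError("interaction constants must be positive")

    @property
    def any_mechanism(self) -> bool:
        return any(v is not None for v in (self.ki, self.kinact, self.ind_max))


@dataclass(frozen=True)
class PerpetratorModel:
    """One-compartment oral perpetrator with its interaction constants."""

    name: str
    molecular_weight: float
    dose_mg: float
    interval_h: float
    days: int
    ka: float       # 1/h
    v_f: float      # L
    cl_f: float     # L/h
    fu: float
    interactions: Mapping[str, InteractionTerms] = field(default_factory=dict)

    def __post_init__(self):
        for v in (self.molecular_weight, self.dose_mg, self.interval_h, self.ka, self.v_f, self.cl_f):
            if v <= 0:
                raise ConfigurationError(f"{self.name}: perpetrator parameters must be positive")
        if not (0 < self.fu <= 1):
            raise ConfigurationError(f"{self.name}: fu must lie in (0, 1]")
        if self.days < 1:
            raise ConfigurationError(f"{self.name}: dosing must span at least one day")
        if not any(t.any_mechanism for t in self.interactions.values()):
            raise ConfigurationError(f"{self.name}: at least one interaction term required")

    @property
    def dose_times(self) -> np.ndarray:
        """Dose calendar in hours from the first perpetrator dose."""
        return np.arange(0.0, self.days * 24.0, self.interval_h)

    @property
    def kel(self) -> float:
        return self.cl_f / self.v_f

    def terms(self, enzyme_id: str) -> InteractionTerms:
        return self.interactions.get(enzyme_id, InteractionTerms())

    @classmethod
    def load(cls, source: str | dict, days: int | None = None) -> "PerpetratorModel":
        """Load a packaged perpetrator fixture by name, path or dict."""
        if isinstance(source, str) and not source.endswith((".yaml", ".yml")):
            doc = load_yaml(perpetrator_path(source))
        else:
            doc = load_yaml(source)
        inter = {}
        for eid, blocks in doc.get("interactions", {}).items():
            kw: dict = {}
            if "competitive" in blocks:
                kw["ki"] = float(blocks["competitive"]["ki"])
            if "mbi" in blocks:
                kw["kinact"] = float(blocks["mbi"]["kinact"])
                kw["ki_app"] = float(blocks["mbi"]["ki_app"])
            if "induction" in blocks:
                kw["ind_max"] = float(blocks["induction"]["ind_max"])
                kw["ind_c50"] = float(blocks["induction"]["ind_c50"])
            inter[eid] = InteractionTerms(**kw)
        dosing = doc["dosing"]
        return cls(
            name=doc["name"],
            molecular_weight=float(doc["molecular_weight"]),
            dose_mg=float(dosing["dose_mg"]),
            interval_h=float(dosing["interval_h"]),
            days=int(days if days is not None else dosing["days"]),
            ka=float(doc["pk"]["ka"]),
            v_f=float(doc["pk"]["v_f"]),
            cl_f=float(doc["pk"]["cl_f"]),
            fu=float(doc["pk"]["fu"]),
            interactions=inter,
        )


@dataclass
class EnzymeState:
    """Relative active enzyme amounts (1 = healthy baseline) per tissue."""

    liver: dict[str, float] = field(default_factory=lambda: dict.fromkeys(KDEG_LIVER_DEFAULT, 1.0))
    gut_cyp3a4: float = 1.0


def scale_vmax_to_organ(
    kinetics: EnzymeKinetics,
    physiology: "IndividualPhysiology",
    molecular_weight: float,
) -> float:
    """Whole-liver Vmax in mg/h.

    Vmax[pmol/min/mg] * MPPGL[mg/g] * liver weight[g] * abundance scalar
    * 60 min/h * MW[g/mol] * 1e-12 g/pmol * 1e3 mg/g.
    """
    scalar = physiology.enzyme_abundance_scalar.get(kinetics.enzyme_id, 1.0)
    return (
        kinetics.vmax
        * physiology.mppgl
        * physiology.liver_weight
        * scalar
        * 60.0
        * molecular_weight
        * 1e-9
    )


def metabolic_rate(
    unbound_liver_concentration: float,
    enzymes: list[EnzymeKinetics],
    organ_vmax: Mapping[str, float],
    enzyme_state: Mapping[str, float] | None = None,
    inhibitor_unbound: Mapping[str, float] | None = None,
    ki: Mapping[str, float] | None = None,
) -> float:
    """Total hepatic metabolic rate in mg/h at unbound concentration Cu (uM).

    rate = sum_e E_e * Vmax_organ,e * Cu / (Km_e (1 + Iu_e/Ki_e) + Cu).
    """
    cu = unbound_liver_concentration
    if cu < 0:
        raise InvalidInputError("concentration cannot be negative")
    total = 0.0
    for kin in enzymes:
        e = 1.0 if enzyme_state is None else enzyme_state.get(kin.enzyme_id, 1.0)
        km_app = kin.km
        if inhibitor_unbound and ki and kin.enzyme_id in ki:
            km_app *= 1.0 + inhibitor_unbound.get(kin.enzyme_id, 0.0) / ki[kin.enzyme_id]
        total += e * organ_vmax[kin.enzyme_id] * cu / (km_app + cu)
    return total


def enzyme_turnover_rhs(enzyme_amount: float, k_deg: float, iu: float, terms: InteractionTerms) -> float:
    """dE/dt of one enzyme pool under induction and/or inactivation.

    dE/dt = k_deg [1 + IndMax Iu/(IndC50+Iu)] - k_deg E - kinact Iu/(KI+Iu) E.
    E = 1 is a fixed point when Iu = 0.
    """
    if enzyme_amount < 0:
        raise InvalidInputError("enzyme amount cannot be negative")
    synth = k_deg
    if terms.ind_max is not None:
        synth *= 1.0 + terms.ind_max * iu / (terms.ind_c50 + iu)
    loss = k_deg
    if terms.kinact is not None:
        loss += terms.kinact * iu / (terms.ki_app + iu)
    return synth - loss * enzyme_amount


def renal_clearance(fu: float, gfr: float) -> float:
    """Filtration-only renal clearance in L/h from fu and GFR (mL/min)."""
    if fu < 0 or gfr < 0:
        raise InvalidInputError("fu and gfr cannot be negative")
    return fu * gfr * 0.06


def perpetrator_concentration(perp: PerpetratorModel, t: float | np.ndarray) -> float | np.ndarray:
    """Unbound perpetrator plasma concentration in uM at time(s) t (h).

    Superposition of one-compartment first-order-absorption doses over the
    calendar; zero before the first dose.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    ka, kel = perp.ka, perp.kel
    if abs(ka - kel) < 1e-9:
        ka = kel * (1.0 + 1e-6)
    dt = t_arr[:, None] - perp.dose_times[None, :]
    active = dt > 0
    dt = np.where(active, dt, 0.0)
    prof = np.where(active, np.exp(-kel * dt) - np.exp(-ka * dt), 0.0).sum(axis=1)
    coef = (perp.dose_mg / perp.v_f) * ka / (ka - kel)
    c_total = coef * prof  # mg/L
    cu = perp.fu * c_total / perp.molecular_weight * 1e3  # uM
    return cu if np.ndim(t) else float(cu[0])
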