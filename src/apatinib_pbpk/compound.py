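"""Victim-drug parameters and the permeability / ionisation primitives.

Apatinib is a poorly soluble, dibasic, lipophilic tyrosine-kinase inhibitor
cleared almost entirely by CYP3A4/5 and CYP2D6.  This module houses its
physicochemical and ADME inputs together with the three small computations
that feed absorption and distribution:

* Caco-2 apparent permeability (Papp) from a transport experiment,
* the single-point Caco-2 -> human jejunal Peff calibration, and
* the Henderson-Hasselbalch neutral fraction of a diprotic base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .config import load_yaml
from .errors import InvalidInputError

__all__ = [
    "CompoundParameters",
    "EnzymeKinetics",
    "PEFF_CALIBRATION_DEFAULT",
    "calc_papp",
    "peff_from_papp",
    "neutral_fraction",
]

COMPOUND_CLASSES = {"monoprotic_base", "diprotic_base", "acid", "neutral"}

#: Single-point linear anchor mapping the measured Caco-2 Papp (6.81e-6 cm/s)
#: onto the reported effective jejunal permeability (0.80e-4 cm/s).
PEFF_CALIBRATION_DEFAULT = 0.80e-4 / 6.81e-6


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten kinetics of one metabolic pathway in human liver
    microsomes: ``vmax`` in pmol/min/mg microsomal protein, ``km`` in uM."""

    enzyme_id: str
    vmax: float
    km: float

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise InvalidInputError(
                f"{self.enzyme_id}: vmax and km must be positive "
                f"(got vmax={self.vmax}, km={self.km})"
            )


@dataclass(frozen=True)
class CompoundParameters:
    """All victim-drug inputs of the model.

    Units: molecular_weight g/mol, papp_caco2 cm/s, peff_human 1e-4 cm/s,
    vss_predicted L/kg, intrinsic_solubility and solubility_cap mg/mL,
    dissolution_coefficient 1/h.  ``salt_factor`` converts labelled dose mass
    to free-base mass (1.0 = dose interpreted as free base).
    """

    name: str
    molecular_weight: float
    log_p: float
    compound_class: str
    pka1: float
    pka2: float
    fu_plasma: float
    blood_to_plasma: float
    papp_caco2: float
    peff_human: float
    kp_scalar: float
    vss_predicted: float
    intrinsic_solubility: float
    solubility_cap: float
    dissolution_coefficient: float
    salt_factor: float = 1.0
    enzymes: tuple[EnzymeKinetics, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise InvalidInputError("molecular_weight must be positive")
        if not (0 < self.fu_plasma <= 1):
            raise InvalidInputError("fu_plasma must lie in (0, 1]")
        if self.blood_to_plasma <= 0:
            raise InvalidInputError("blood_to_plasma must be positive")
        if self.compound_class not in COMPOUND_CLASSES:
            raise InvalidInputError(
                f"unknown compound_class {self.compound_class!r}; "
                f"expected one of {sorted(COMPOUND_CLASSES)}"
            )
        if self.compound_class == "diprotic_base" and self.pka1 < self.pka2:
            raise InvalidInputError("pka1 must be >= pka2 for a diprotic base")
        if not (0 < self.kp_scalar <= 1):
            raise InvalidInputError("kp_scalar must lie in (0, 1]")
        if self.intrinsic_solubility <= 0 or self.solubility_cap <= 0:
            raise InvalidInputError("solubilities must be positive")
        if self.salt_factor <= 0:
            raise InvalidInputError("salt_factor must be positive")

    @classmethod
    def from_dict(cls, doc: dict) -> "CompoundParameters":
        doc = dict(doc)
        enz = tuple(
            EnzymeKinetics(enzyme_id=eid, vmax=float(v["vmax"]), km=float(v["km"]))
            for eid, v in doc.pop("enzymes", {}).items()
        )
        return cls(enzymes=enz, **{k: (v if k in ("name", "compound_class") else float(v)) for k, v in doc.items()})

    @classmethod
    def load(cls, source: str | dict = "apatinib.yaml") -> "CompoundParameters":
        """Load compound parameters from a packaged or user YAML file."""
        return cls.from_dict(load_yaml(source))

    def with_overrides(self, **kw) -> "CompoundParameters":
        return replace(self, **kw)

    def enzyme(self, enzyme_id: str) -> EnzymeKinetics:
        for e in self.enzymes:
            if e.enzyme_id == enzyme_id:
                return e
        raise KeyError(enzyme_id)


def calc_papp(
    cumulative_amount_transported: float,
    elapsed_time: float,
    membrane_area: float,
    initial_donor_concentration: float,
) -> float:
    """Apparent permeability dQ / (dT * A * C0) in cm/s.

    Arguments: dQ in nmol, dT in s, A in cm^2, C0 in nmol/cm^3.
    """
    if elapsed_time <= 0 or membrane_area <= 0 or initial_donor_concentration <= 0:
        raise InvalidInputError("time, area and donor concentration must be positive")
    if cumulative_amount_transported < 0:
        raise InvalidInputError("transported amount cannot be negative")
    return cumulative_amount_transported / (
        elapsed_time * membrane_area * initial_donor_concentration
    )


def peff_from_papp(papp: float, calibration_factor: float = PEFF_CALIBRATION_DEFAULT) -> float:
    """Effective human jejunal permeability in 1e-4 cm/s from Caco-2 Papp (cm/s).

    A single-point linear calibration: the default factor is anchored so the
    measured apatinib pair (6.81e-6 cm/s -> 0.80e-4 cm/s) maps exactly.
    """
    if papp <= 0 or calibration_factor <= 0:
        raise InvalidInputError("papp and calibration_factor must be positive")
    return papp * calibration_factor / 1e-4


def neutral_fraction(ph: float, pka1: float, pka2: float) -> float:
    """Un-ionised fraction of a diprotic base at the given pH.

    f0 = 1 / (1 + 10^(pKa1-pH) + 10^(pKa1+pKa2-2 pH)); strictly increasing
    in pH, approaching 1 far above pKa1.
    """
    if not (0 < ph < 14):
        raise InvalidInputError("ph must lie in (0, 14)")
    return 1.0 / (1.0 + 10.0 ** (pka1 - ph) + 10.0 ** (pka1 + pka2 - 2.0 * ph))
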