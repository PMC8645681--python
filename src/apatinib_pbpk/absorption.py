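"""Segmented gastrointestinal absorption.

The gut lumen is a chain of nine compartments (stomach, duodenum, two
jejunum, three ileum, caecum, colon).  In every segment the dose exists as
solid and dissolved drug: solid dissolves with a Noyes-Whitney-type rate
(first order in remaining solid, linear in the saturation driving force and
signed, so supersaturated segments re-precipitate onto the transiting
solid), both states transit to the next segment with first-order rate
constants, and dissolved drug is taken up across the wall at
ka = 2 Peff / R.  Unabsorbed drug leaving the colon is tracked as fecal
loss.  Solubility in each segment follows the diprotic-base
Henderson-Hasselbalch relation S(pH) = S0 / f_neutral(pH), capped to
represent the finite solubilisation of the mesylate salt in gastric fluid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compound import CompoundParameters, neutral_fraction
from .config import load_yaml
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "GutParameters",
    "GutState",
    "segment_solubility",
    "dissolution_rate",
    "absorption_rate_constant",
    "gut_rhs",
    "simulate_gut_only",
]


@dataclass(frozen=True)
class GutParameters:
    """Geometry, transit and fluid environment of the nine gut segments."""

    names: tuple[str, ...]
    volumes_ml: np.ndarray   # resident fluid volume per segment, mL
    ph: np.ndarray
    transit_h: np.ndarray    # mean residence time per segment, h
    radius_cm: np.ndarray    # effective lumen radius (stomach entry unused)
    absorption_scale: np.ndarray  # relative mucosal permeability (stomach 0)

    def __post_init__(self):
        n = len(self.names)
        for arr in (self.volumes_ml, self.ph, self.transit_h, self.radius_cm, self.absorption_scale):
            if len(arr) != n:
                raise ConfigurationError("gut parameter arrays must share one length")
        if np.any(self.transit_h <= 0) or np.any(self.volumes_ml <= 0) or np.any(self.radius_cm <= 0):
            raise ConfigurationError("gut volumes, radii and transit times must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.names)

    @property
    def transit_rate(self) -> np.ndarray:
        """First-order transit rate constants, 1/h."""
        return 1.0 / self.transit_h

    @classmethod
    def load(cls, source: str | dict = "gut.yaml") -> "GutParameters":
        doc = load_yaml(source)
        segs = doc["segments"]
        return cls(
            names=tuple(s["name"] for s in segs),
            volumes_ml=np.array([float(s["volume_ml"]) for s in segs]),
            ph=np.array([float(s["ph"]) for s in segs]),
            transit_h=np.array([float(s["transit_h"]) for s in segs]),
            radius_cm=np.array([float(s["radius_cm"]) for s in segs]),
            absorption_scale=np.array([float(s["absorption_scale"]) for s in segs]),
        )


@dataclass
class GutState:
    """Per-segment solid/dissolved amounts (mg) plus loss ledgers (mg)."""

    solid: np.ndarray
    dissolved: np.ndarray
    absorbed: float = 0.0
    fecal: float = 0.0

    def total(self) -> float:
        return float(self.solid.sum() + self.dissolved.sum() + self.absorbed + self.fecal)


def segment_solubility(
    intrinsic_solubility: float,
    ph: float,
    compound: CompoundParameters,
    cap: float | None = None,
) -> float:
    """Total solubility (mg/mL) of the base at a luminal pH.

    S(pH) = S0 / f_neutral(pH), decreasing with pH for a base and bounded
    above by the solubility cap.
    """
    if intrinsic_solubility <= 0:
        raise InvalidInputError("intrinsic solubility must be positive")
    cap = compound.solubility_cap if cap is None else cap
    s = intrinsic_solubility / neutral_fraction(ph, compound.pka1, compound.pka2)
    return min(s, cap)


def dissolution_rate(
    solid_amount: float,
    dissolved_concentration: float,
    solubility_at_ph: float,
    dissolution_coefficient: float,
) -> float:
    """Noyes-Whitney-type dissolution rate, mg/h.

    rate = k_d * solid * (1 - C/S).  The rate is zero with no solid or at
    saturation, and negative (precipitation onto the remaining solid) when
    the segment is supersaturated.
    """
    if solubility_at_ph < 0:
        raise ConfigurationError("solubility cannot be negative")
    if solid_amount <= 0:
        return 0.0
    driving = 1.0 - dissolved_concentration / solubility_at_ph
    return dissolution_coefficient * solid_amount * driving


def absorption_rate_constant(peff: float, segment_radius: float) -> float:
    """First-order uptake constant ka = 2 Peff / R in 1/h.

    ``peff`` in 1e-4 cm/s units, ``segment_radius`` in cm.
    """
    if peff <= 0 or segment_radius <= 0:
        raise InvalidInputError("peff and radius must be positive")
    return 2.0 * peff * 1e-4 / segment_radius * 3600.0


def _segment_arrays(compound: CompoundParameters, gut: GutParameters):
    """Precompute per-segment solubility (mg/mL) and ka (1/h)."""
    sol = np.array(
        [segment_solubility(compound.intrinsic_solubility, ph, compound) for ph in gut.ph]
    )
    ka = np.array(
        [
            scale * absorption_rate_constant(compound.peff_human, r) if scale > 0 else 0.0
            for scale, r in zip(gut.absorption_scale, gut.radius_cm)
        ]
    )
    return sol, ka


def gut_rhs(
    state: GutState,
    t: float,
    compound: CompoundParameters,
    gut: GutParameters,
    solubility: np.ndarray | None = None,
    ka: np.ndarray | None = None,
):
    """Time derivative of the gut state.

    Returns ``(dsolid, ddissolved, absorption_flux, fecal_flux)`` with the
    fluxes in mg/h; ``absorption_flux`` is the total rate of drug crossing
    the gut wall (before any enterocyte first-pass extraction, which is
    applied downstream by the whole-body engine).
    """
    if np.any(state.solid < -1e-6) or np.any(state.dissolved < -1e-6):
        raise InvalidInputError(f"negative gut amounts at t={t}")
    if solubility is None or ka is None:
        solubility, ka = _segment_arrays(compound, gut)
    kt = gut.transit_rate
    solid = np.maximum(state.solid, 0.0)
    dissolved = np.maximum(state.dissolved, 0.0)

    conc = dissolved / gut.volumes_ml  # mg/mL
    diss = compound.dissolution_coefficient * solid * (1.0 - conc / solubility)

    ds = -kt * solid - diss
    dd = -kt * dissolved + diss - ka * dissolved
    # chain transit: segment i feeds i+1; the last segment feeds the feces
    ds[1:] += kt[:-1] * solid[:-1]
    dd[1:] += kt[:-1] * dissolved[:-1]
    fecal_flux = kt[-1] * (solid[-1] + dissolved[-1])
    absorption_flux = float((ka * dissolved).sum())
    return ds, dd, absorption_flux, fecal_flux


def simulate_gut_only(
    compound: CompoundParameters,
    gut: GutParameters | None = None,
    dose_mg: float = 750.0,
    t_end: float = 48.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict:
    """Integrate the gut chain alone (perfect sink beyond the wall).

    Useful for calibrating dissolution against the fraction absorbed and for
    mass-balance tests; returns fraction absorbed, fraction lost to feces
    and the residual luminal fraction.
    """
    from scipy.integrate import solve_ivp

    gut = gut or GutParameters.load()
    sol_arr, ka_arr = _segment_arrays(compound, gut)
    n = gut.n_segments

    def rhs(t, y):
        st = GutState(solid=y[:n], dissolved=y[n : 2 * n])
        ds, dd, j_abs, j_fec = gut_rhs(st, t, compound, gut, sol_arr, ka_arr)
        return np.concatenate([ds, dd, [j_abs, j_fec]])

    y0 = np.zeros(2 * n + 2)
    y0[0] = dose_mg * compound.salt_factor
    res = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol)
    if not res.success:
        raise ConfigurationError(f"gut-only integration failed: {res.message}")
    yf = res.y[:, -1]
    dose = dose_mg * compound.salt_factor
    return {
        "fraction_absorbed": yf[2 * n] / dose,
        "fraction_fecal": yf[2 * n + 1] / dose,
        "fraction_residual": yf[: 2 * n].sum() / dose,
    }
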