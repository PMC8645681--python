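"""Virtual individuals and populations.

This is the pipeline's synthetic-data generator: it emulates between-subject
physiological variability (seeded, mean-preserving log-normal perturbations
with stated CVs) around a packaged healthy Chinese adult mean, and overlays
disease-stage multipliers for Child-Pugh A/B/C hepatic impairment and
moderate/severe renal impairment (reduced liver size, hepatic and intestinal
CYP abundance, serum albumin, hematocrit, portal flow and GFR).

Serum albumin enters only through the unbound plasma fraction: a reduced
albumin scalar a rescales fu upward as fu' = 1 / (1 + a (1 - fu)/fu).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .absorption import GutParameters
from .config import load_yaml
from .errors import ConfigurationError

__all__ = [
    "IndividualPhysiology",
    "PopulationSpec",
    "POPULATION_NAMES",
    "IMPAIRMENT_STAGES",
    "fu_albumin_adjusted",
    "population_spec",
    "sample_individual",
    "build_population",
    "apply_impairment",
]

POPULATION_NAMES = ("healthy_chinese", "hi_cp_a", "hi_cp_b", "hi_cp_c", "ri_moderate", "ri_severe")
IMPAIRMENT_STAGES = POPULATION_NAMES[1:]

#: Density used to derive liver weight (g) from liver volume (L).
LIVER_DENSITY_G_PER_L = 1050.0


@dataclass(frozen=True)
class IndividualPhysiology:
    """Anatomy, flows and enzymology of one virtual subject.

    Volumes in L, flows in L/h, liver weight g, MPPGL mg/g, GFR mL/min.
    ``organ_blood_flows`` carries the arterial supply of each non-lung
    tissue (liver = hepatic artery only); their sum equals cardiac output.
    """

    body_weight: float
    cardiac_output: float
    organ_volumes: dict[str, float]
    organ_blood_flows: dict[str, float]
    liver_weight: float
    mppgl: float
    enzyme_abundance_scalar: dict[str, float]
    hematocrit: float
    albumin_scalar: float
    gfr: float
    gut: GutParameters
    enterocyte_cyp3a4_scalar: float
    qgut: float               # enterocyte-model hybrid flow, L/h
    gut_cyp3a4_clint: float   # baseline enterocyte CYP3A4 CLint, L/h

    def validate(self) -> None:
        if any(v <= 0 for v in self.organ_volumes.values()):
            raise ConfigurationError("all organ volumes must be positive")
        if any(q <= 0 for q in self.organ_blood_flows.values()):
            raise ConfigurationError("all organ flows must be positive")
        total_q = sum(self.organ_blood_flows.values())
        if abs(total_q - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ConfigurationError(
                f"organ flows sum to {total_q:.6g}, cardiac output is {self.cardiac_output:.6g}"
            )
        if not (0.2 < self.hematocrit < 0.6):
            raise ConfigurationError("hematocrit outside (0.2, 0.6)")
        if self.gfr < 0:
            raise ConfigurationError("gfr cannot be negative")

    @classmethod
    def from_dict(cls, doc: dict, gut: GutParameters | None = None) -> "IndividualPhysiology":
        gut = gut or GutParameters.load()
        co = float(doc["cardiac_output"])
        fractions = {k: float(v) for k, v in doc["flow_fractions"].items()}
        flows = {k: f * co for k, f in fractions.items()}
        volumes = {k: float(v) for k, v in doc["organ_volumes"].items()}
        ind = cls(
            body_weight=float(doc["body_weight"]),
            cardiac_output=co,
            organ_volumes=volumes,
            organ_blood_flows=flows,
            liver_weight=volumes["liver"] * LIVER_DENSITY_G_PER_L,
            mppgl=float(doc["mppgl"]),
            enzyme_abundance_scalar={k: float(v) for k, v in doc["enzyme_abundance_scalar"].items()},
            hematocrit=float(doc["hematocrit"]),
            albumin_scalar=float(doc.get("albumin_scalar", 1.0)),
            gfr=float(doc["gfr"]),
            gut=gut,
            enterocyte_cyp3a4_scalar=float(doc.get("enterocyte_cyp3a4_scalar", 1.0)),
            qgut=float(doc["qgut"]),
            gut_cyp3a4_clint=float(doc["gut_cyp3a4_clint"]),
        )
        ind.validate()
        return ind

    @classmethod
    def load_healthy_mean(cls, source: str | dict = "physiology_healthy_chinese.yaml") -> "IndividualPhysiology":
        return cls.from_dict(load_yaml(source))


def fu_albumin_adjusted(fu: float, albumin_scalar: float) -> float:
    """Unbound fraction after rescaling the binding-protein concentration."""
    if albumin_scalar <= 0:
        raise ConfigurationError("albumin scalar must be positive")
    return 1.0 / (1.0 + albumin_scalar * (1.0 - fu) / fu)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    mean_physiology: IndividualPhysiology
    variability_cv: dict[str, float]
    disease_scalars: dict[str, float]
    seed: int

    def __post_init__(self):
        if self.name not in POPULATION_NAMES:
            raise ConfigurationError(f"unknown population {self.name!r}")
        if any(cv < 0 for cv in self.variability_cv.values()):
            raise ConfigurationError("CVs cannot be negative")
        if any(s <= 0 for s in self.disease_scalars.values()):
            raise ConfigurationError("disease scalars must be positive")


def _load_stage_scalars(stage: str, source: str | dict = "impairment.yaml") -> dict[str, float]:
    doc = load_yaml(source)
    if stage not in doc:
        raise ConfigurationError(f"unknown impairment stage {stage!r}")
    return {k: float(v) for k, v in doc[stage].items()}


def population_spec(
    name: str,
    seed: int,
    physiology_source: str | dict = "physiology_healthy_chinese.yaml",
    variability_source: str | dict = "variability.yaml",
    impairment_source: str | dict = "impairment.yaml",
) -> PopulationSpec:
    """Assemble a population specification from the packaged fixtures."""
    if name not in POPULATION_NAMES:
        raise ConfigurationError(f"unknown population {name!r}")
    mean = IndividualPhysiology.load_healthy_mean(physiology_source)
    cvs = {k: float(v) for k, v in load_yaml(variability_source).items()}
    scalars = {} if name == "healthy_chinese" else _load_stage_scalars(name, impairment_source)
    return PopulationSpec(name=name, mean_physiology=mean, variability_cv=cvs, disease_scalars=scalars, seed=seed)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-preserving log-normal draw; degenerate at cv = 0."""
    if cv <= 0:
        return mean
    sigma2 = np.log(1.0 + cv * cv)
    return float(mean * np.exp(rng.normal(-0.5 * sigma2, np.sqrt(sigma2))))


def _apply_scalars(ind: IndividualPhysiology, scalars: Mapping[str, float]) -> IndividualPhysiology:
    volumes = dict(ind.organ_volumes)
    flows = dict(ind.organ_blood_flows)
    enzymes = dict(ind.enzyme_abundance_scalar)
    changes: dict = {}
    for key, s in scalars.items():
        if key.startswith("volume:"):
            volumes[key.split(":", 1)[1]] = volumes[key.split(":", 1)[1]] * s
        elif key.startswith("flow:"):
            flows[key.split(":", 1)[1]] = flows[key.split(":", 1)[1]] * s
        elif key.startswith("enzyme:"):
            eid = key.split(":", 1)[1]
            enzymes[eid] = enzymes.get(eid, 1.0) * s
        elif key == "albumin":
            changes["albumin_scalar"] = ind.albumin_scalar * s
        elif key == "hematocrit":
            changes["hematocrit"] = float(np.clip(ind.hematocrit * s, 0.205, 0.595))
        elif key == "gfr":
            changes["gfr"] = ind.gfr * s
        elif key == "gfr_absolute":
            changes["gfr"] = s
        elif key == "gut_cyp3a4":
            changes["enterocyte_cyp3a4_scalar"] = ind.enterocyte_cyp3a4_scalar * s
        else:
            raise ConfigurationError(f"unknown disease scalar key {key!r}")
    changes["organ_volumes"] = volumes
    changes["organ_blood_flows"] = flows
    changes["enzyme_abundance_scalar"] = enzymes
    changes["liver_weight"] = volumes["liver"] * LIVER_DENSITY_G_PER_L
    return replace(ind, **changes)


def _renormalize_flows(ind: IndividualPhysiology) -> IndividualPhysiology:
    total = sum(ind.organ_blood_flows.values())
    scale = ind.cardiac_output / total
    return replace(ind, organ_blood_flows={k: q * scale for k, q in ind.organ_blood_flows.items()})


def apply_impairment(
    mean_healthy: IndividualPhysiology,
    stage: str,
    impairment_source: str | dict = "impairment.yaml",
) -> IndividualPhysiology:
    """Return the physiology with stage-specific multipliers applied (pure)."""
    if stage not in IMPAIRMENT_STAGES:
        raise ConfigurationError(f"unknown impairment stage {stage!r}")
    out = _renormalize_flows(_apply_scalars(mean_healthy, _load_stage_scalars(stage, impairment_source)))
    out.validate()
    return out


def sample_individual(spec: PopulationSpec, subject_index: int) -> IndividualPhysiology:
    """Draw one virtual subject, deterministic in (seed, subject_index).

    Log-normal perturbation of the population mean by the stated CVs, then
    disease scalars, then flow renormalisation to cardiac output.
    """
    if subject_index < 0:
        raise ConfigurationError("subject_index must be >= 0")
    rng = np.random.default_rng([spec.seed, subject_index])
    m = spec.mean_physiology
    cv = spec.variability_cv

    bw = _lognormal(rng, m.body_weight, cv.get("body_weight", 0.0))
    co = _lognormal(rng, m.cardiac_output, cv.get("cardiac_output", 0.0))
    volumes = {k: _lognormal(rng, v, cv.get("volumes", 0.0)) for k, v in sorted(m.organ_volumes.items())}
    flows = {k: _lognormal(rng, q, cv.get("flows", 0.0)) for k, q in sorted(m.organ_blood_flows.items())}
    mppgl = _lognormal(rng, m.mppgl, cv.get("mppgl", 0.0))
    enzymes = {
        k: _lognormal(rng, v, cv.get("enzyme_abundance", 0.0))
        for k, v in sorted(m.enzyme_abundance_scalar.items())
    }
    gfr = _lognormal(rng, m.gfr, cv.get("gfr", 0.0))
    hct = float(np.clip(_lognormal(rng, m.hematocrit, cv.get("hematocrit", 0.0)), 0.205, 0.595))
    entero = _lognormal(rng, m.enterocyte_cyp3a4_scalar, cv.get("enterocyte_cyp3a4", 0.0))

    ind = replace(
        m,
        body_weight=bw,
        cardiac_output=co,
        organ_volumes=volumes,
        organ_blood_flows=flows,
        liver_weight=volumes["liver"] * LIVER_DENSITY_G_PER_L,
        mppgl=mppgl,
        enzyme_abundance_scalar=enzymes,
        gfr=gfr,
        hematocrit=hct,
        enterocyte_cyp3a4_scalar=entero,
    )
    if spec.disease_scalars:
        ind = _apply_scalars(ind, spec.disease_scalars)
    ind = _renormalize_flows(ind)
    ind.validate()
    return ind


def build_population(
    spec: PopulationSpec, n_trials: int, n_subjects: int
) -> list[list[IndividualPhysiology]]:
    """n_trials x n_subjects virtual subjects, grouped by trial."""
    if n_trials < 1 or n_subjects < 1:
        raise ConfigurationError("n_trials and n_subjects must be >= 1")
    return [
        [sample_individual(spec, trial * n_subjects + j) for j in range(n_subjects)]
        for trial in range(n_trials)
    ]
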