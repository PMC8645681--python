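"""Canonical trial designs and high-level runners.

The designs mirror the clinical and simulated studies the model targets:

* verification — 750 / 250 mg single oral doses in healthy Chinese adults;
  itraconazole 100 mg qd days 1-6 with 250 mg apatinib on day 4; rifampin
  600 mg qd days 1-10 with 750 mg apatinib on day 6;
* DDI application — apatinib 750 mg on day 4 with fluvoxamine, quinidine,
  paroxetine (qd), erythromycin (qid) or verapamil (tid) on days 1-6, and
  750 mg on day 8 with carbamazepine (bid), efavirenz or phenytoin (qd) on
  days 1-10;
* DDZI — 750 mg single dose in Child-Pugh A/B/C and moderate/severe renal
  impairment populations against matched healthy controls.

All runners use a paired two-arm design: the same seeded virtual subjects
are simulated with and without the perpetrator (or with and without the
disease overlay), so within-subject ratios are free of sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compound import CompoundParameters
from .distribution import build_kp_map
from .engine import DoseRegimen, run_trial
from .errors import ConfigurationError
from .metabolism import PerpetratorModel
from .metrics import ExposureSummary, ddi_ratio, summarize_trials
from .population import build_population, population_spec

__all__ = ["DDIDesign", "DDI_DESIGNS", "DDZI_STAGES", "run_base_trial", "run_ddi_trial", "run_ddzi_trial"]


@dataclass(frozen=True)
class DDIDesign:
    perpetrator: str
    victim_dose_mg: float
    victim_day: int      # perpetrator day 1 = trial day 1
    perpetrator_days: int

    @property
    def victim_dose_time_h(self) -> float:
        return (self.victim_day - 1) * 24.0


DDI_DESIGNS: dict[str, DDIDesign] = {
    # verification designs
    "itraconazole": DDIDesign("itraconazole", 250.0, 4, 6),
    "rifampin": DDIDesign("rifampin", 750.0, 6, 10),
    # application designs
    "fluvoxamine": DDIDesign("fluvoxamine", 750.0, 4, 6),
    "quinidine": DDIDesign("quinidine", 750.0, 4, 6),
    "paroxetine": DDIDesign("paroxetine", 750.0, 4, 6),
    "erythromycin": DDIDesign("erythromycin", 750.0, 4, 6),
    "verapamil": DDIDesign("verapamil", 750.0, 4, 6),
    "carbamazepine": DDIDesign("carbamazepine", 750.0, 8, 10),
    "efavirenz": DDIDesign("efavirenz", 750.0, 8, 10),
    "phenytoin": DDIDesign("phenytoin", 750.0, 8, 10),
}

DDZI_STAGES = ("hi_cp_a", "hi_cp_b", "hi_cp_c", "ri_moderate", "ri_severe")


def run_base_trial(
    dose_mg: float,
    seed: int,
    population: str = "healthy_chinese",
    n_trials: int = 10,
    n_subjects: int = 10,
    compound: CompoundParameters | None = None,
    followup_h: float = 96.0,
    grid_dt: float = 0.1,
    arm: str | None = None,
) -> ExposureSummary:
    """Single oral dose at t = 0 in the named population."""
    compound = compound or CompoundParameters.load()
    spec = population_spec(population, seed)
    pop = build_population(spec, n_trials, n_subjects)
    regimen = DoseRegimen(dose_mg=dose_mg)
    results = run_trial(
        pop, compound, regimen, followup_h=followup_h, grid_dt=grid_dt,
        arm_label=arm or f"{population}:{dose_mg:g}mg",
    )
    return summarize_trials(results, arm=arm or f"{population}:{dose_mg:g}mg")


def run_ddi_trial(
    name: str,
    seed: int,
    n_trials: int = 10,
    n_subjects: int = 10,
    compound: CompoundParameters | None = None,
    control: ExposureSummary | None = None,
    followup_h: float = 96.0,
    grid_dt: float = 0.1,
) -> dict:
    """Paired two-arm DDI trial for one named design.

    The control arm (victim alone, dose at t = 0) can be passed in to share
    one baseline across designs with the same victim dose and population.
    Returns the ``ddi_ratio`` dict plus both arm summaries.
    """
    if name not in DDI_DESIGNS:
        raise ConfigurationError(f"unknown DDI design {name!r}")
    design = DDI_DESIGNS[name]
    compound = compound or CompoundParameters.load()
    kp_map = build_kp_map(compound)
    spec = population_spec("healthy_chinese", seed)
    pop = build_population(spec, n_trials, n_subjects)

    perp = PerpetratorModel.load(design.perpetrator, days=design.perpetrator_days)
    victim_perp = DoseRegimen(dose_mg=design.victim_dose_mg, dose_times=(design.victim_dose_time_h,))
    with_arm = run_trial(
        pop, compound, victim_perp, perpetrator=perp, kp_map=kp_map,
        followup_h=followup_h, grid_dt=grid_dt, arm_label=f"{name}:with",
    )
    with_summary = summarize_trials(with_arm, arm=f"{name}:with")

    if control is None:
        victim_alone = DoseRegimen(dose_mg=design.victim_dose_mg)
        ctrl_arm = run_trial(
            pop, compound, victim_alone, kp_map=kp_map,
            followup_h=followup_h, grid_dt=grid_dt, arm_label=f"{name}:control",
        )
        control = summarize_trials(ctrl_arm, arm=f"{name}:control")

    out = ddi_ratio(with_summary, control)
    out["with_perpetrator"] = with_summary
    out["control"] = control
    out["design"] = design
    return out


def run_ddzi_trial(
    stage: str,
    seed: int,
    dose_mg: float = 750.0,
    n_trials: int = 10,
    n_subjects: int = 10,
    compound: CompoundParameters | None = None,
    healthy: ExposureSummary | None = None,
    followup_h: float = 96.0,
    grid_dt: float = 0.1,
) -> dict:
    """Single 750 mg dose in an impaired population vs matched healthy arm."""
    if stage not in DDZI_STAGES:
        raise ConfigurationError(f"unknown impairment stage {stage!r}")
    compound = compound or CompoundParameters.load()
    disease = run_base_trial(
        dose_mg, seed, population=stage, n_trials=n_trials, n_subjects=n_subjects,
        compound=compound, followup_h=followup_h, grid_dt=grid_dt, arm=stage,
    )
    if healthy is None:
        healthy = run_base_trial(
            dose_mg, seed, population="healthy_chinese", n_trials=n_trials,
            n_subjects=n_subjects, compound=compound, followup_h=followup_h,
            grid_dt=grid_dt, arm="healthy_chinese",
        )
    out = ddi_ratio(disease, healthy)
    out["disease"] = disease
    out["healthy"] = healthy
    return out
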