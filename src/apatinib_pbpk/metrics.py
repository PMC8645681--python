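"""Noncompartmental exposure metrics, fold errors and interaction ratios.

Cmax is the maximum of the reported grid, Tmax the earliest time attaining
it, AUC0-t the linear trapezoid over the grid.  The fold error is the
simulated/observed ratio with the conventional [0.5, 2.0] acceptance band;
DDI and DDZI ratios are ratios of arithmetic population means of the paired
arms (per-subject ratios are also reported for dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "FOLD_ERROR_BAND",
    "ExposureSummary",
    "nca",
    "nca_result",
    "summarize_trials",
    "fold_error",
    "in_fold_error_band",
    "ddi_ratio",
    "build_report",
]

FOLD_ERROR_BAND = (0.5, 2.0)


def nca(time: np.ndarray, conc: np.ndarray) -> dict[str, float]:
    """Cmax / Tmax / AUC0-t of one concentration-time profile."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(time) < 2:
        raise InvalidInputError("need at least two time points")
    if np.any(np.diff(time) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    i = int(np.argmax(conc))
    return {
        "cmax": float(conc[i]),
        "tmax": float(time[i]),
        "auc_0_t": float(np.trapezoid(conc, time)),
    }


def nca_result(result: SimulationResult) -> dict[str, float]:
    return nca(result.time_post_dose_h, result.conc_ng_ml)


@dataclass
class ExposureSummary:
    """Per-subject exposure metrics of one arm plus its population summary."""

    arm: str
    per_subject: pd.DataFrame  # columns: trial, subject, cmax, tmax, auc_0_t

    @property
    def mean_cmax(self) -> float:
        return float(self.per_subject["cmax"].mean())

    @property
    def mean_auc(self) -> float:
        return float(self.per_subject["auc_0_t"].mean())

    @property
    def median_tmax(self) -> float:
        return float(self.per_subject["tmax"].median())

    def geo_mean(self, col: str) -> float:
        return float(np.exp(np.log(self.per_subject[col]).mean()))

    def trial_means(self, col: str) -> pd.Series:
        return self.per_subject.groupby("trial")[col].mean()


def summarize_trials(results: Sequence[Sequence[SimulationResult]], arm: str = "") -> ExposureSummary:
    rows = []
    for trial_idx, group in enumerate(results):
        for subj_idx, res in enumerate(group):
            m = nca_result(res)
            rows.append(
                {
                    "trial": res.metadata.get("trial", trial_idx),
                    "subject": res.metadata.get("subject", subj_idx),
                    **m,
                    "mass_balance": res.mass_balance_rel_max,
                }
            )
    return ExposureSummary(arm=arm, per_subject=pd.DataFrame(rows))


def fold_error(simulated: float, observed: float) -> float:
    """Ratio of simulated to observed; [0.5, 2.0] is the acceptance band."""
    if observed == 0:
        raise InvalidInputError("observed value must be non-zero")
    return simulated / observed


def in_fold_error_band(value: float, band: tuple[float, float] = FOLD_ERROR_BAND) -> bool:
    return band[0] <= value <= band[1]


def ddi_ratio(with_perpetrator: ExposureSummary, without: ExposureSummary) -> dict:
    """Cmax and AUC ratios of the paired arms (ratio of arithmetic means).

    Per-subject ratios are returned alongside for dispersion; the subject
    sets of the two arms must match exactly.
    """
    a = with_perpetrator.per_subject.set_index(["trial", "subject"]).sort_index()
    b = without.per_subject.set_index(["trial", "subject"]).sort_index()
    if not a.index.equals(b.index):
        raise InvalidInputError("mismatched subject sets between arms")
    per_subject = pd.DataFrame(
        {
            "cmax_ratio": a["cmax"] / b["cmax"],
            "auc_ratio": a["auc_0_t"] / b["auc_0_t"],
        }
    )
    return {
        "cmax_ratio": float(a["cmax"].mean() / b["cmax"].mean()),
        "auc_ratio": float(a["auc_0_t"].mean() / b["auc_0_t"].mean()),
        "cmax_ratio_mean_of_subjects": float(per_subject["cmax_ratio"].mean()),
        "auc_ratio_mean_of_subjects": float(per_subject["auc_ratio"].mean()),
        "per_subject": per_subject,
    }


def build_report(
    base: dict[str, ExposureSummary],
    observed: pd.DataFrame | None = None,
    ddi: dict[str, dict] | None = None,
    ddzi: dict[str, dict] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble machine-readable tables of exposures, fold errors and ratios.

    ``base`` maps scenario labels to single-arm summaries; ``observed`` is a
    long-form table (scenario, parameter, observed) used for fold errors;
    ``ddi``/``ddzi`` map scenario labels to ``ddi_ratio`` outputs.
    """
    rows = []
    for label, summ in base.items():
        rows.append(
            {
                "scenario": label,
                "cmax_ng_ml": round(summ.mean_cmax, 2),
                "tmax_h": round(summ.median_tmax, 2),
                "auc_ng_ml_h": round(summ.mean_auc, 2),
            }
        )
    exposure = pd.DataFrame(rows)

    tables = {"exposure": exposure}
    if observed is not None:
        fe_rows = []
        obs = observed.set_index(["scenario", "parameter"])["observed"]
        for label, summ in base.items():
            for param, value in (
                ("cmax_ng_ml", summ.mean_cmax),
                ("tmax_h", summ.median_tmax),
                ("auc_ng_ml_h", summ.mean_auc),
            ):
                key = (label, param)
                if key in obs.index:
                    fe = fold_error(value, float(obs.loc[key]))
                    fe_rows.append(
                        {
                            "scenario": label,
                            "parameter": param,
                            "predicted": round(value, 2),
                            "observed": float(obs.loc[key]),
                            "fold_error": round(fe, 2),
                            "within_band": in_fold_error_band(fe),
                        }
                    )
        tables["fold_errors"] = pd.DataFrame(fe_rows)

    for name, block in (("ddi", ddi), ("ddzi", ddzi)):
        if block is None:
            continue
        if any("auc_ratio" not in v for v in block.values()):
            raise ConfigurationError("ratio blocks require a baseline arm")
        tables[name] = pd.DataFrame(
            [
                {
                    "scenario": label,
                    "cmax_ratio": round(v["cmax_ratio"], 2),
                    "auc_ratio": round(v["auc_ratio"], 2),
                }
                for label, v in block.items()
            ]
        )
    return tables
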