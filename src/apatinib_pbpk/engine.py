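"""Whole-body PBPK assembly and integration.

The model couples, for one virtual subject:

* a nine-segment gut lumen (solid + dissolved states, dissolution,
  transit, Peff-driven uptake) feeding the portal vein through an
  enterocyte CYP3A4 first-pass step (hybrid-flow extraction,
  Eg = CLg / (Qgut + CLg));
* twelve perfusion-limited tissues, dC_t/dt = Q_t/V_t (C_art - C_t B:P/Kp_t),
  with lung in series between the venous and arterial pools;
* saturable hepatic elimination by CYP3A4/3A5/2D6 acting on the unbound
  liver concentration Cu = C_liver fu / Kp_liver, and filtration-only renal
  clearance fu x GFR;
* dynamic enzyme turnover states (liver 3A4/3A5/2D6 and gut 3A4) driven by
  an analytic one-compartment perpetrator forcing function implementing
  competitive inhibition, mechanism-based inactivation and induction.

Amount states are in mg; every flux is conservative, so dose in equals the
sum of all amounts plus the metabolic/renal/fecal ledgers at all times
(checked on the reporting grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .absorption import _segment_arrays
from .compound import CompoundParameters
from .distribution import build_kp_map
from .errors import ConfigurationError, IntegrationFailure
from .metabolism import (
    KDEG_GUT_CYP3A4,
    KDEG_LIVER_DEFAULT,
    PerpetratorModel,
    perpetrator_concentration,
    renal_clearance,
    scale_vmax_to_organ,
)
from .population import IndividualPhysiology, fu_albumin_adjusted

__all__ = ["DoseRegimen", "SimulationResult", "PBPKModel", "build_odes", "simulate_individual", "run_trial"]

TISSUE_ORDER = (
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver", "lung", "muscle", "skin", "spleen", "pancreas",
)
PORTAL_TISSUES = ("gut", "spleen", "pancreas")
LIVER_ENZYMES = ("CYP3A4", "CYP3A5", "CYP2D6")


@dataclass(frozen=True)
class DoseRegimen:
    """Victim dosing: dose in mg (as labelled), times in h on the trial clock."""

    dose_mg: float
    route: str = "oral"  # oral | iv_bolus | iv_infusion
    dose_times: tuple[float, ...] = (0.0,)
    infusion_duration_h: float = 0.0

    def __post_init__(self):
        if self.dose_mg < 0:
            raise ConfigurationError("dose must be non-negative")
        if self.route not in ("oral", "iv_bolus", "iv_infusion"):
            raise ConfigurationError(f"unknown route {self.route!r}")
        if list(self.dose_times) != sorted(self.dose_times):
            raise ConfigurationError("dose times must be non-decreasing")
        if self.route == "iv_infusion" and self.infusion_duration_h <= 0:
            raise ConfigurationError("infusion requires a positive duration")


@dataclass
class SimulationResult:
    """One subject's simulated profile plus the amounts ledger."""

    time_h: np.ndarray            # absolute trial clock
    time_post_dose_h: np.ndarray  # relative to the first victim dose
    conc_ng_ml: np.ndarray        # venous plasma concentration
    enzyme_trajectories: dict[str, np.ndarray]
    amounts_final: dict[str, float]
    mass_balance_rel_max: float
    dose_mg: float
    metadata: dict = field(default_factory=dict)


class PBPKModel:
    """Assembled ODE right-hand side for one individual."""

    N_GUT = 9

    def __init__(
        self,
        individual: IndividualPhysiology,
        compound: CompoundParameters,
        kp_map: dict[str, float] | None = None,
        perpetrator: PerpetratorModel | None = None,
        enterocyte_first_pass: bool = True,
        kdeg_liver: dict[str, float] | None = None,
        kdeg_gut: float = KDEG_GUT_CYP3A4,
    ):
        self.individual = individual
        self.compound = compound
        self.perpetrator = perpetrator
        kp_map = kp_map if kp_map is not None else build_kp_map(compound)
        missing = set(TISSUE_ORDER) - set(kp_map)
        if missing:
            raise ConfigurationError(f"kp_map lacks tissues {sorted(missing)}")
        missing_v = set(TISSUE_ORDER) - set(individual.organ_volumes)
        if missing_v:
            raise ConfigurationError(f"physiology lacks tissues {sorted(missing_v)}")

        gut = individual.gut
        if gut.n_segments != self.N_GUT:
            raise ConfigurationError("gut fixture must define nine segments")
        self.gut = gut
        self.sol_mg_ml, self.ka_gut = _segment_arrays(compound, gut)
        self.kt = gut.transit_rate
        self.vol_ml = gut.volumes_ml
        self.kd = compound.dissolution_coefficient

        self.V = np.array([individual.organ_volumes[t] for t in TISSUE_ORDER])
        self.kp = np.array([kp_map[t] for t in TISSUE_ORDER])
        self.bp = compound.blood_to_plasma
        self.co = individual.cardiac_output
        q = dict(individual.organ_blood_flows)
        self.Q = np.array([q.get(t, 0.0) for t in TISSUE_ORDER])
        self.i_liver = TISSUE_ORDER.index("liver")
        self.i_lung = TISSUE_ORDER.index("lung")
        self.i_kidney = TISSUE_ORDER.index("kidney")
        self.i_portal = np.array([TISSUE_ORDER.index(t) for t in PORTAL_TISSUES])
        self.i_systemic = np.array(
            [i for i, t in enumerate(TISSUE_ORDER) if t not in PORTAL_TISSUES + ("liver", "lung")]
        )
        self.q_ha = self.Q[self.i_liver]
        self.q_portal = float(self.Q[self.i_portal].sum())
        self.q_liver_out = self.q_ha + self.q_portal

        v_blood = individual.organ_volumes["blood"]
        self.v_art = v_blood / 3.0
        self.v_ven = 2.0 * v_blood / 3.0

        self.fu_eff = fu_albumin_adjusted(compound.fu_plasma, individual.albumin_scalar)
        self.clr = renal_clearance(self.fu_eff, individual.gfr)
        self.cu_conv = self.fu_eff / self.kp[self.i_liver] * 1e3 / compound.molecular_weight

        self.vmax_org = np.zeros(len(LIVER_ENZYMES))
        self.km = np.ones(len(LIVER_ENZYMES))
        for j, eid in enumerate(LIVER_ENZYMES):
            try:
                kin = compound.enzyme(eid)
            except KeyError:
                continue
            self.vmax_org[j] = scale_vmax_to_organ(kin, individual, compound.molecular_weight)
            self.km[j] = kin.km

        self.first_pass = enterocyte_first_pass
        self.qgut = individual.qgut
        self.clg_base = individual.gut_cyp3a4_clint * individual.enterocyte_cyp3a4_scalar

        kdl = dict(KDEG_LIVER_DEFAULT)
        if kdeg_liver:
            kdl.update(kdeg_liver)
        self.kdeg_liver = np.array([kdl[e] for e in LIVER_ENZYMES])
        self.kdeg_gut = kdeg_gut

        # perpetrator interaction constants as dense arrays (inactive defaults)
        self.ki = np.full(len(LIVER_ENZYMES), np.inf)
        self.kinact = np.zeros(len(LIVER_ENZYMES))
        self.ki_app = np.ones(len(LIVER_ENZYMES))
        self.ind_max = np.zeros(len(LIVER_ENZYMES))
        self.ind_c50 = np.ones(len(LIVER_ENZYMES))
        if perpetrator is not None:
            for j, eid in enumerate(LIVER_ENZYMES):
                terms = perpetrator.terms(eid)
                if terms.ki is not None:
                    self.ki[j] = terms.ki
                if terms.kinact is not None:
                    self.kinact[j] = terms.kinact
                    self.ki_app[j] = terms.ki_app
                if terms.ind_max is not None:
                    self.ind_max[j] = terms.ind_max
                    self.ind_c50[j] = terms.ind_c50
        self.j_3a4 = LIVER_ENZYMES.index("CYP3A4")

        self._infusion_rate = 0.0
        self.n_states = 2 * self.N_GUT + len(TISSUE_ORDER) + 2 + 4 + 4

    # -- state layout ------------------------------------------------------
    # [0:9] gut solid, [9:18] gut dissolved, [18:30] tissue amounts,
    # [30] venous, [31] arterial, [32] hepatic met, [33] gut-wall met,
    # [34] renal excreted, [35] fecal, [36:39] liver enzymes, [39] gut 3A4

    def iu(self, t: float) -> float:
        if self.perpetrator is None:
            return 0.0
        return perpetrator_concentration(self.perpetrator, t)

    def _enzyme_rhs(self, e_liver: np.ndarray, e_gut: float, iu: float):
        synth = self.kdeg_liver * (1.0 + self.ind_max * iu / (self.ind_c50 + iu))
        loss = self.kdeg_liver + self.kinact * iu / (self.ki_app + iu)
        de_liver = synth - loss * e_liver
        j = self.j_3a4
        synth_g = self.kdeg_gut * (1.0 + self.ind_max[j] * iu / (self.ind_c50[j] + iu))
        loss_g = self.kdeg_gut + self.kinact[j] * iu / (self.ki_app[j] + iu)
        de_gut = synth_g - loss_g * e_gut
        return de_liver, de_gut

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.N_GUT
        s = y[:n]
        d = y[n : 2 * n]
        A = y[2 * n : 2 * n + 12]
        a_ven, a_art = y[30], y[31]
        e_liver = y[36:39]
        e_gut = y[39]

        iu = self.iu(t)

        # gut lumen
        s_pos = np.maximum(s, 0.0)
        d_pos = np.maximum(d, 0.0)
        conc = d_pos / self.vol_ml
        diss = self.kd * s_pos * (1.0 - conc / self.sol_mg_ml)
        ds = -self.kt * s - diss
        dd = -self.kt * d + diss - self.ka_gut * d_pos
        ds[1:] += self.kt[:-1] * s[:-1]
        dd[1:] += self.kt[:-1] * d[:-1]
        fecal_flux = self.kt[-1] * (s[-1] + d[-1])
        j_abs = float((self.ka_gut * d_pos).sum())

        # enterocyte first pass
        if self.first_pass and self.clg_base > 0.0:
            clg = self.clg_base * e_gut / (1.0 + iu / self.ki[self.j_3a4])
            eg = clg / (self.qgut + clg)
        else:
            eg = 0.0
        j_portal = j_abs * (1.0 - eg)
        gut_met_flux = j_abs * eg

        # circulation
        C = A / self.V
        Cv = C * self.bp / self.kp
        c_ven = a_ven / self.v_ven
        c_art = a_art / self.v_art

        cu = max(C[self.i_liver], 0.0) * self.cu_conv  # unbound, uM
        km_app = self.km * (1.0 + iu / self.ki)
        met = float((e_liver * self.vmax_org * cu / (km_app + cu)).sum())

        dA = self.Q * (c_art - Cv)
        dA[self.i_liver] = (
            self.q_ha * c_art
            + float((self.Q[self.i_portal] * Cv[self.i_portal]).sum())
            + j_portal
            - self.q_liver_out * Cv[self.i_liver]
            - met
        )
        dA[self.i_lung] = self.co * (c_ven - Cv[self.i_lung])
        renal_flux = self.clr * c_art / self.bp
        dA[self.i_kidney] -= renal_flux

        d_ven = (
            float((self.Q[self.i_systemic] * Cv[self.i_systemic]).sum())
            + self.q_liver_out * Cv[self.i_liver]
            - self.co * c_ven
            + self._infusion_rate
        )
        d_art = self.co * (Cv[self.i_lung] - c_art)

        de_liver, de_gut = self._enzyme_rhs(e_liver, e_gut, iu)

        dy = np.empty(self.n_states)
        dy[:n] = ds
        dy[n : 2 * n] = dd
        dy[2 * n : 2 * n + 12] = dA
        dy[30] = d_ven
        dy[31] = d_art
        dy[32] = met
        dy[33] = gut_met_flux
        dy[34] = renal_flux
        dy[35] = fecal_flux
        dy[36:39] = de_liver
        dy[39] = de_gut
        return dy

    def pretreat_enzymes(self, t0: float, t1: float, rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
        """Integrate only the four enzyme states over a drug-free window."""
        if self.perpetrator is None or t1 <= t0:
            return np.ones(4)

        def rhs(t, e):
            de_l, de_g = self._enzyme_rhs(e[:3], e[3], self.iu(t))
            return np.concatenate([de_l, [de_g]])

        res = solve_ivp(rhs, (t0, t1), np.ones(4), method="LSODA", rtol=rtol, atol=atol)
        if not res.success:
            raise IntegrationFailure(f"enzyme pretreatment failed: {res.message}", t1)
        return res.y[:, -1]


def build_odes(
    individual: IndividualPhysiology,
    compound: CompoundParameters,
    kp_map: dict[str, float] | None = None,
    perpetrator: PerpetratorModel | None = None,
    **kw,
) -> PBPKModel:
    """Assemble the ODE system; the returned model exposes ``rhs(t, y)``."""
    return PBPKModel(individual, compound, kp_map=kp_map, perpetrator=perpetrator, **kw)


def simulate_individual(
    model: PBPKModel,
    regimen: DoseRegimen,
    followup_h: float = 96.0,
    grid_dt: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    metadata: dict | None = None,
) -> SimulationResult:
    """Integrate one subject and report on a fixed post-dose grid.

    Oral doses are applied as instantaneous additions of free-base mass to
    the stomach solid state at each dose time; the first dose time defines
    the reporting origin.  A perpetrator pretreatment window before the
    first victim dose is integrated on the reduced enzyme-only system.
    """
    t_first = regimen.dose_times[0]
    t_end = regimen.dose_times[-1] + followup_h
    grid = t_first + np.arange(0.0, t_end - t_first + grid_dt / 2.0, grid_dt)
    grid[-1] = min(grid[-1], t_end)

    y0 = np.zeros(model.n_states)
    y0[36:40] = model.pretreat_enzymes(0.0, t_first)

    dose_free_base = regimen.dose_mg * model.compound.salt_factor
    inf_rate = dose_free_base / regimen.infusion_duration_h if regimen.route == "iv_infusion" else 0.0

    # span boundaries: every dose time, every infusion end, the horizon
    spans: list[float] = list(regimen.dose_times) + [t_end]
    if regimen.route == "iv_infusion":
        spans += [td + regimen.infusion_duration_h for td in regimen.dose_times]
    spans = sorted({round(t, 9) for t in spans if t_first <= t <= t_end})

    times_out: list[np.ndarray] = []
    ys_out: list[np.ndarray] = []
    y = y0.copy()
    for ta, tb in zip(spans[:-1], spans[1:]):
        for td in regimen.dose_times:
            if abs(td - ta) < 1e-9:
                if regimen.route == "oral":
                    y[0] += dose_free_base
                elif regimen.route == "iv_bolus":
                    y[30] += dose_free_base
        rate = 0.0
        if regimen.route == "iv_infusion":
            mid = 0.5 * (ta + tb)
            rate = inf_rate * sum(
                1 for td in regimen.dose_times if td <= mid < td + regimen.infusion_duration_h
            )
        model._infusion_rate = rate
        te = grid[(grid >= ta - 1e-12) & (grid < tb - 1e-12)]
        te_full = np.append(te, tb)
        res = solve_ivp(model.rhs, (ta, tb), y, method="LSODA", rtol=rtol, atol=atol, t_eval=te_full)
        if not res.success:
            raise IntegrationFailure(
                f"integration failed: {res.message}", res.t[-1] if len(res.t) else ta
            )
        y = res.y[:, -1].copy()
        times_out.append(res.t[: len(te)])
        ys_out.append(res.y[:, : len(te)])
    model._infusion_rate = 0.0
    # horizon endpoint
    times_out.append(np.array([t_end]))
    ys_out.append(y[:, None])

    t_all = np.concatenate(times_out)
    y_all = np.concatenate(ys_out, axis=1)
    dosed_total = dose_free_base * len(regimen.dose_times)
    if regimen.route == "iv_infusion":
        dosed_all = np.array(
            [
                inf_rate
                * sum(np.clip(t - td, 0.0, regimen.infusion_duration_h) for td in regimen.dose_times)
                for t in t_all
            ]
        )
    else:
        dosed_all = dose_free_base * np.array(
            [sum(1 for td in regimen.dose_times if td <= t + 1e-12) for t in t_all]
        )

    c_ven = y_all[30] / model.v_ven
    conc_ng_ml = c_ven / model.bp * 1e3

    total_amounts = y_all[:36].sum(axis=0)
    denom = max(dosed_total, 1e-12)
    residual = float(np.max(np.abs(total_amounts - dosed_all)) / denom) if dosed_total > 0 else 0.0

    enz = {
        "liver_CYP3A4": y_all[36],
        "liver_CYP3A5": y_all[37],
        "liver_CYP2D6": y_all[38],
        "gut_CYP3A4": y_all[39],
    }
    amounts_final = {
        "gut_lumen": float(y_all[:18, -1].sum()),
        "tissues": float(y_all[18:30, -1].sum()),
        "blood": float(y_all[30:32, -1].sum()),
        "hepatic_metabolized": float(y_all[32, -1]),
        "gut_metabolized": float(y_all[33, -1]),
        "renal_excreted": float(y_all[34, -1]),
        "fecal": float(y_all[35, -1]),
    }
    return SimulationResult(
        time_h=t_all,
        time_post_dose_h=t_all - t_first,
        conc_ng_ml=conc_ng_ml,
        enzyme_trajectories=enz,
        amounts_final=amounts_final,
        mass_balance_rel_max=residual,
        dose_mg=regimen.dose_mg,
        metadata=metadata or {},
    )


def run_trial(
    population: Sequence[Sequence[IndividualPhysiology]],
    compound: CompoundParameters,
    regimen: DoseRegimen,
    perpetrator: PerpetratorModel | None = None,
    kp_map: dict[str, float] | None = None,
    followup_h: float = 96.0,
    grid_dt: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    arm_label: str | None = None,
) -> list[list[SimulationResult]]:
    """Simulate every subject of a (trial-grouped) population for one arm."""
    if not population or not population[0]:
        raise ConfigurationError("population is empty")
    kp_map = kp_map if kp_map is not None else build_kp_map(compound)
    out: list[list[SimulationResult]] = []
    for trial_idx, group in enumerate(population):
        row = []
        for subj_idx, ind in enumerate(group):
            model = PBPKModel(ind, compound, kp_map=kp_map, perpetrator=perpetrator)
            meta = {"trial": trial_idx, "subject": subj_idx, "arm": arm_label or ("perpetrator" if perpetrator else "control")}
            row.append(simulate_individual(model, regimen, followup_h=followup_h, grid_dt=grid_dt, rtol=rtol, atol=atol, metadata=meta))
        out.append(row)
    return out
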