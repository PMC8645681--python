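import dataclasses

import numpy as np
import pytest

from apatinib_pbpk.engine import (
    DoseRegimen,
    PBPKModel,
    TISSUE_ORDER,
    build_odes,
    run_trial,
    simulate_individual,
)
from apatinib_pbpk.errors import ConfigurationError
from apatinib_pbpk.metrics import nca
from apatinib_pbpk.population import build_population, population_spec


def _auc(res):
    return nca(res.time_post_dose_h, res.conc_ng_ml)["auc_0_t"]


class TestConservation:
    def test_iv_bolus_without_elimination_conserves_amount(self, compound, kp_map, mean_physiology):
        """No enzymes, no filtration, no gut first pass: the dose circulates
        forever."""
        inert = compound.with_overrides(enzymes=())
        phys = dataclasses.replace(mean_physiology, gfr=0.0)
        model = PBPKModel(phys, inert, kp_map=kp_map, enterocyte_first_pass=False)
        res = simulate_individual(model, DoseRegimen(100.0, route="iv_bolus"), followup_h=48.0)
        total = res.amounts_final["tissues"] + res.amounts_final["blood"]
        assert total == pytest.approx(100.0, rel=1e-6)
        assert res.mass_balance_rel_max < 1e-6

    def test_oral_mass_balance_closes(self, compound, kp_map, mean_physiology):
        model = PBPKModel(mean_physiology, compound, kp_map=kp_map)
        res = simulate_individual(model, DoseRegimen(750.0))
        assert res.mass_balance_rel_max < 1e-3
        assert sum(res.amounts_final.values()) == pytest.approx(750.0, rel=1e-6)


class TestDegenerateConfigurations:
    def test_two_compartment_closed_form(self, compound, kp_map, lumped_physiology):
        """Collapsing the body to blood + muscle with linear renal loss must
        match the analytic biexponential solution."""
        inert = compound.with_overrides(enzymes=(), blood_to_plasma=1.0)
        kp_ones = {t: 1.0 for t in TISSUE_ORDER}
        model = PBPKModel(lumped_physiology, inert, kp_map=kp_ones, enterocyte_first_pass=False)
        dose = 100.0
        res = simulate_individual(
            model, DoseRegimen(dose, route="iv_bolus"), followup_h=96.0, rtol=1e-8, atol=1e-11
        )
        # analytic two-compartment: central = blood, peripheral = muscle
        vc = lumped_physiology.organ_volumes["blood"]
        vp = lumped_physiology.organ_volumes["muscle"]
        q = lumped_physiology.organ_blood_flows["muscle"]
        cl = 0.076 * lumped_physiology.gfr * 0.06
        a_mat = np.array([[-(cl + q) / vc, q / vp], [q / vc, -q / vp]])
        lam, vecs = np.linalg.eig(a_mat)
        coef = np.linalg.solve(vecs, [dose, 0.0])
        t = res.time_post_dose_h
        ac = (vecs[0] * coef * np.exp(np.outer(t, lam))).sum(axis=1)
        expected_ng_ml = ac / vc * 1e3
        mask = t > 0.5  # skip the instant-mixing transient of the tiny organs
        err = np.abs(res.conc_ng_ml[mask] - expected_ng_ml[mask]) / expected_ng_ml[mask].max()
        assert err.max() < 5e-3

    def test_steady_infusion_reaches_predicted_css(self, compound, kp_map, mean_physiology):
        """Renal-only elimination: Css(plasma) = infusion rate / CLr."""
        inert = compound.with_overrides(enzymes=(), fu_plasma=1.0)
        model = PBPKModel(mean_physiology, inert, kp_map=kp_map, enterocyte_first_pass=False)
        regimen = DoseRegimen(200.0, route="iv_infusion", infusion_duration_h=300.0)
        res = simulate_individual(model, regimen, followup_h=310.0)
        rate = 200.0 / 300.0
        clr = 1.0 * mean_physiology.gfr * 0.06
        css = rate / clr * 1e3
        near_end = res.time_post_dose_h > 290.0
        assert res.conc_ng_ml[near_end & (res.time_post_dose_h < 300)].mean() == pytest.approx(
            css, rel=5e-3
        )

    def test_zero_dose_gives_zero_concentrations(self, compound, kp_map, mean_physiology):
        model = PBPKModel(mean_physiology, compound, kp_map=kp_map)
        res = simulate_individual(model, DoseRegimen(0.0))
        assert np.all(res.conc_ng_ml == 0.0)


class TestLinearRegimeProperties:
    def test_dose_proportionality(self, linear_compound, kp_map, mean_physiology):
        model = PBPKModel(mean_physiology, linear_compound, kp_map=kp_map)
        auc750 = _auc(simulate_individual(model, DoseRegimen(750.0)))
        auc250 = _auc(simulate_individual(model, DoseRegimen(250.0)))
        assert auc750 / auc250 == pytest.approx(3.000, rel=1e-3)

    def test_superposition_of_shifted_doses(self, linear_compound, kp_map, mean_physiology):
        model = PBPKModel(mean_physiology, linear_compound, kp_map=kp_map)
        single = simulate_individual(model, DoseRegimen(250.0), followup_h=144.0)
        multi = simulate_individual(
            model, DoseRegimen(250.0, dose_times=(0.0, 24.0)), followup_h=120.0
        )
        shift = int(round(24.0 / 0.1))
        n = len(multi.conc_ng_ml)
        expected = single.conc_ng_ml[:n].copy()
        expected[shift:] += single.conc_ng_ml[: n - shift]
        err = np.abs(multi.conc_ng_ml - expected) / expected.max()
        assert err.max() < 5e-3

    def test_tolerance_convergence(self, compound, kp_map, mean_physiology):
        model = PBPKModel(mean_physiology, compound, kp_map=kp_map)
        a = _auc(simulate_individual(model, DoseRegimen(750.0), rtol=1e-6, atol=1e-9))
        b = _auc(simulate_individual(model, DoseRegimen(750.0), rtol=5e-7, atol=5e-10))
        assert abs(a - b) / b < 1e-3


class TestPackagedDefaults:
    def test_single_dose_tmax_in_plausible_window(self, compound, kp_map, mean_physiology):
        model = PBPKModel(mean_physiology, compound, kp_map=kp_map)
        res = simulate_individual(model, DoseRegimen(250.0))
        m = nca(res.time_post_dose_h, res.conc_ng_ml)
        assert 1.0 <= m["tmax"] <= 4.0

    def test_deterministic_rerun_is_byte_identical(self, compound, kp_map, mean_physiology):
        model = PBPKModel(mean_physiology, compound, kp_map=kp_map)
        a = simulate_individual(model, DoseRegimen(750.0))
        b = simulate_individual(model, DoseRegimen(750.0))
        assert np.array_equal(a.conc_ng_ml, b.conc_ng_ml)


class TestValidation:
    def test_inconsistent_tissue_sets_rejected(self, compound, kp_map, mean_physiology):
        bad = {t: k for t, k in kp_map.items() if t != "muscle"}
        with pytest.raises(ConfigurationError):
            build_odes(mean_physiology, compound, kp_map=bad)

    def test_decreasing_dose_times_rejected(self):
        with pytest.raises(ConfigurationError):
            DoseRegimen(100.0, dose_times=(24.0, 0.0))

    def test_empty_population_rejected(self, compound):
        with pytest.raises(ConfigurationError):
            run_trial([], compound, DoseRegimen(100.0))


def test_run_trial_preserves_grouping(compound, kp_map):
    spec = population_spec("healthy_chinese", 7)
    spec = dataclasses.replace(spec, variability_cv={"volumes": 0.1})
    pop = build_population(spec, 2, 2)
    results = run_trial(pop, compound, DoseRegimen(250.0), kp_map=kp_map, followup_h=24.0)
    assert len(results) == 2 and len(results[0]) == 2
    assert results[1][0].metadata["trial"] == 1
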