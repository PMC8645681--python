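import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from apatinib_pbpk.compound import EnzymeKinetics
from apatinib_pbpk.errors import ConfigurationError
from apatinib_pbpk.metabolism import (
    InteractionTerms,
    PerpetratorModel,
    enzyme_turnover_rhs,
    metabolic_rate,
    perpetrator_concentration,
    renal_clearance,
    scale_vmax_to_organ,
)


class TestScaleVmax:
    def test_hand_unit_conversion(self, mean_physiology):
        """39.1 pmol/min/mg x 40 mg/g x 1800 g x 60 min/h x 397.48e-12 g/pmol."""
        phys = dataclasses.replace(mean_physiology, mppgl=40.0, liver_weight=1800.0)
        kin = EnzymeKinetics("CYP3A4", 39.1, 2.18)
        expected = 39.1 * 40.0 * 1800.0 * 60.0 * 397.48e-12 * 1e3  # mg/h
        assert scale_vmax_to_organ(kin, phys, 397.48) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(67.1, rel=2e-3)

    def test_zero_abundance_silences_enzyme(self, mean_physiology):
        phys = dataclasses.replace(
            mean_physiology, enzyme_abundance_scalar={"CYP3A4": 0.0}
        )
        kin = EnzymeKinetics("CYP3A4", 39.1, 2.18)
        assert scale_vmax_to_organ(kin, phys, 397.48) == 0.0

    def test_linear_in_mppgl_and_liver_weight(self, mean_physiology):
        kin = EnzymeKinetics("CYP3A4", 39.1, 2.18)
        base = scale_vmax_to_organ(kin, mean_physiology, 397.48)
        doubled = dataclasses.replace(
            mean_physiology, mppgl=2 * mean_physiology.mppgl,
            liver_weight=2 * mean_physiology.liver_weight,
        )
        assert scale_vmax_to_organ(kin, doubled, 397.48) == pytest.approx(4 * base)


ENZYMES = [
    EnzymeKinetics("CYP3A4", 39.1, 2.18),
    EnzymeKinetics("CYP3A5", 3.28, 1.93),
    EnzymeKinetics("CYP2D6", 9.82, 1.41),
]
VMAX_ORG = {"CYP3A4": 60.0, "CYP3A5": 5.0, "CYP2D6": 15.0}


class TestMetabolicRate:
    def test_first_order_limit(self):
        cu = 1e-6
        rate = metabolic_rate(cu, ENZYMES, VMAX_ORG)
        clint = sum(VMAX_ORG[e.enzyme_id] / e.km for e in ENZYMES)
        assert rate / cu == pytest.approx(clint, rel=1e-4)

    def test_saturation_limit(self):
        rate = metabolic_rate(1e6, ENZYMES, VMAX_ORG)
        assert rate == pytest.approx(sum(VMAX_ORG.values()), rel=1e-4)

    def test_competitive_inhibition_scales_km(self):
        cu = 1e-4
        base = metabolic_rate(cu, ENZYMES[:1], VMAX_ORG)
        inhibited = metabolic_rate(
            cu, ENZYMES[:1], VMAX_ORG, inhibitor_unbound={"CYP3A4": 9.0}, ki={"CYP3A4": 1.0}
        )
        assert base / inhibited == pytest.approx(10.0, rel=1e-3)

    def test_against_brute_force_sum(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            cu = float(rng.uniform(0, 20))
            state = {e.enzyme_id: float(rng.uniform(0.1, 2)) for e in ENZYMES}
            iu = {e.enzyme_id: float(rng.uniform(0, 5)) for e in ENZYMES}
            ki = {e.enzyme_id: float(rng.uniform(0.5, 5)) for e in ENZYMES}
            expected = 0.0
            for e in ENZYMES:
                km_app = e.km * (1 + iu[e.enzyme_id] / ki[e.enzyme_id])
                expected += state[e.enzyme_id] * VMAX_ORG[e.enzyme_id] * cu / (km_app + cu)
            got = metabolic_rate(cu, ENZYMES, VMAX_ORG, state, iu, ki)
            assert got == pytest.approx(expected, rel=1e-12)


class TestEnzymeTurnover:
    def test_baseline_fixed_point(self):
        terms = InteractionTerms(kinact=1.0, ki_app=1.0)
        assert enzyme_turnover_rhs(1.0, 0.03, 0.0, terms) == pytest.approx(0.0)
        assert enzyme_turnover_rhs(0.5, 0.03, 0.0, terms) > 0  # relaxes back up

    def test_pure_induction_steady_state(self):
        terms = InteractionTerms(ind_max=7.0, ind_c50=0.1)
        e_ss = 1.0 + 7.0  # Iu >> IndC50
        assert enzyme_turnover_rhs(e_ss, 0.02, 1e6, terms) == pytest.approx(0.0, abs=1e-4)

    def test_pure_inactivation_closed_form_matches_integration(self):
        kdeg, kinact, ki_app, iu = 0.0193, 2.0, 5.0, 1.3
        terms = InteractionTerms(kinact=kinact, ki_app=ki_app)
        lam = kinact * iu / (ki_app + iu)
        e_closed = kdeg / (kdeg + lam)
        sol = solve_ivp(
            lambda t, e: [enzyme_turnover_rhs(e[0], kdeg, iu, terms)],
            (0, 2000.0), [1.0], rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(e_closed, rel=1e-6)


def test_renal_clearance_hand_value():
    assert renal_clearance(0.076, 120.0) == pytest.approx(0.5472, rel=1e-12)
    assert renal_clearance(0.076, 0.0) == 0.0
    assert renal_clearance(0.152, 60.0) == pytest.approx(renal_clearance(0.076, 120.0))


def _perp(**kw):
    base = dict(
        name="probe", molecular_weight=400.0, dose_mg=100.0, interval_h=24.0, days=6,
        ka=1.0, v_f=50.0, cl_f=5.0, fu=0.5,
        interactions={"CYP3A4": InteractionTerms(ki=1.0)},
    )
    base.update(kw)
    return PerpetratorModel(**base)


class TestPerpetratorForcing:
    def test_zero_before_first_dose(self):
        assert perpetrator_concentration(_perp(), -0.5) == 0.0

    def test_bolus_limit_matches_monoexponential(self):
        p = _perp(ka=500.0, days=1)
        kel = p.kel
        for t in (1.0, 5.0, 20.0):
            expected = 0.5 * (100.0 / 50.0) * np.exp(-kel * t) / 400.0 * 1e3
            assert perpetrator_concentration(p, t) == pytest.approx(expected, rel=2e-2)

    def test_steady_state_accumulation_ratio(self):
        """Trough accumulation approaches 1/(1 - exp(-kel tau))."""
        p = _perp(ka=50.0, days=40, cl_f=5.0, v_f=50.0)  # kel = 0.1/h
        tau = 24.0
        trough1 = perpetrator_concentration(p, tau - 1e-6)
        trough_ss = perpetrator_concentration(p, 40 * tau - 1e-6)
        expected = 1.0 / (1.0 - np.exp(-p.kel * tau))
        assert trough_ss / trough1 == pytest.approx(expected, rel=1e-3)

    def test_requires_an_interaction_mechanism(self):
        with pytest.raises(ConfigurationError):
            _perp(interactions={})

    def test_packaged_fixtures_load(self):
        from apatinib_pbpk.config import list_perpetrators

        names = list_perpetrators()
        assert len(names) == 10
        for n in names:
            p = PerpetratorModel.load(n)
            assert any(t.any_mechanism for t in p.interactions.values())
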