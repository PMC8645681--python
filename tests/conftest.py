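import dataclasses

import numpy as np
import pytest

from apatinib_pbpk import CompoundParameters, build_kp_map
from apatinib_pbpk.engine import TISSUE_ORDER
from apatinib_pbpk.population import IndividualPhysiology, population_spec


@pytest.fixture(scope="session")
def compound() -> CompoundParameters:
    return CompoundParameters.load()


@pytest.fixture(scope="session")
def kp_map(compound):
    return build_kp_map(compound)


@pytest.fixture(scope="session")
def mean_physiology() -> IndividualPhysiology:
    return population_spec("healthy_chinese", 0).mean_physiology


@pytest.fixture(scope="session")
def linear_compound(compound) -> CompoundParameters:
    """Forced-linear configuration: unbounded solubility, first-order
    metabolism (Km and Vmax scaled together so CLint is unchanged)."""
    enzymes = tuple(
        dataclasses.replace(e, vmax=e.vmax * 1e5, km=e.km * 1e5) for e in compound.enzymes
    )
    return compound.with_overrides(
        intrinsic_solubility=1e5, solubility_cap=1e7, enzymes=enzymes
    )


@pytest.fixture(scope="session")
def lumped_physiology(mean_physiology) -> IndividualPhysiology:
    """Degenerate physiology that collapses the body to blood + muscle:
    all other tissues carry negligible volume and equilibrate instantly."""
    co = 1000.0
    q_muscle = 20.0
    volumes = {t: 1e-3 for t in TISSUE_ORDER}
    volumes["muscle"] = 25.0
    volumes["blood"] = 4.7
    n_other = len(TISSUE_ORDER) - 2  # lung carries no systemic flow entry
    flows = {t: (co - q_muscle) / n_other for t in TISSUE_ORDER if t != "lung"}
    flows["muscle"] = q_muscle
    ind = dataclasses.replace(
        mean_physiology,
        cardiac_output=co,
        organ_volumes=volumes,
        organ_blood_flows=flows,
        liver_weight=1.0,
        gfr=438.596491,  # fu 0.076 -> CLr = 2.0 L/h
    )
    ind.validate()
    return ind
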