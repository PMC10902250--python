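"""Shared fixtures: reference patients, populations, calibrated constants."""

import pytest

from ldp_insilico.physiology import ModelConstants, calibrate_constants
from ldp_insilico.population import (
    PatientParameters,
    default_population_specs,
    sample_population,
)


def make_patient(**overrides) -> PatientParameters:
    """A mid-cohort reference patient; fields overridable per test."""
    base = dict(
        id=0, age=55.0, weight=85.0, height=1.70, sex="male", pao2=100.0,
        vco2=223.0, vd_anat=128.0, f_alv_ds=0.37, r_rs=11.0, peep_i=1.5,
        c_lung=47.0, c_cw=125.0, sid=34.0, rr=28.0, g_chemo=2.5,
        b_apnea=34.0,
    )
    base.update(overrides)
    return PatientParameters(**base)


@pytest.fixture
def reference_patient() -> PatientParameters:
    return make_patient()


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def small_population():
    return sample_population(n=200, seed=11)


@pytest.fixture(scope="session")
def calibration():
    """Controller constants calibrated on a 600-patient sample."""
    pop = sample_population(n=600, seed=101)
    return calibrate_constants(pop)


@pytest.fixture(scope="session")
def calibrated_specs(calibration):
    return default_population_specs(
        g_chemo_median=calibration.g_chemo_median,
        b_apnea_mean=calibration.b_apnea_mean,
    )
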