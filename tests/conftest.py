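import pytest
from hypothesis import HealthCheck, settings

from chromspace import (
    CalibrationDesign,
    DEFAULT_INSTRUMENT,
    MethodConditions,
    NoiseSpec,
    default_apixaban_mixture,
    fit_model,
    generate_run_table,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

WORKING_POINT = MethodConditions(tG_min=3.0, T_C=40.0, pH=6.0)


@pytest.fixture(scope="session")
def instr():
    return DEFAULT_INSTRUMENT


@pytest.fixture(scope="session")
def design():
    return CalibrationDesign()


@pytest.fixture(scope="session")
def mixture():
    return default_apixaban_mixture()


@pytest.fixture(scope="session")
def working_point():
    return WORKING_POINT


@pytest.fixture(scope="session")
def clean_run_table(mixture, design, instr):
    """Noise-free simulated 12-run calibration table (seed 1)."""
    return generate_run_table(mixture, design, instr, NoiseSpec(seed=1))


@pytest.fixture(scope="session")
def fitted_model(clean_run_table, design, instr):
    """Model fitted to the noise-free fixture table."""
    return fit_model(clean_run_table, design, instr)
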