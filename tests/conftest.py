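import pytest
from hypothesis import HealthCheck, settings

from fluokin.calibration import compute_adjustment_factor, load_validation_studies
from fluokin.config import default_config
from fluokin.exposure import scenario_preset
from fluokin.model import ModelBundle

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def validation_studies():
    return load_validation_studies()


@pytest.fixture(scope="session")
def calibration_result(config, validation_studies):
    """Adjustment-factor computation shared across the suite (six simulations)."""
    return compute_adjustment_factor(validation_studies, config)


@pytest.fixture(scope="session")
def adjustment_factor(calibration_result):
    return calibration_result.adjustment_factor


@pytest.fixture(scope="session")
def bundle4_s1(config):
    """Uncalibrated 4-year-old under the fluoridated-water scenario."""
    return ModelBundle.build(4.0, scenario_preset("ontario-s1", 4.0), config)


@pytest.fixture(scope="session")
def bundle8_s1(config):
    return ModelBundle.build(8.0, scenario_preset("ontario-s1", 8.0), config)
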