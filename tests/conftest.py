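import pytest
from hypothesis import HealthCheck, settings

import insulin_cea as ic

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibration_report() -> ic.CalibrationReport:
    return ic.calibrate()


@pytest.fixture(scope="session")
def calibrated(calibration_report):
    """Calibrated base-case parameters per patient group."""
    return {
        g: ic.calibrated_parameters(g, calibration_report) for g in ic.PatientGroup
    }


@pytest.fixture(scope="session")
def clinical_inputs():
    return ic.load_clinical_inputs()


@pytest.fixture(scope="session")
def summary():
    return ic.load_cost_utility_summary()
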