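from dataclasses import replace

import pytest

from ecco2r.calibrate import CalibrationTargets, calibrate
from ecco2r.lung import VentilatorSettings
from ecco2r.transport import PatientParameters, solve_steady_state


@pytest.fixture(scope="session")
def reference_patient():
    """Uncalibrated 78-kg average ventilated patient."""
    return PatientParameters(actual_body_weight=78.0)


@pytest.fixture(scope="session")
def calibration(reference_patient):
    """(shunt fraction, RQ) calibrated to the population operating point."""
    return calibrate(CalibrationTargets(), reference_patient)


@pytest.fixture(scope="session")
def calibrated_patient_fx(reference_patient, calibration):
    fs, rq = calibration
    return replace(reference_patient, shunt_fraction=fs, rq=rq)


@pytest.fixture(scope="session")
def baseline_vent():
    return VentilatorSettings(frequency=20.8, tidal_volume_per_kg=7.6, fio2=0.6)


@pytest.fixture(scope="session")
def baseline_solution(calibrated_patient_fx, baseline_vent):
    return solve_steady_state(calibrated_patient_fx, baseline_vent)
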