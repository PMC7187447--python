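"""Calibration of unobserved model parameters to a population operating point.

The pulmonary shunt fraction and respiratory quotient are not directly
observable in routine data.  They are recovered by requiring the model, run at
the population-average ventilator prescription, to reproduce the reported
arterial blood gases: PaCO2 and PaO2 (the latter given as a PaO2/FiO2 ratio).
The O2 uptake per kg predicted body weight is held fixed at its reported
value, closing the two-equation system in the two unknowns.

The default targets are the average ventilated ARDS patient of a large
observational cohort: PaCO2 46.0 mmHg and PaO2/FiO2 161 at FiO2 0.6, under
f 20.8/min, VT 7.6 mL/kg PBW, VO2 4.0 mL/min/kg PBW, without extracorporeal
support.  Once calibrated, (shunt fraction, RQ, VO2) are frozen for all
scenario runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, root

from .constants import DEFAULT_CONSTANTS, ChemistryConstants
from .lung import VentilatorSettings
from .transport import Ecco2rDevice, PatientParameters, solve_steady_state

__all__ = ["CalibrationTargets", "CalibrationError", "calibrate", "derived_metabolic_rates"]

_FS_BOUNDS = (1e-4, 0.5)
_RQ_BOUNDS = (0.6, 1.1)


class CalibrationError(RuntimeError):
    """Raised when no (shunt fraction, RQ) pair reproduces the targets."""


@dataclass(frozen=True)
class CalibrationTargets:
    """Population-average operating point used to pin down (fs, RQ)."""

    paco2_target: float = 46.0         # mmHg
    pao2_over_fio2: float = 161.0      # mmHg
    fio2: float = 0.6
    frequency: float = 20.8            # /min
    tidal_volume_per_kg: float = 7.6   # mL/kg PBW
    vo2_per_kg_pbw: float = 4.0        # mL/min/kg PBW
    ecco2r_rate: float = 0.0           # mL/min

    def __post_init__(self) -> None:
        for name in ("paco2_target", "pao2_over_fio2", "fio2", "frequency",
                     "tidal_volume_per_kg", "vo2_per_kg_pbw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ecco2r_rate < 0:
            raise ValueError("ecco2r_rate must be non-negative")

    @property
    def pao2_target(self) -> float:
        """Arterial PO2 target in mmHg (ratio times FiO2)."""
        return self.pao2_over_fio2 * self.fio2

    def ventilator_settings(self) -> VentilatorSettings:
        return VentilatorSettings(
            frequency=self.frequency,
            tidal_volume_per_kg=self.tidal_volume_per_kg,
            fio2=self.fio2,
        )


def _residuals(fs, rq, targets, patient, constants):
    trial = replace(patient, shunt_fraction=fs, rq=rq,
                    vo2_per_kg_pbw=targets.vo2_per_kg_pbw)
    sol = solve_steady_state(
        trial, targets.ventilator_settings(),
        Ecco2rDevice(targets.ecco2r_rate), constants,
    )
    return sol.paco2 - targets.paco2_target, sol.arterial.po2 - targets.pao2_target


def calibrate(
    targets: CalibrationTargets,
    patient: PatientParameters,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
    tol: float = 0.05,
) -> tuple[float, float]:
    """Recover (shunt_fraction, rq) reproducing the target blood gases.

    A two-dimensional Powell-hybrid root find on (fs, RQ); if it fails to meet
    ``tol`` (mmHg, on both PaCO2 and PaO2) a deterministic nested bisection
    (RQ from the CO2 target inside, fs from the O2 target outside) is used.
    Deterministic throughout.
    """

    def vec(x):
        fs = float(np.clip(x[0], *_FS_BOUNDS))
        rq = float(np.clip(x[1], *_RQ_BOUNDS))
        return _residuals(fs, rq, targets, patient, constants)

    sol = root(vec, x0=[0.15, 0.9], method="hybr", tol=1e-12)
    fs, rq = float(np.clip(sol.x[0], *_FS_BOUNDS)), float(np.clip(sol.x[1], *_RQ_BOUNDS))
    r_co2, r_o2 = _residuals(fs, rq, targets, patient, constants)
    if max(abs(r_co2), abs(r_o2)) <= tol:
        return fs, rq

    # fallback: nested scalar bisection
    def rq_for(fs_trial):
        def f(rq_trial):
            return _residuals(fs_trial, rq_trial, targets, patient, constants)[0]
        lo, hi = _RQ_BOUNDS
        if f(lo) * f(hi) > 0:
            raise CalibrationError(
                f"no RQ in {_RQ_BOUNDS} matches PaCO2 {targets.paco2_target} "
                f"mmHg at fs={fs_trial:.4f} (residuals {f(lo):.3g}, {f(hi):.3g})"
            )
        return brentq(f, lo, hi, xtol=1e-10)

    def o2_resid(fs_trial):
        return _residuals(fs_trial, rq_for(fs_trial), targets, patient, constants)[1]

    lo, hi = _FS_BOUNDS
    rlo, rhi = o2_resid(lo), o2_resid(hi)
    if rlo * rhi > 0:
        raise CalibrationError(
            f"no shunt fraction in {_FS_BOUNDS} matches PaO2 "
            f"{targets.pao2_target:.1f} mmHg (residuals {rlo:.3g}, {rhi:.3g})"
        )
    fs = brentq(o2_resid, lo, hi, xtol=1e-10)
    rq = rq_for(fs)
    r_co2, r_o2 = _residuals(fs, rq, targets, patient, constants)
    if max(abs(r_co2), abs(r_o2)) > tol:
        raise CalibrationError(
            f"calibration residuals ({r_co2:.3g}, {r_o2:.3g}) mmHg exceed {tol}"
        )
    return fs, rq


def derived_metabolic_rates(
    patient: PatientParameters, rq: float
) -> tuple[float, float]:
    """(VO2, VCO2) in mL/min: uptake scales with PBW, production is RQ x VO2."""
    if patient.pbw <= 0:
        raise ValueError("pbw must be positive")
    vo2 = patient.vo2_per_kg_pbw * patient.pbw
    return vo2, rq * vo2
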