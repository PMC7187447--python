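"""Scripted scenario sweeps: tabular reproductions of the model's result set.

Each function runs a family of steady-state solutions over a grid of
ventilator settings (and, where relevant, PaCO2 targets) for a calibrated
patient and returns a tidy :class:`pandas.DataFrame`.  The solver contains no
randomness, so re-running a sweep with the same configuration reproduces the
output byte for byte.

A YAML/JSON configuration (see :func:`load_config` / :func:`default_config`)
describes the patient, the calibration targets and the sweep grids; the
:mod:`ecco2r.cli` verbs are thin wrappers over these functions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace

import pandas as pd
import yaml

from .calibrate import CalibrationTargets, calibrate
from .constants import DEFAULT_CONSTANTS, ChemistryConstants
from .lung import VentilatorSettings
from .transport import (
    Ecco2rDevice,
    InfeasibleError,
    PatientParameters,
    find_required_ecco2r,
    solve_steady_state,
)

__all__ = [
    "default_config",
    "load_config",
    "calibrated_patient",
    "run_tidal_volume_sweep",
    "run_required_ecco2r_sweep",
    "run_compartment_mass_report",
    "write_table",
]

log = logging.getLogger("ecco2r.scenarios")

#: Column order of the tidal-volume sweep tables (documented in the README).
SWEEP_COLUMNS = [
    "tidal_volume_per_kg", "frequency", "ecco2r_rate",
    "paco2", "pha", "pvco2", "phv",
    "alveolar_pco2", "alveolar_po2", "pao2",
    "total_body_co2", "total_body_co2_pbw_basis",
    "co2_arterial_mmol", "co2_venous_mmol",
    "co2_interstitial_mmol", "co2_tissue_mmol",
]


def default_config() -> dict:
    """Reference configuration: the 78-kg average ventilated ARDS patient."""
    return {
        "patient": {
            "actual_body_weight": 78.0,
            "hematocrit": 0.30,
            "base_excess": -3.0,
        },
        "calibration": asdict(CalibrationTargets()),
        "ventilator": {
            "frequency": 20.8,
            "tidal_volume_per_kg": 7.6,
            "dead_space_fraction": 0.60,
            "fio2": 0.60,
        },
        "device": {"removal_rate": 0.0},
        "sweeps": {
            "tidal_volumes": [7.6, 6.0, 5.0, 4.0, 3.0],
            "frequencies": [20.8, 26.0],
            "targets": [46.0, 40.0],
        },
    }


def load_config(path=None) -> dict:
    """Read a YAML or JSON scenario configuration, filling in defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        user = (json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def calibrated_patient(
    config: dict | None = None,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> tuple[PatientParameters, CalibrationTargets, tuple[float, float]]:
    """Build the patient from a config and calibrate (shunt fraction, RQ).

    Returns the frozen calibrated patient, the targets used, and the
    calibrated ``(fs, rq)`` pair.
    """
    cfg = config or default_config()
    targets = CalibrationTargets(**cfg["calibration"])
    patient = PatientParameters(
        vo2_per_kg_pbw=targets.vo2_per_kg_pbw, **cfg["patient"]
    )
    fs, rq = calibrate(targets, patient, constants)
    log.info("calibrated shunt_fraction=%.5f rq=%.5f", fs, rq)
    return replace(patient, shunt_fraction=fs, rq=rq), targets, (fs, rq)


def _row(vent: VentilatorSettings, sol) -> dict:
    return {
        "tidal_volume_per_kg": vent.tidal_volume_per_kg,
        "frequency": vent.frequency,
        "ecco2r_rate": sol.ecco2r_rate,
        "paco2": sol.paco2,
        "pha": sol.arterial.plasma_ph,
        "pvco2": sol.pvco2,
        "phv": sol.venous.plasma_ph,
        "alveolar_pco2": sol.alveolar.alveolar_pco2,
        "alveolar_po2": sol.alveolar.alveolar_po2,
        "pao2": sol.arterial.po2,
        "total_body_co2": sol.total_body_co2,
        "total_body_co2_pbw_basis": sol.total_body_co2_pbw_basis,
        "co2_arterial_mmol": sol.compartment_co2_mmol["arterial"],
        "co2_venous_mmol": sol.compartment_co2_mmol["venous"],
        "co2_interstitial_mmol": sol.compartment_co2_mmol["interstitial"],
        "co2_tissue_mmol": sol.compartment_co2_mmol["tissue"],
    }


def run_tidal_volume_sweep(
    vt_list,
    frequency: float,
    device_rate: float = 0.0,
    patient: PatientParameters | None = None,
    fio2: float = 0.60,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Steady-state blood gases and CO2 stores over a tidal-volume grid.

    One row per tidal volume (mL/kg PBW) at the given ventilation frequency
    and device removal rate; rows are ordered as supplied.
    """
    if patient is None:
        patient, _, _ = calibrated_patient(constants=constants)
    rows = []
    for vt in vt_list:
        vent = VentilatorSettings(frequency, vt, fio2=fio2)
        try:
            sol = solve_steady_state(patient, vent, Ecco2rDevice(device_rate), constants)
        except (InfeasibleError, ValueError) as exc:
            raise type(exc)(f"tidal volume {vt} mL/kg PBW: {exc}") from exc
        log.info(
            "solved VT=%.1f f=%.1f device=%.1f -> PaCO2=%.2f residual=%.2e",
            vt, frequency, device_rate, sol.paco2,
            max(abs(v) for v in sol.residuals.values()),
        )
        rows.append(_row(vent, sol))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def run_required_ecco2r_sweep(
    vt_list,
    frequencies,
    target_paco2_list,
    patient: PatientParameters | None = None,
    fio2: float = 0.60,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Required device CO2 removal rate over a (VT, frequency, target) grid.

    Infeasible cells (target unreachable) are flagged in the ``feasible``
    column rather than aborting the sweep; the mixed-venous PCO2 of each
    converged solution is reported alongside the rate.
    """
    if patient is None:
        patient, _, _ = calibrated_patient(constants=constants)
    rows = []
    for target in target_paco2_list:
        for f in frequencies:
            for vt in vt_list:
                vent = VentilatorSettings(f, vt, fio2=fio2)
                row = {
                    "tidal_volume_per_kg": vt, "frequency": f,
                    "target_paco2": target,
                }
                try:
                    res = find_required_ecco2r(patient, vent, target, constants)
                except InfeasibleError as exc:
                    log.warning("infeasible cell VT=%.1f f=%.1f target=%.1f: %s",
                                vt, f, target, exc)
                    row.update({
                        "required_ecco2r": float("nan"), "pvco2": float("nan"),
                        "paco2": float("nan"), "already_below_target": False,
                        "feasible": False,
                    })
                else:
                    log.info("required rate VT=%.1f f=%.1f target=%.1f -> %.2f mL/min",
                             vt, f, target, res.removal_rate)
                    row.update({
                        "required_ecco2r": res.removal_rate,
                        "pvco2": res.solution.venous.pco2,
                        "paco2": res.solution.paco2,
                        "already_below_target": res.already_below_target,
                        "feasible": True,
                    })
                rows.append(row)
    return pd.DataFrame(rows)


def run_compartment_mass_report(
    vt_list,
    frequency: float = 20.8,
    patient: PatientParameters | None = None,
    fio2: float = 0.60,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Per-compartment CO2 masses (mmol) across a tidal-volume grid.

    Arterial blood carries a negligible share; the interstitial space holds
    the largest single share of the whole-body store.
    """
    sweep = run_tidal_volume_sweep(vt_list, frequency, 0.0, patient, fio2, constants)
    out = sweep[[
        "tidal_volume_per_kg", "frequency",
        "co2_arterial_mmol", "co2_venous_mmol",
        "co2_interstitial_mmol", "co2_tissue_mmol",
        "total_body_co2",
    ]].copy()
    out["interstitial_share"] = out["co2_interstitial_mmol"] / out["total_body_co2"]
    return out


def write_table(df: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write a scenario table as CSV (one header row) or JSON records."""
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'json')")
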