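"""Six-compartment steady-state CO2/O2 transport with extracorporeal removal.

Compartments: arterial blood, mixed-venous blood, post-device venous blood,
lung-capillary blood (all four at full acid-base equilibrium), plus
interstitial fluid and tissue cells, whose contents are derived from the
venous state alone.  Blood circulates venous -> ECCO2R device -> {lung
capillary, pulmonary shunt} -> arterial -> tissues -> venous; the device sits
in-line on the whole cardiac output upstream of the lung, so shunted blood is
post-device blood.  The device is characterised solely by its CO2 removal
rate; O2 transfer across it is neglected.

At steady state the solution is sequential rather than iterative in the gas
tensions: the lung must eliminate exactly (production - device rate), which
fixes alveolar PCO2; nitrogen balance at the required O2 uptake fixes alveolar
PO2; end-capillary blood equilibrates with the alveolus; and the remaining
compartments follow from linear content algebra plus content -> tension
inversions of the blood-chemistry model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from scipy.optimize import brentq

from . import blood, lung
from .blood import BloodState, ExtravascularState
from .constants import DEFAULT_CONSTANTS, ChemistryConstants
from .lung import AlveolarState, VentilatorSettings

__all__ = [
    "PatientParameters",
    "Ecco2rDevice",
    "SteadyStateSolution",
    "RequiredEcco2rResult",
    "InfeasibleError",
    "predicted_body_weight",
    "cardiac_output",
    "solve_steady_state",
    "total_body_co2",
    "find_required_ecco2r",
]

#: Compartment volumes as fractions of body weight (kg ~ L of water space).
#: Vascular compartments scale with predicted body weight; the extravascular
#: spaces (interstitial fluid, muscle tissue cells) scale with actual body
#: weight -- the basis that reproduces printed whole-body CO2 stores across
#: the tidal-volume range (the predicted-weight-only sum is also reported).
DEFAULT_VOLUME_FRACTIONS: Mapping[str, float] = MappingProxyType({
    "arterial": 0.0075,
    "venous": 0.0675,
    "lung_capillary": 0.0,
    "post_ecco2r": 0.0,
    "interstitial": 0.126,
    "tissue": 0.20,
})

_EXTRAVASCULAR = ("interstitial", "tissue")

#: Floor on venous PO2 (mmHg) to keep the chemistry solvable in extreme
#: scenarios; solutions report when it is hit.
VENOUS_PO2_FLOOR = 1.0


class InfeasibleError(ValueError):
    """No physical steady state exists for the requested inputs."""


def predicted_body_weight(actual_body_weight: float) -> float:
    """Predicted body weight, taken as 85% of actual body weight (kg)."""
    if actual_body_weight <= 0:
        raise ValueError("actual_body_weight must be positive")
    return 0.85 * actual_body_weight


def cardiac_output(pbw: float) -> float:
    """Cardiac output in L/min, 0.251 * PBW^0.67 (body-surface-area scaling)."""
    if pbw <= 0:
        raise ValueError("pbw must be positive")
    return 0.251 * pbw ** 0.67


@dataclass(frozen=True)
class PatientParameters:
    """Anthropometrics and fixed physiological parameters of one patient.

    Defaults are the calibrated average ventilated ARDS patient: hematocrit
    30%, base excess -3 mEq/L, O2 uptake 4.0 mL/min per kg PBW, respiratory
    quotient 0.966 and pulmonary shunt fraction 0.176 (see
    :mod:`ecco2r.calibrate` for how the last three are obtained).
    """

    actual_body_weight: float
    pbw: float | None = None
    hematocrit: float = 0.30
    base_excess: float = -3.0
    vo2_per_kg_pbw: float = 4.0
    rq: float = 0.966
    shunt_fraction: float = 0.176
    volume_fractions: Mapping[str, float] = field(default_factory=lambda: DEFAULT_VOLUME_FRACTIONS)

    def __post_init__(self) -> None:
        if self.actual_body_weight <= 0:
            raise ValueError("actual_body_weight must be positive")
        if self.pbw is None:
            object.__setattr__(self, "pbw", predicted_body_weight(self.actual_body_weight))
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if not 0 <= self.shunt_fraction < 1:
            raise ValueError("shunt_fraction must lie in [0, 1)")
        if self.vo2_per_kg_pbw <= 0 or self.rq <= 0:
            raise ValueError("metabolic rates must be positive")
        missing = set(DEFAULT_VOLUME_FRACTIONS) - set(self.volume_fractions)
        if missing:
            raise ValueError(f"volume_fractions missing compartments: {sorted(missing)}")

    @property
    def vo2(self) -> float:
        """Whole-body O2 uptake, mL/min."""
        return self.vo2_per_kg_pbw * self.pbw

    @property
    def vco2(self) -> float:
        """Whole-body CO2 production, mL/min."""
        return self.rq * self.vo2

    @property
    def cardiac_output(self) -> float:
        return cardiac_output(self.pbw)

    def compartment_volume(self, name: str) -> float:
        """Compartment volume in litres (vascular on PBW, extravascular on ABW)."""
        basis = self.actual_body_weight if name in _EXTRAVASCULAR else self.pbw
        return self.volume_fractions[name] * basis

    def compartment_volume_pbw(self, name: str) -> float:
        """Compartment volume in litres with every fraction applied to PBW."""
        return self.volume_fractions[name] * self.pbw


@dataclass(frozen=True)
class Ecco2rDevice:
    """Veno-venous extracorporeal CO2 removal device.

    Characterised only by its CO2 removal rate (mL/min); blood-flow and
    membrane geometry are outside the model's scope.
    """

    removal_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.removal_rate < 0:
            raise ValueError("removal_rate must be non-negative")


@dataclass(frozen=True)
class SteadyStateSolution:
    """Converged states of all six compartments plus fluxes and CO2 stores."""

    arterial: BloodState
    venous: BloodState
    post_ecco2r: BloodState
    lung_capillary: BloodState
    interstitial: ExtravascularState
    tissue: ExtravascularState
    alveolar: AlveolarState
    cardiac_output: float              # L/min
    co2_production: float              # mL/min
    o2_uptake: float                   # mL/min
    lung_co2_elimination: float        # mL/min
    ecco2r_rate: float                 # mL/min
    total_body_co2: float              # mmol, mixed volume basis (primary)
    total_body_co2_pbw_basis: float    # mmol, all fractions on PBW
    compartment_co2_mmol: Mapping[str, float]
    residuals: Mapping[str, float]
    venous_po2_floor_hit: bool = False

    @property
    def paco2(self) -> float:
        return self.arterial.pco2

    @property
    def pvco2(self) -> float:
        return self.venous.pco2


def _compartment_masses(patient, arterial, venous, isf, tissue, pbw_basis=False):
    vol = patient.compartment_volume_pbw if pbw_basis else patient.compartment_volume
    conc = {
        "arterial": arterial.total_co2,
        "venous": venous.total_co2,
        "lung_capillary": 0.0,
        "post_ecco2r": 0.0,
        "interstitial": isf.total_co2,
        "tissue": tissue.total_co2,
    }
    return {name: conc[name] * vol(name) for name in DEFAULT_VOLUME_FRACTIONS}


def solve_steady_state(
    patient: PatientParameters,
    vent: VentilatorSettings,
    device: Ecco2rDevice = Ecco2rDevice(0.0),
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> SteadyStateSolution:
    """Solve the whole-body steady state for one prescription.

    Raises
    ------
    InfeasibleError
        If the device removal rate meets or exceeds CO2 production (the lung
        would need a non-positive alveolar PCO2) or the ventilation cannot
        sustain the O2 uptake.
    """
    c = constants
    vco2, vo2 = patient.vco2, patient.vo2
    q = patient.cardiac_output
    fs = patient.shunt_fraction

    if device.removal_rate >= vco2:
        raise InfeasibleError(
            f"device removal rate {device.removal_rate:.1f} mL/min >= CO2 "
            f"production {vco2:.1f} mL/min: no steady state with positive "
            "alveolar PCO2"
        )

    # --- alveolar gas (closed form at steady state) -------------------------
    va = lung.alveolar_ventilation(vent, patient.pbw)
    j_lung = vco2 - device.removal_rate
    pa_co2 = j_lung * c.dry_pressure / (1000.0 * va)
    try:
        pa_o2 = lung.alveolar_po2_for_uptake(va, vent.fio2, pa_co2, vo2, c)
    except ValueError as exc:
        raise InfeasibleError(str(exc)) from exc

    # --- end-capillary blood (equilibrated with alveolus) -------------------
    cap = blood.solve_blood_equilibrium(
        pa_co2, pa_o2, patient.base_excess, patient.hematocrit, c
    )

    # --- content algebra ----------------------------------------------------
    # per-pass content increments (mM) across tissues and the device
    d_tissue_co2 = vco2 / (c.co2_ml_per_mmol * q)
    d_device_co2 = device.removal_rate / (c.co2_ml_per_mmol * q)
    d_tissue_o2 = vo2 / (c.o2_ml_per_mmol * q)

    # arterial = (1-fs)*capillary + fs*post-device, venous = arterial + tissue
    # increment, post-device = venous - device decrement  =>  closed form:
    shunt_gain = fs / (1.0 - fs)
    c_art_co2 = cap.total_co2 + shunt_gain * (d_tissue_co2 - d_device_co2)
    c_art_o2 = cap.total_o2 - shunt_gain * d_tissue_o2
    c_ven_co2 = c_art_co2 + d_tissue_co2
    c_ven_o2 = c_art_o2 - d_tissue_o2
    c_post_co2 = c_ven_co2 - d_device_co2

    if c_art_o2 <= 0 or c_ven_o2 <= 0:
        raise InfeasibleError(
            "oxygen delivery cannot sustain the requested O2 uptake "
            f"(arterial O2 content {c_art_o2:.3f} mM, venous {c_ven_o2:.3f} mM)"
        )

    # --- recover full states from contents ----------------------------------
    be, hct = patient.base_excess, patient.hematocrit
    arterial = blood.blood_state_from_contents(c_art_co2, c_art_o2, be, hct, c)
    floor_hit = False
    try:
        venous = blood.blood_state_from_contents(c_ven_co2, c_ven_o2, be, hct, c)
        if venous.po2 < VENOUS_PO2_FLOOR:
            raise ValueError("below venous PO2 floor")
    except (ValueError, blood.ConvergenceError):
        floor_hit = True
        pv_co2 = blood.pco2_from_total_co2(c_ven_co2, VENOUS_PO2_FLOOR, be, hct, c)
        venous = blood.solve_blood_equilibrium(pv_co2, VENOUS_PO2_FLOOR, be, hct, c)
    post_po2 = max(venous.po2, VENOUS_PO2_FLOOR)
    post_pco2 = blood.pco2_from_total_co2(c_post_co2, post_po2, be, hct, c)
    post = blood.solve_blood_equilibrium(post_pco2, post_po2, be, hct, c)

    isf = blood.interstitial_from_venous(venous, c)
    tissue = blood.tissue_cell_from_venous(venous, c)

    # --- stores and residual bookkeeping ------------------------------------
    masses = _compartment_masses(patient, arterial, venous, isf, tissue)
    masses_pbw = _compartment_masses(patient, arterial, venous, isf, tissue, pbw_basis=True)

    j_lung_check = lung.lung_co2_elimination(va, pa_co2, c)
    j_lung_blood = (1.0 - fs) * q * (post.total_co2 - cap.total_co2) * c.co2_ml_per_mmol
    o2_gas = lung.lung_o2_uptake(va, vent.fio2, pa_o2, pa_co2, c) if vent.fio2 < 1 else vo2
    residuals = {
        "co2_conservation_ml_min": vco2 - j_lung_check - device.removal_rate,
        "co2_gas_blood_flux_ml_min": j_lung_check - j_lung_blood,
        "o2_conservation_ml_min": vo2 - o2_gas,
        "arterial_mix_mM": arterial.total_co2
        - lung.shunt_mix(cap.total_co2, post.total_co2, fs),
        "venous_content_mM": venous.total_co2 - (arterial.total_co2 + d_tissue_co2),
    }
    worst = max(abs(v) for v in residuals.values())
    if not floor_hit and worst > 1e-6:
        raise blood.ConvergenceError(
            f"steady-state residual {worst:.3g} exceeds tolerance: {residuals}"
        )

    return SteadyStateSolution(
        arterial=arterial, venous=venous, post_ecco2r=post, lung_capillary=cap,
        interstitial=isf, tissue=tissue,
        alveolar=AlveolarState(pa_co2, pa_o2, va),
        cardiac_output=q, co2_production=vco2, o2_uptake=vo2,
        lung_co2_elimination=j_lung, ecco2r_rate=device.removal_rate,
        total_body_co2=sum(masses.values()),
        total_body_co2_pbw_basis=sum(masses_pbw.values()),
        compartment_co2_mmol=MappingProxyType(masses),
        residuals=MappingProxyType(residuals),
        venous_po2_floor_hit=floor_hit,
    )


def total_body_co2(solution: SteadyStateSolution, patient: PatientParameters) -> float:
    """Whole-body CO2 store (mmol): sum of content x volume over compartments.

    Recomputed from the solution's compartment states; equal to
    ``solution.total_body_co2``.
    """
    masses = _compartment_masses(
        patient, solution.arterial, solution.venous,
        solution.interstitial, solution.tissue,
    )
    return sum(masses.values())


@dataclass(frozen=True)
class RequiredEcco2rResult:
    """Outcome of the required-removal-rate search."""

    removal_rate: float            # mL/min
    target_paco2: float            # mmHg
    already_below_target: bool     # True if no device was needed (rate 0)
    solution: SteadyStateSolution

    @property
    def pvco2(self) -> float:
        return self.solution.venous.pco2


def find_required_ecco2r(
    patient: PatientParameters,
    vent: VentilatorSettings,
    target_paco2: float,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
    tol: float = 0.05,
) -> RequiredEcco2rResult:
    """Smallest device CO2 removal rate that brings PaCO2 to the target.

    Arterial PCO2 decreases monotonically with the removal rate, so the root
    is bracketed on [0, production) and refined by Brent's method to within
    ``tol`` mmHg on PaCO2.  If the no-device PaCO2 is already at or below the
    target the result reports a rate of 0 with ``already_below_target`` set.
    """
    if target_paco2 <= 0:
        raise ValueError("target_paco2 must be positive")

    base = solve_steady_state(patient, vent, Ecco2rDevice(0.0), constants)
    if base.paco2 <= target_paco2 + tol:
        return RequiredEcco2rResult(0.0, target_paco2, True, base)

    vco2 = patient.vco2

    def resid(rate):
        sol = solve_steady_state(patient, vent, Ecco2rDevice(rate), constants)
        return sol.paco2 - target_paco2

    # expand the bracket towards the infeasibility bound, stopping before the
    # degenerate regime where nearly all production is removed
    lo, f_lo = 0.0, base.paco2 - target_paco2
    hi = None
    for frac in (0.25, 0.5, 0.75, 0.9, 0.97, 0.995):
        rate = frac * vco2
        try:
            f = resid(rate)
        except (InfeasibleError, ValueError, blood.ConvergenceError) as exc:
            raise InfeasibleError(
                f"PaCO2 target {target_paco2} mmHg not bracketed: removal "
                f"rates up to {lo:.1f} mL/min leave PaCO2 "
                f"{f_lo + target_paco2:.1f} mmHg and the steady state "
                f"degenerates above {rate:.1f} mL/min ({exc})"
            ) from exc
        if f <= 0:
            hi = rate
            break
        lo, f_lo = rate, f
    if hi is None:
        raise InfeasibleError(
            f"PaCO2 target {target_paco2} mmHg unreachable: removing "
            f"{lo:.1f} of {vco2:.1f} mL/min CO2 production leaves PaCO2 "
            f"{f_lo + target_paco2:.1f} mmHg"
        )
    rate = brentq(resid, lo, hi, xtol=1e-6)
    sol = solve_steady_state(patient, vent, Ecco2rDevice(rate), constants)
    if abs(sol.paco2 - target_paco2) > tol:
        raise blood.ConvergenceError(
            f"required-rate search left |PaCO2 - target| = "
            f"{abs(sol.paco2 - target_paco2):.3g} mmHg > {tol}"
        )
    return RequiredEcco2rResult(rate, target_paco2, False, sol)
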