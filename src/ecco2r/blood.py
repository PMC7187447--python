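"""Acid-base and gas equilibrium of blood, interstitial fluid and tissue cells.

Blood is treated as two phases in equilibrium at 37 degC: plasma and
erythrocytes.  Given the CO2 and O2 partial pressures, the base excess and the
hematocrit, the module solves the coupled equilibrium

* Henderson-Hasselbalch bicarbonate equilibria in plasma and erythrocyte water,
* the van Slyke non-bicarbonate buffer line of whole blood (hemoglobin plus
  plasma proteins), offset by the base excess,
* oxygen-linked proton binding by hemoglobin (Haldane effect on bicarbonate),
* carbamate (carbaminohemoglobin) formation on the alpha-amino termini, with
  separate oxy/deoxy mass-action constants (Haldane effect on carbamino CO2),
* a Severinghaus oxyhemoglobin dissociation curve with Kelman-type pH and PCO2
  corrections (Bohr effect),
* a fixed Donnan-type affine coupling between plasma and erythrocyte pH,

for the single unknown plasma pH; every other quantity follows.  Whole-blood
contents are volume-weighted averages of the phase contents.

Interstitial fluid is modelled as a protein-poor plasma ultrafiltrate whose
bicarbonate is a fixed Donnan-type multiple of plasma bicarbonate at the venous
PCO2; tissue-cell (muscle) pH is an affine map of venous plasma pH.  Both maps
are anchored at a reference ventilated-patient operating point and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, ChemistryConstants

__all__ = [
    "BloodState",
    "ExtravascularState",
    "ConvergenceError",
    "o2_saturation",
    "o2_content",
    "solve_blood_equilibrium",
    "pco2_from_total_co2",
    "blood_state_from_contents",
    "interstitial_from_venous",
    "tissue_cell_from_venous",
]

LN10 = np.log(10.0)

_PH_LO, _PH_HI = 5.5, 9.2      # plasma pH bracket for the equilibrium solve


class ConvergenceError(RuntimeError):
    """Raised when an equilibrium or inversion fails to converge."""


@dataclass(frozen=True)
class BloodState:
    """Fully converged acid-base/gas equilibrium of one blood compartment.

    Concentrations are mM; ``hco3_plasma``/``hco3_erythrocyte``/``carbamino``
    are per litre of their phase, ``total_co2``/``total_o2`` per litre of whole
    blood.
    """

    pco2: float
    po2: float
    plasma_ph: float
    erythrocyte_ph: float
    hco3_plasma: float
    hco3_erythrocyte: float
    carbamino: float
    so2: float
    total_co2: float
    total_o2: float
    hematocrit: float
    base_excess: float
    temperature: float = 37.0

    @property
    def plasma_co2_content(self) -> float:
        """Dissolved + bicarbonate CO2 per litre of plasma (mM)."""
        return DEFAULT_CONSTANTS.co2_solubility_plasma * self.pco2 + self.hco3_plasma

    @property
    def erythrocyte_co2_content(self) -> float:
        """Dissolved + bicarbonate + carbamino CO2 per litre of erythrocytes (mM)."""
        return (
            DEFAULT_CONSTANTS.co2_solubility_rbc * self.pco2
            + self.hco3_erythrocyte
            + self.carbamino
        )


@dataclass(frozen=True)
class ExtravascularState:
    """CO2 content and pH of a non-vascular compartment."""

    compartment_label: str        # "interstitial" or "tissue_cell"
    total_co2: float              # mM
    ph: float


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _validate_gas_inputs(pco2: float, po2: float, hematocrit: float) -> None:
    if not np.isfinite(pco2) or pco2 <= 0:
        raise ValueError(f"pco2 must be positive and finite, got {pco2}")
    if not np.isfinite(po2) or po2 < 0:
        raise ValueError(f"po2 must be non-negative and finite, got {po2}")
    if not 0 < hematocrit < 1:
        raise ValueError(f"hematocrit must lie in (0, 1), got {hematocrit}")


# ---------------------------------------------------------------------------
# oxyhemoglobin dissociation
# ---------------------------------------------------------------------------

def o2_saturation(
    po2: float,
    plasma_ph: float = 7.40,
    pco2: float = 40.0,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Fractional hemoglobin O2 saturation at the given PO2, pH and PCO2.

    Severinghaus curve evaluated at a Bohr-corrected virtual PO2:
    ``pv = po2 * 10**(0.40*(pH - 7.40) + 0.06*log10(40/pco2))`` so that
    acidosis and hypercapnia shift the curve rightwards.
    """
    if po2 < 0:
        raise ValueError(f"po2 must be non-negative, got {po2}")
    if pco2 <= 0:
        raise ValueError(f"pco2 must be positive, got {pco2}")
    if po2 == 0.0:
        return 0.0
    c = constants
    shift = (
        c.bohr_ph_coefficient * (plasma_ph - c.reference_ph)
        + c.bohr_pco2_coefficient * np.log10(c.bohr_reference_pco2 / pco2)
    )
    pv = po2 * 10.0 ** shift
    x = pv ** 3 + c.severinghaus_linear * pv
    return x / (x + c.severinghaus_k)


def _saturation_and_derivative(po2, ph, pco2, c):
    """(S, dS/dpH) at fixed po2 and pco2, for the Newton pH iteration."""
    if po2 == 0.0:
        return 0.0, 0.0
    shift = (
        c.bohr_ph_coefficient * (ph - c.reference_ph)
        + c.bohr_pco2_coefficient * np.log10(c.bohr_reference_pco2 / pco2)
    )
    pv = po2 * 10.0 ** shift
    x = pv ** 3 + c.severinghaus_linear * pv
    s = x / (x + c.severinghaus_k)
    dx_dpv = 3.0 * pv ** 2 + c.severinghaus_linear
    ds_dx = c.severinghaus_k / (x + c.severinghaus_k) ** 2
    ds_dph = ds_dx * dx_dpv * pv * LN10 * c.bohr_ph_coefficient
    return s, ds_dph


def o2_content(
    po2: float,
    plasma_ph: float,
    pco2: float,
    hematocrit: float,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Total O2 content of whole blood (mM): Hb-bound plus dissolved."""
    sat = o2_saturation(po2, plasma_ph, pco2, constants)
    return constants.o2_capacity(hematocrit) * sat + constants.o2_solubility_blood * po2


# ---------------------------------------------------------------------------
# carbamate
# ---------------------------------------------------------------------------

def _carbamino(pco2, ph_rbc, so2, c):
    """Carbaminohemoglobin CO2 per litre of erythrocytes (mM).

    Site occupancy from R-NH3+ <-> R-NH2 + H+ (Ka) and
    R-NH2 + CO2 <-> R-NHCOO- + H+ (Kc); oxy and deoxy hemoglobin are
    weighted by the O2 saturation.
    """
    cd = c.co2_solubility_rbc * pco2 * 1e-3        # dissolved CO2 in RBC water, M
    h = 10.0 ** (-ph_rbc)
    z = c.carbamino_site_concentration()

    def occupancy(pka, kc):
        x = kc * cd / h
        return x / (1.0 + h / 10.0 ** (-pka) + x)

    phi_oxy = occupancy(c.carbamate_pka_oxy, c.carbamate_kc_oxy)
    phi_deoxy = occupancy(c.carbamate_pka_deoxy, c.carbamate_kc_deoxy)
    return z * (so2 * phi_oxy + (1.0 - so2) * phi_deoxy)


# ---------------------------------------------------------------------------
# whole-blood equilibrium
# ---------------------------------------------------------------------------

def _balance(ph, pco2, po2, base_excess, hematocrit, c):
    """Buffer-line residual F(pH); strictly increasing in pH."""
    hco3 = c.co2_solubility_plasma * pco2 * 10.0 ** (ph - c.carbonic_acid_pk_plasma)
    sat, _ = _saturation_and_derivative(po2, ph, pco2, c)
    rhs = (
        c.hco3_reference
        + base_excess
        - c.buffer_capacity(hematocrit) * (ph - c.reference_ph)
        + c.haldane_h_per_o2 * c.o2_capacity(hematocrit) * (1.0 - sat)
    )
    return hco3 - rhs


def _solve_plasma_ph(pco2, po2, base_excess, hematocrit, c, tol=1e-12):
    """Newton iteration on the buffer-line residual, brentq fallback."""
    ph = 7.4
    for _ in range(60):
        hco3 = c.co2_solubility_plasma * pco2 * 10.0 ** (ph - c.carbonic_acid_pk_plasma)
        sat, ds_dph = _saturation_and_derivative(po2, ph, pco2, c)
        beta = c.buffer_capacity(hematocrit)
        cap = c.o2_capacity(hematocrit)
        f = hco3 - (
            c.hco3_reference + base_excess - beta * (ph - c.reference_ph)
            + c.haldane_h_per_o2 * cap * (1.0 - sat)
        )
        fprime = LN10 * hco3 + beta + c.haldane_h_per_o2 * cap * ds_dph
        step = f / fprime
        ph -= step
        if not _PH_LO < ph < _PH_HI:
            break
        if abs(step) < tol:
            return ph
    # fall back to bracketed root finding
    flo = _balance(_PH_LO, pco2, po2, base_excess, hematocrit, c)
    fhi = _balance(_PH_HI, pco2, po2, base_excess, hematocrit, c)
    if flo * fhi > 0:
        raise ConvergenceError(
            f"plasma pH not bracketed in [{_PH_LO}, {_PH_HI}] for "
            f"pco2={pco2}, po2={po2}, BE={base_excess}: F={flo:.3g}..{fhi:.3g}"
        )
    return brentq(
        _balance, _PH_LO, _PH_HI,
        args=(pco2, po2, base_excess, hematocrit, c), xtol=1e-12,
    )


def solve_blood_equilibrium(
    pco2: float,
    po2: float,
    base_excess: float = -3.0,
    hematocrit: float = 0.30,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> BloodState:
    """Solve the full plasma + erythrocyte equilibrium at given gas tensions.

    Parameters
    ----------
    pco2, po2 : float
        CO2 and O2 partial pressures, mmHg (``pco2 > 0``, ``po2 >= 0``).
    base_excess : float
        Whole-blood base excess, mEq/L (0 at pH 7.40 / PCO2 40).
    hematocrit : float
        Fractional hematocrit in (0, 1).

    Returns
    -------
    BloodState
        Converged state; Bohr and Haldane couplings are active, so changing
        ``po2`` changes ``total_co2`` at fixed ``pco2`` and vice versa.
    """
    _validate_gas_inputs(pco2, po2, hematocrit)
    c = constants
    ph = _solve_plasma_ph(pco2, po2, base_excess, hematocrit, c)

    sat = o2_saturation(po2, ph, pco2, c)
    ph_rbc = c.rbc_ph_intercept + c.rbc_ph_slope * (ph - c.reference_ph)
    hco3_p = c.co2_solubility_plasma * pco2 * 10.0 ** (ph - c.carbonic_acid_pk_plasma)
    hco3_r = c.co2_solubility_rbc * pco2 * 10.0 ** (ph_rbc - c.carbonic_acid_pk_rbc)
    carb = _carbamino(pco2, ph_rbc, sat, c)

    plasma = c.co2_solubility_plasma * pco2 + hco3_p
    rbc = c.co2_solubility_rbc * pco2 + hco3_r + carb
    total_co2 = (1.0 - hematocrit) * plasma + hematocrit * rbc
    total_o2 = c.o2_capacity(hematocrit) * sat + c.o2_solubility_blood * po2

    residual = _balance(ph, pco2, po2, base_excess, hematocrit, c)
    if abs(residual) > 1e-8:
        raise ConvergenceError(
            f"blood equilibrium residual {residual:.3g} mEq/L at "
            f"pco2={pco2}, po2={po2} exceeds tolerance"
        )

    return BloodState(
        pco2=pco2, po2=po2, plasma_ph=ph, erythrocyte_ph=ph_rbc,
        hco3_plasma=hco3_p, hco3_erythrocyte=hco3_r, carbamino=carb,
        so2=sat, total_co2=total_co2, total_o2=total_o2,
        hematocrit=hematocrit, base_excess=base_excess,
        temperature=c.temperature_c,
    )


# ---------------------------------------------------------------------------
# content -> pressure inversions
# ---------------------------------------------------------------------------

_PCO2_LO, _PCO2_HI = 1e-6, 400.0
_PO2_LO, _PO2_HI = 1e-9, 1500.0


def pco2_from_total_co2(
    total_co2: float,
    po2: float,
    base_excess: float = -3.0,
    hematocrit: float = 0.30,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Invert the CO2 content curve: PCO2 (mmHg) giving the requested content.

    The content curve is strictly increasing in PCO2, so the root is unique;
    it is bracketed on [1e-6, 400] mmHg and refined to ~1e-10 mmHg.
    """

    def resid(p):
        return (
            solve_blood_equilibrium(p, po2, base_excess, hematocrit, constants).total_co2
            - total_co2
        )

    flo, fhi = resid(_PCO2_LO), resid(_PCO2_HI)
    if flo * fhi > 0:
        raise ValueError(
            f"total_co2={total_co2} mM not attainable for PCO2 in "
            f"[{_PCO2_LO}, {_PCO2_HI}] mmHg (content range "
            f"[{flo + total_co2:.3f}, {fhi + total_co2:.3f}] mM)"
        )
    return brentq(resid, _PCO2_LO, _PCO2_HI, xtol=1e-10)


def _po2_from_total_o2(total_o2, pco2, base_excess, hematocrit, c):
    """PO2 giving the requested whole-blood O2 content at fixed PCO2."""

    def resid(p):
        st = solve_blood_equilibrium(pco2, p, base_excess, hematocrit, c)
        return st.total_o2 - total_o2

    flo, fhi = resid(_PO2_LO), resid(_PO2_HI)
    if flo * fhi > 0:
        raise ValueError(
            f"total_o2={total_o2} mM not attainable for PO2 in "
            f"[{_PO2_LO}, {_PO2_HI}] mmHg"
        )
    return brentq(resid, _PO2_LO, _PO2_HI, xtol=1e-10)


def blood_state_from_contents(
    total_co2: float,
    total_o2: float,
    base_excess: float = -3.0,
    hematocrit: float = 0.30,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> BloodState:
    """Recover the full equilibrium state from whole-blood CO2 and O2 contents.

    Nested bracketed root find: the outer loop searches PCO2; for each trial
    PCO2 the inner loop finds the PO2 matching ``total_o2`` (monotone), and the
    outer residual is the CO2 content mismatch.  Deterministic and globally
    convergent on the physiological range.
    """

    def co2_resid(p):
        po2 = _po2_from_total_o2(total_o2, p, base_excess, hematocrit, constants)
        st = solve_blood_equilibrium(p, po2, base_excess, hematocrit, constants)
        return st.total_co2 - total_co2

    lo, hi = 1.0, _PCO2_HI
    flo, fhi = co2_resid(lo), co2_resid(hi)
    if flo > 0:          # very low content: extend bracket downwards
        lo, flo = 1e-4, co2_resid(1e-4)
    if flo * fhi > 0:
        raise ConvergenceError(
            f"contents (CO2 {total_co2} mM, O2 {total_o2} mM) not invertible "
            f"for PCO2 in [{lo}, {hi}] mmHg"
        )
    pco2 = brentq(co2_resid, lo, hi, xtol=1e-9)
    po2 = _po2_from_total_o2(total_o2, pco2, base_excess, hematocrit, constants)
    return solve_blood_equilibrium(pco2, po2, base_excess, hematocrit, constants)


# ---------------------------------------------------------------------------
# extravascular compartments (derived from venous blood only)
# ---------------------------------------------------------------------------

def interstitial_from_venous(
    venous: BloodState,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> ExtravascularState:
    """Interstitial-fluid CO2 content at the venous operating point.

    Protein-poor plasma ultrafiltrate: dissolved CO2 at the venous PCO2 plus
    bicarbonate equal to a fixed Donnan-type multiple of venous plasma
    bicarbonate.  Monotone increasing in venous PCO2.
    """
    c = constants
    hco3 = c.isf_donnan_factor * venous.hco3_plasma
    dissolved = c.co2_solubility_isf * venous.pco2
    ph = c.carbonic_acid_pk_plasma + np.log10(hco3 / dissolved)
    return ExtravascularState("interstitial", total_co2=dissolved + hco3, ph=ph)


def tissue_cell_from_venous(
    venous: BloodState,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> ExtravascularState:
    """Tissue-cell (muscle) CO2 content at the venous operating point.

    Intracellular pH follows venous plasma pH through a fixed affine map
    anchored at the reference operating point; the content is dissolved CO2 at
    the venous PCO2 plus bicarbonate at the intracellular pH.
    """
    c = constants
    ph_i = c.icf_ph_anchor + c.icf_ph_slope * (venous.plasma_ph - c.venous_ph_anchor)
    dissolved = c.co2_solubility_icf * venous.pco2
    hco3 = dissolved * 10.0 ** (ph_i - c.carbonic_acid_pk_icf)
    return ExtravascularState("tissue_cell", total_co2=dissolved + hco3, ph=ph_i)
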