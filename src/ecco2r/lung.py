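"""Gas exchange in the mechanically ventilated lung.

The lung is three elements in parallel/series: gas-exchanging alveoli, series
dead space (ventilated, not perfused) and a pulmonary shunt (perfused, not
ventilated).  Alveolar gas and end-capillary blood are in full equilibrium
(no diffusion resistance), so end-capillary tensions equal alveolar tensions.

Convention: alveolar ventilation is computed at body conditions (BTPS) and gas
fluxes are related to alveolar partial pressures through the water-vapour-
corrected dry pressure, flux = 1000 * VA * P / (PB - PH2O) in mL/min.  The
same volume units are used for the metabolic and extracorporeal rates, and
blood contents are bridged at the molar gas volumes in
:class:`~ecco2r.constants.ChemistryConstants`, keeping every mass balance in
one consistent unit system.  Inspired CO2 is taken as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, ChemistryConstants

__all__ = [
    "VentilatorSettings",
    "AlveolarState",
    "alveolar_ventilation",
    "lung_co2_elimination",
    "lung_o2_uptake",
    "alveolar_po2_for_uptake",
    "shunt_mix",
]


@dataclass(frozen=True)
class VentilatorSettings:
    """Mechanical ventilation prescription.

    frequency            breaths/min
    tidal_volume_per_kg  mL per kg predicted body weight
    dead_space_fraction  VD/VT, series dead space (ARDS average 0.60)
    fio2                 inspired O2 fraction
    """

    frequency: float
    tidal_volume_per_kg: float
    dead_space_fraction: float = 0.60
    fio2: float = 0.60

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.tidal_volume_per_kg <= 0:
            raise ValueError("tidal_volume_per_kg must be positive")
        if not 0 <= self.dead_space_fraction < 1:
            raise ValueError("dead_space_fraction must lie in [0, 1)")
        if not 0 < self.fio2 <= 1:
            raise ValueError("fio2 must lie in (0, 1]")


@dataclass(frozen=True)
class AlveolarState:
    """Alveolar gas tensions (mmHg) and alveolar ventilation (L/min BTPS)."""

    alveolar_pco2: float
    alveolar_po2: float
    alveolar_ventilation: float


def alveolar_ventilation(settings: VentilatorSettings, pbw: float) -> float:
    """Alveolar (dead-space-corrected) ventilation in L/min BTPS."""
    if pbw <= 0:
        raise ValueError("pbw must be positive")
    return (
        settings.frequency
        * settings.tidal_volume_per_kg
        * pbw
        * (1.0 - settings.dead_space_fraction)
        / 1000.0
    )


def lung_co2_elimination(
    va: float,
    alveolar_pco2: float,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """CO2 eliminated through the alveoli (mL/min) at the given alveolar PCO2.

    Linear in both arguments: flux = 1000 * VA * PACO2 / (PB - PH2O), with
    zero inspired CO2.
    """
    if va < 0 or alveolar_pco2 < 0:
        raise ValueError("alveolar ventilation and PCO2 must be non-negative")
    return 1000.0 * va * alveolar_pco2 / constants.dry_pressure


def lung_o2_uptake(
    va: float,
    fio2: float,
    alveolar_po2: float,
    alveolar_pco2: float,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """O2 taken up through the alveoli (mL/min).

    Inspired and expired alveolar flows differ when the exchange ratio is not
    one; nitrogen conservation fixes the inspired flow,
    ``VI = VA * (1 - FAO2 - FACO2) / (1 - FiO2)``, and the uptake is
    ``1000 * (VI*FiO2 - VA*FAO2)`` with fractions of dry gas.  For an exchange
    ratio of one this reduces to the symmetric form
    ``1000 * VA * (PiO2 - PAO2) / (PB - PH2O)``.
    """
    if va < 0:
        raise ValueError("alveolar ventilation must be non-negative")
    if fio2 >= 1.0:
        # no nitrogen balance with pure O2; uptake is not determined by
        # alveolar tensions alone
        raise ValueError("lung_o2_uptake requires fio2 < 1")
    pdry = constants.dry_pressure
    fa_o2 = alveolar_po2 / pdry
    fa_co2 = alveolar_pco2 / pdry
    vi = va * (1.0 - fa_o2 - fa_co2) / (1.0 - fio2)
    return 1000.0 * (vi * fio2 - va * fa_o2)


def alveolar_po2_for_uptake(
    va: float,
    fio2: float,
    alveolar_pco2: float,
    vo2: float,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Alveolar PO2 (mmHg) at which the lung O2 uptake equals ``vo2`` mL/min.

    Closed-form inverse of :func:`lung_o2_uptake` (linear in FAO2); equivalent
    to the alveolar gas equation with the lung exchange-ratio correction.
    """
    if va <= 0:
        raise ValueError("alveolar ventilation must be positive")
    pdry = constants.dry_pressure
    fa_co2 = alveolar_pco2 / pdry
    if fio2 >= 1.0:
        # pure O2: the alveolus holds only O2 and CO2, fixing PAO2 directly
        pao2 = pdry - alveolar_pco2
        if pao2 <= 0:
            raise ValueError("alveolar PCO2 exceeds the available dry pressure")
        return pao2
    a = fio2 / (1.0 - fio2)
    fa_o2 = (a * (1.0 - fa_co2) - vo2 / (1000.0 * va)) / (a + 1.0)
    pao2 = fa_o2 * pdry
    if pao2 <= 0:
        raise ValueError(
            f"no positive alveolar PO2 sustains an O2 uptake of {vo2} mL/min "
            f"at VA={va} L/min, FiO2={fio2}"
        )
    return pao2


def shunt_mix(capillary_content: float, shunted_content: float, shunt_fraction: float) -> float:
    """Flow-weighted arterial content from end-capillary and shunted blood."""
    if not 0 <= shunt_fraction < 1:
        raise ValueError("shunt_fraction must lie in [0, 1)")
    return (1.0 - shunt_fraction) * capillary_content + shunt_fraction * shunted_content
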