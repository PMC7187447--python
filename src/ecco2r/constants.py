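"""Physicochemical constants for blood, interstitial-fluid and tissue CO2/O2 chemistry.

All equilibria are evaluated at 37 degC, barometric pressure 760 mmHg, water
vapour pressure 47 mmHg.  Concentrations are mM (mmol per litre of the phase
they refer to), partial pressures mmHg, buffer capacities mEq/L per pH unit.

The constant set composites standard published formulations:

* CO2 solubility and carbonic-acid pK: Henderson-Hasselbalch in plasma and
  erythrocyte water (erythrocyte values scaled for the lower water fraction).
* Whole-blood non-bicarbonate buffering: van Slyke line,
  beta = 2.3*ctHb[g/dL] + 7.7, zeroed at pH 7.40 / PCO2 40 (base-excess
  convention of Siggaard-Andersen).
* Oxyhemoglobin dissociation: Severinghaus curve with Kelman-type pH/PCO2
  virtual-pressure corrections (Bohr effect).
* Oxygen-linked proton binding (Haldane effect on bicarbonate): 0.5 H+ bound
  per O2 released, mid-range of reported values (0.3-0.7) and set so the
  arteriovenous content/pressure relation matches the reference operating
  point.
* Carbamate: mass action R-NH2 + CO2 <-> R-NHCOO- + H+ on the four alpha-amino
  termini per tetramer, with separate oxy/deoxy constants chosen to reproduce
  textbook carbamino contents (~1 mM in oxygenated whole blood at PCO2 40,
  roughly 50% more when deoxygenated).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields


@dataclass(frozen=True)
class ChemistryConstants:
    """Equilibrium constants and solubilities for blood acid-base chemistry.

    The defaults form a self-consistent 37 degC set; alternative sets can be
    loaded from JSON via :meth:`from_json` and passed to every operation in
    :mod:`ecco2r.blood`.
    """

    temperature_c: float = 37.0
    barometric_pressure: float = 760.0       # mmHg
    water_vapor_pressure: float = 47.0       # mmHg at 37 degC

    # -- gas solubilities (mM/mmHg) ------------------------------------------
    co2_solubility_plasma: float = 0.0307
    co2_solubility_rbc: float = 0.0235       # plasma value scaled by RBC/plasma water
    co2_solubility_isf: float = 0.0325       # near-pure-water interstitial fluid
    co2_solubility_icf: float = 0.0307
    o2_solubility_blood: float = 0.00134     # whole blood, ~0.003 mL/dL/mmHg

    # -- carbonic acid pK ----------------------------------------------------
    carbonic_acid_pk_plasma: float = 6.10
    carbonic_acid_pk_rbc: float = 6.12
    carbonic_acid_pk_icf: float = 6.10

    # -- hemoglobin ----------------------------------------------------------
    mchc_g_per_l: float = 330.0              # mean corpuscular Hb concentration
    hb_tetramer_mw: float = 64458.0          # g/mol
    o2_per_tetramer: float = 4.0
    carbamino_sites_per_tetramer: float = 4.0

    # -- non-bicarbonate buffering (van Slyke) -------------------------------
    buffer_slope_per_hb: float = 2.3         # mEq/L/pH per g/dL Hb
    buffer_intercept: float = 7.7            # mEq/L/pH, plasma proteins + phosphate
    hco3_reference: float = 24.25            # plasma HCO3- at pH 7.40, PCO2 40, BE 0
    reference_ph: float = 7.40

    # -- oxygen-linked proton binding (Haldane) ------------------------------
    haldane_h_per_o2: float = 0.5            # H+ bound per O2 released from Hb

    # -- oxyhemoglobin dissociation (Severinghaus / Kelman) ------------------
    severinghaus_k: float = 23400.0
    severinghaus_linear: float = 150.0
    bohr_ph_coefficient: float = 0.40        # d(log10 P)/d(pH)
    bohr_pco2_coefficient: float = 0.06      # d(log10 P)/d(log10 PCO2)
    bohr_reference_pco2: float = 40.0

    # -- plasma -> erythrocyte pH coupling (Donnan-type, fixed) --------------
    rbc_ph_intercept: float = 7.19           # pH_rbc at plasma pH 7.40
    rbc_ph_slope: float = 0.77

    # -- carbamate mass-action constants -------------------------------------
    # R-NH3+ <-> R-NH2 + H+ (pKa) and R-NH2 + CO2 <-> R-NHCOO- + H+ (Kc, M)
    carbamate_pka_oxy: float = 6.9
    carbamate_pka_deoxy: float = 7.2
    carbamate_kc_oxy: float = 1.30e-5
    carbamate_kc_deoxy: float = 2.86e-5

    # -- interstitial fluid / tissue-cell mapping ----------------------------
    # Interstitial HCO3- = isf_donnan_factor * plasma HCO3- at the venous PCO2
    # (protein-poor ultrafiltrate, fixed Donnan-type factor); intracellular pH
    # mapped affinely from venous plasma pH.  The two anchors are frozen at the
    # reference ventilated-patient operating point (see ecco2r.blood).
    isf_donnan_factor: float = 0.9707
    icf_ph_anchor: float = 6.8087            # intracellular pH at the anchor point
    icf_ph_slope: float = 0.55               # d(pH_icf)/d(venous plasma pH)
    venous_ph_anchor: float = 7.2842         # venous plasma pH at the anchor point

    # -- unit bridges --------------------------------------------------------
    co2_ml_per_mmol: float = 22.26           # mL gas per mmol CO2
    o2_ml_per_mmol: float = 22.392           # mL gas per mmol O2

    # ------------------------------------------------------------------------
    def __post_init__(self) -> None:
        positive = (
            "co2_solubility_plasma", "co2_solubility_rbc", "co2_solubility_isf",
            "co2_solubility_icf", "o2_solubility_blood", "mchc_g_per_l",
            "buffer_slope_per_hb", "buffer_intercept", "co2_ml_per_mmol",
            "o2_ml_per_mmol",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("carbonic_acid_pk_plasma", "carbonic_acid_pk_rbc"):
            pk = getattr(self, name)
            if not 6.0 <= pk <= 6.2:
                raise ValueError(f"{name}={pk} outside the physiological range [6.0, 6.2]")

    # -- derived helpers -----------------------------------------------------
    @property
    def dry_pressure(self) -> float:
        """Barometric minus water-vapour pressure (mmHg)."""
        return self.barometric_pressure - self.water_vapor_pressure

    def hb_g_per_dl(self, hematocrit: float) -> float:
        return hematocrit * self.mchc_g_per_l / 10.0

    def o2_capacity(self, hematocrit: float) -> float:
        """Hemoglobin-bound O2 capacity of whole blood (mM)."""
        return (
            hematocrit * self.mchc_g_per_l / self.hb_tetramer_mw
            * self.o2_per_tetramer * 1000.0
        )

    def carbamino_site_concentration(self) -> float:
        """Carbamate-forming amino groups per litre of erythrocytes (mM)."""
        return self.mchc_g_per_l / self.hb_tetramer_mw * self.carbamino_sites_per_tetramer * 1000.0

    def buffer_capacity(self, hematocrit: float) -> float:
        """Whole-blood non-bicarbonate buffer capacity (mEq/L/pH), van Slyke line."""
        return self.buffer_slope_per_hb * self.hb_g_per_dl(hematocrit) + self.buffer_intercept

    # -- serialisation -------------------------------------------------------
    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ChemistryConstants":
        """Load a constant set from a JSON string or file path."""
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown chemistry constants: {sorted(unknown)}")
        return cls(**data)


#: Default 37 degC constant set used throughout the package.
DEFAULT_CONSTANTS = ChemistryConstants()
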