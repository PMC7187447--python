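"""Calibrate the model and solve the baseline whole-body steady state.

The shunt fraction and respiratory quotient are recovered from the
population-average blood gases (PaCO2 46 mmHg, PaO2/FiO2 161 at FiO2 0.6),
then the six-compartment steady state is solved at the average prescription
(f 20.8/min, VT 7.6 mL/kg PBW) without extracorporeal support.  The printed
stores show where the body keeps its CO2: mostly interstitial fluid and
tissue, almost none in arterial blood.
"""

from ecco2r import VentilatorSettings, calibrated_patient, solve_steady_state

patient, targets, (fs, rq) = calibrated_patient()
print(f"calibrated shunt fraction {fs:.3f}, respiratory quotient {rq:.3f}")
print(f"VO2 {patient.vo2:.0f} mL/min, VCO2 {patient.vco2:.0f} mL/min, "
      f"cardiac output {patient.cardiac_output:.2f} L/min")

sol = solve_steady_state(patient, VentilatorSettings(frequency=20.8, tidal_volume_per_kg=7.6))
print(f"\nbaseline steady state (VT 7.6 mL/kg PBW, f 20.8/min, no device):")
print(f"  alveolar   PCO2 {sol.alveolar.alveolar_pco2:6.1f}  PO2 {sol.alveolar.alveolar_po2:6.1f} mmHg")
print(f"  arterial   PCO2 {sol.paco2:6.1f}  PO2 {sol.arterial.po2:6.1f} mmHg   pH {sol.arterial.plasma_ph:.2f}")
print(f"  venous     PCO2 {sol.pvco2:6.1f}  PO2 {sol.venous.po2:6.1f} mmHg   pH {sol.venous.plasma_ph:.2f}")
print(f"  contents: arterial {sol.arterial.total_co2:.1f} mM, venous {sol.venous.total_co2:.1f} mM, "
      f"interstitial {sol.interstitial.total_co2:.1f} mM, tissue {sol.tissue.total_co2:.1f} mM")
print(f"  whole-body CO2 store {sol.total_body_co2:.0f} mmol "
      f"({sol.total_body_co2_pbw_basis:.0f} mmol on the PBW-only volume basis)")
for name, mmol in sol.compartment_co2_mmol.items():
    if mmol > 0:
        print(f"    {name:<13s} {mmol:6.0f} mmol")
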