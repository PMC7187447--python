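"""Solve the full acid-base equilibrium of a blood sample.

Given PCO2, PO2, base excess and hematocrit, the chemistry model returns
plasma and erythrocyte pH, bicarbonate in both phases, carbaminohemoglobin,
O2 saturation and whole-blood CO2/O2 contents.  The second solve shows the
Haldane effect: deoxygenated blood carries more CO2 at the same PCO2.
"""

from ecco2r import solve_blood_equilibrium

arterial = solve_blood_equilibrium(pco2=46.0, po2=96.6, base_excess=-3.0, hematocrit=0.30)
print("arterial blood at PCO2 46 / PO2 96.6 mmHg, BE -3 mEq/L, Hct 30%:")
print(f"  plasma pH        {arterial.plasma_ph:6.3f}")
print(f"  erythrocyte pH   {arterial.erythrocyte_ph:6.3f}")
print(f"  plasma HCO3-     {arterial.hco3_plasma:6.2f} mM")
print(f"  carbamino CO2    {arterial.carbamino:6.2f} mM (per L RBC)")
print(f"  O2 saturation    {arterial.so2:6.1%}")
print(f"  total CO2        {arterial.total_co2:6.2f} mM   total O2 {arterial.total_o2:5.2f} mM")

deoxygenated = solve_blood_equilibrium(pco2=46.0, po2=30.0, base_excess=-3.0, hematocrit=0.30)
extra = deoxygenated.total_co2 - arterial.total_co2
print(f"\nsame PCO2 at PO2 30 mmHg (SO2 {deoxygenated.so2:.1%}):")
print(f"  total CO2        {deoxygenated.total_co2:6.2f} mM "
      f"(+{extra:.2f} mM -- the Haldane effect)")
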