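"""Extracorporeal CO2 removal rates required at protective tidal volumes.

For each tidal volume and ventilation frequency, the model searches for the
smallest device removal rate that holds PaCO2 at the target: 46 mmHg (mild
permissive hypercapnia) or 40 mmHg (normocapnia).  Rates rise steeply as
tidal volume falls and drop substantially at the higher frequency -- at
6 mL/kg PBW and 26/min essentially no extracorporeal support is needed,
while 3-4 mL/kg PBW requires rates near or beyond 100 mL/min.
"""

from ecco2r import calibrated_patient, run_required_ecco2r_sweep

patient, _, _ = calibrated_patient()
grid = run_required_ecco2r_sweep(
    [6.0, 5.0, 4.0, 3.0], frequencies=[20.8, 26.0],
    target_paco2_list=[46.0, 40.0], patient=patient,
)
cols = ["target_paco2", "frequency", "tidal_volume_per_kg", "required_ecco2r", "pvco2"]
print(grid[cols].round({"required_ecco2r": 0, "pvco2": 1}).to_string(index=False))
print("\nrequired_ecco2r is the device CO2 removal rate in mL/min; pvco2 the "
      "mixed-venous PCO2 (mmHg) of the converged solution.")
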