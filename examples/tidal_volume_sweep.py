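"""Blood gases and CO2 stores as tidal volume is reduced, without a device.

Reducing tidal volume from 7.6 to 3 mL/kg PBW at a fixed frequency of
20.8/min raises PaCO2 from mild permissive hypercapnia (46 mmHg) to severe
hypercapnia above 110 mmHg, drops arterial pH below 7.1, and inflates the
whole-body CO2 store by roughly half.
"""

from ecco2r import calibrated_patient, run_tidal_volume_sweep

patient, _, _ = calibrated_patient()
table = run_tidal_volume_sweep([7.6, 6.0, 5.0, 4.0, 3.0], frequency=20.8, patient=patient)
cols = ["tidal_volume_per_kg", "paco2", "pha", "pvco2", "phv", "total_body_co2"]
print(table[cols].round({"paco2": 1, "pha": 2, "pvco2": 1, "phv": 2, "total_body_co2": 0})
      .to_string(index=False))
print("\nEach row is one converged steady state; PaCO2/PvCO2 in mmHg, "
      "whole-body CO2 in mmol.")
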