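# Methods

This note documents the model, its assumptions, the numerical choices and the
known limitations, in the package's own terms.

## Scope and assumptions

The model predicts **steady states only**: ventilator settings, metabolism
and the extracorporeal device are constant and all compartments are fully
equilibrated. Transient washin/washout of the large CO₂ stores, device
recirculation, ventilation/perfusion heterogeneity beyond the single
alveolar + dead-space + shunt decomposition, hemodynamic feedback of the
extracorporeal circuit, and O₂ transfer across the device are all outside
scope. Temperature is fixed at 37 °C, barometric pressure at 760 mmHg, water
vapour at 47 mmHg.

Six compartments are tracked. Four contain blood and are solved at full
acid-base equilibrium: lung capillary, arterial, mixed venous, post-device
venous (the latter two vascular spaces have zero volume — they are mixing
points, not stores). Interstitial fluid and tissue cells are derived from the
venous state alone and do not enter the transport balances. The device sits
in line on the whole cardiac output between the mixed-venous pool and the
lung/shunt split, so shunted blood is post-device blood; it is characterised
solely by its CO₂ removal rate in mL/min.

## Blood chemistry

One unknown — plasma pH — closes the whole-blood equilibrium at given PCO₂,
PO₂, base excess (BE) and hematocrit (Hct):

* plasma bicarbonate from Henderson–Hasselbalch (α_p = 0.0307 mM/mmHg,
  pK 6.10); erythrocyte bicarbonate likewise (α_r = 0.0235, pK 6.12) at an
  erythrocyte pH coupled to plasma pH by the fixed Donnan-type affine map
  pH_rbc = 7.19 + 0.77·(pH_p − 7.40);
* the van Slyke buffer line: non-bicarbonate buffer capacity
  β = 2.3·ctHb[g/dL] + 7.7 mEq/L/pH, with the zero point (plasma HCO₃⁻
  24.25 mM at pH 7.40, PCO₂ 40) shifted by BE. This anchors BE to its
  clinical definition: at PCO₂ 40 / PO₂ 100 / BE 0 the model returns plasma
  pH 7.398;
* oxygen-linked proton binding: 0.5 H⁺ bound per O₂ released. Reported
  values span roughly 0.3–0.7; the mid-range value also makes the modelled
  arteriovenous content/pressure relation consistent with the reference
  operating point, and is frozen;
* carbamate on the four α-amino termini per hemoglobin tetramer, with
  mass-action constants (pKa 6.9/7.2, K_c 1.30e−5/2.86e−5 M for oxy/deoxy
  hemoglobin) chosen to reproduce textbook carbamino contents (~1 mM per
  litre of oxygenated whole blood at PCO₂ 40, appreciably more when
  deoxygenated);
* O₂ saturation from the Severinghaus curve evaluated at a Bohr-corrected
  virtual PO₂, `po2·10^(0.40(pH−7.4) + 0.06·log10(40/pco2))`, giving P50
  26.9 mmHg at standard conditions.

The residual is strictly increasing in pH, so the scalar solve (damped Newton
with an analytic derivative, bracketed-bisection fallback on [5.5, 9.2]) is
globally convergent; tolerance 1e−12 pH units. Whole-blood contents are
exact volume-weighted averages of the phase contents,
`(1−Hct)·c_plasma + Hct·c_rbc`.

Interstitial fluid is a protein-poor ultrafiltrate: dissolved CO₂ at the
venous PCO₂ (α 0.0325) plus bicarbonate equal to 0.9707 × venous plasma
bicarbonate. Tissue cells (muscle, the assumed single well-perfused store)
hold dissolved CO₂ plus bicarbonate at an intracellular pH mapped affinely
from venous plasma pH (slope 0.55, anchor pH_i 6.8087 at venous pH 7.2842).
The two proportionality anchors were set once so that the calibrated baseline
reproduces reference contents of 27.3 mM (interstitial) and 10.5 mM (tissue),
then frozen; the underlying mapping functions are not otherwise identifiable
from whole-body data.

## Lung and unit conventions

Alveolar ventilation V̇_A = f·V_T·PBW·(1 − V_D/V_T) at body conditions, with
V_D/V_T fixed at 0.60 (the ARDS average) as pure series dead space. Gas
fluxes relate to alveolar tensions as `flux = 1000·V̇_A·P/(P_B − P_H₂O)`
mL/min with zero inspired CO₂; O₂ uptake uses the nitrogen-balance form
(inspired flow `V̇_I = V̇_A(1 − F_AO₂ − F_ACO₂)/(1 − F_iO₂)`), which is the
alveolar gas equation including the inspired/expired volume correction for
exchange ratios ≠ 1. No further volume-standardisation factor is applied to
the gas-side fluxes: the same volume units are used for the metabolic rates
and the device rate, and blood contents in mM are bridged to gas volumes at
22.26 mL/mmol (CO₂) and 22.392 mL/mmol (O₂). This single consistent
convention is required for the calibrated operating point to be internally
coherent — inserting the classical 0.826 BTPS→STPD factor would force the
alveolar PCO₂ above the arterial value, which venous admixture cannot
produce.

## Transport solution

At steady state the lung must eliminate exactly V̇CO₂ − J_d, which fixes
alveolar PCO₂ in closed form; the O₂ balance then fixes alveolar PO₂. End-
capillary blood equilibrates with the alveolus, and the remaining contents
follow linearly: with shunt fraction f_s and per-pass increments
Δ_t = V̇CO₂/(22.26·Q) and Δ_d = J_d/(22.26·Q),

    c_art = c_cap + f_s/(1−f_s)·(Δ_t − Δ_d),
    c_ven = c_art + Δ_t,      c_post = c_ven − Δ_d,

and analogously for O₂ with zero device transfer. Arterial, venous and
post-device tensions are recovered by inverting the content surfaces — a
nested bracketed root find (outer PCO₂, inner PO₂) to 1e−9 mmHg. By
construction the mass balances close to machine precision; the solution
carries a residual report and raises if any residual exceeds 1e−6 (gas/blood
flux consistency, shunt mixing, conservation). A venous PO₂ floor of 1 mmHg
keeps the chemistry solvable in extreme scenarios and is flagged on the
solution when hit. Infeasible inputs (device rate ≥ production, ventilation
unable to sustain the O₂ uptake) raise a dedicated error rather than
returning an unphysical state.

The required-removal-rate search exploits that PaCO₂ decreases monotonically
in J_d: the bracket is expanded stepwise towards the infeasibility bound and
refined by Brent's method, tolerance 0.05 mmHg on PaCO₂; a zero rate with an
explicit flag is returned when the no-device PaCO₂ is already at or below
target.

## Calibration

Shunt fraction and respiratory quotient are the two free parameters, fitted
to two observables of the population-average operating point — PaCO₂
46.0 mmHg and PaO₂ = 161 × 0.6 = 96.6 mmHg — with V̇O₂/kg PBW held at its
reported 4.0 mL/min/kg. A Powell-hybrid 2-D root find (initialised at
(0.15, 0.9), deterministic) does the work, with a nested-bisection fallback
(RQ from the CO₂ target inside, f_s from the O₂ target outside, bounds
f_s ∈ (0, 0.5), RQ ∈ (0.6, 1.1)); both routes reproduce self-generated
targets to better than 1e−6. The calibrated values for the 78-kg reference
patient are f_s = 0.168 and RQ = 0.965, after which (f_s, RQ, V̇O₂) are
frozen for all scenarios.

## Whole-body CO₂ stores

Compartment volumes are fractions of body weight: 0.75% arterial and 6.75%
venous blood, 0% lung-capillary and post-device blood, 12.6% interstitial
fluid and 20% tissue (muscle) cells. The vascular fractions are applied to
predicted body weight (PBW = 0.85 × actual weight); the extravascular
fractions are applied to actual body weight. Muscle water and interstitial
fluid scale with the patient's real mass rather than the height-derived PBW,
and this mixed basis is the one under which the modelled store totals behave
consistently across the whole tidal-volume range. Because the basis is a
genuine modelling choice, every solution also reports the alternative
PBW-only sum (`total_body_co2_pbw_basis`; 553 vs 488 mmol at baseline).
Tissue volume is an underestimate of the true CO₂ store (bone is excluded),
which does not affect the steady-state removal-rate predictions.

## Defaults and problem sizes

The reference patient is 78 kg (PBW 66.3 kg), hematocrit 30%, base excess
−3 mEq/L — intermediate of reported values in ventilated ARDS cohorts — with
the population prescription f 20.8/min, V_T 7.6 mL/kg PBW, FiO₂ 0.6. Scenario
grids use V_T ∈ {7.6, 6, 5, 4, 3} mL/kg PBW, frequencies {20.8, 26}/min and
PaCO₂ targets {46, 40} mmHg. Each steady state costs ~15 ms, a full
required-rate grid a few seconds; the test suite and the acceptance script
each run in well under a minute on one core.

## What the tests do and do not show

There is no synthetic-data generator and no randomness: all inputs are
printed clinical averages, and the test suite checks (i) structural
invariants — conservation to 1e−6 mL/min, Bohr/Haldane coupling directions,
content↔tension round trips to 1e−6, the zero-shunt degenerate-lung oracle,
monotone dose-response of PaCO₂ and of the required removal rate, byte-
identical re-runs — and (ii) agreement with the reference operating points of
the average ARDS patient. Passing tests therefore demonstrate internal
consistency and fidelity to population averages, not per-patient predictive
accuracy: real patients differ in dead-space fraction, shunt, metabolic rate
and acid-base status, and the single-compartment lung cannot represent the
V/Q heterogeneity of severe ARDS. Predictions should be read as population-
scale device requirements, not individual titration advice.

## Known limitations

* Steady-state only; no kinetics of store filling or washout.
* The blood-chemistry constants are a composite of standard published
  formulations, not a single reference data set; absolute contents are
  accurate to a few percent and the baseline calibration absorbs small
  constant differences.
* The device is a pure CO₂ sink; blood-flow dependence, membrane surface and
  recirculation must be layered on from device-specific data.
* Interstitial/tissue chemistry uses frozen one-point anchors; their
  extrapolation far from the reference operating point is uncertain (it
  affects store totals, not blood gases or removal rates).
* High-frequency ventilation and FiO₂ = 1 (no nitrogen balance) are outside
  the validated envelope.
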