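"""Six-compartment steady state: conservation, oracles, monotone responses."""

from dataclasses import replace

import pytest

from ecco2r.lung import VentilatorSettings
from ecco2r.transport import (
    DEFAULT_VOLUME_FRACTIONS,
    Ecco2rDevice,
    InfeasibleError,
    PatientParameters,
    cardiac_output,
    find_required_ecco2r,
    predicted_body_weight,
    solve_steady_state,
    total_body_co2,
)


class TestScaling:
    def test_predicted_body_weight(self):
        assert predicted_body_weight(78.0) == pytest.approx(66.3)
        assert predicted_body_weight(100.0) == pytest.approx(85.0)
        with pytest.raises(ValueError):
            predicted_body_weight(0.0)

    def test_cardiac_output_power_law(self):
        assert cardiac_output(1.0) == pytest.approx(0.251)
        assert cardiac_output(66.3) == pytest.approx(0.251 * 66.3 ** 0.67, rel=1e-12)
        assert cardiac_output(66.3) == pytest.approx(4.17, abs=0.01)
        assert cardiac_output(80.0) > cardiac_output(66.3)

    def test_metabolic_rates_scale_with_pbw(self, calibrated_patient_fx):
        p = calibrated_patient_fx
        half = replace(p, actual_body_weight=39.0, pbw=None)
        assert half.vo2 == pytest.approx(p.vo2 / 2)
        assert half.vco2 == pytest.approx(p.vco2 / 2)


class TestSteadyState:
    def test_baseline_blood_gases(self, baseline_solution):
        """Calibrated baseline reproduces the reference operating point."""
        s = baseline_solution
        assert s.paco2 == pytest.approx(46.0, abs=0.05)
        assert s.arterial.plasma_ph == pytest.approx(7.32, abs=0.02)
        assert s.pvco2 == pytest.approx(55.5, rel=0.05)
        assert s.venous.plasma_ph == pytest.approx(7.28, abs=0.02)

    def test_conservation_residuals(self, baseline_solution):
        assert abs(baseline_solution.residuals["co2_conservation_ml_min"]) < 1e-6
        assert abs(baseline_solution.residuals["o2_conservation_ml_min"]) < 1e-6
        assert abs(baseline_solution.residuals["co2_gas_blood_flux_ml_min"]) < 1e-6

    def test_venous_exceeds_arterial_content(self, baseline_solution):
        assert baseline_solution.venous.total_co2 > baseline_solution.arterial.total_co2

    def test_arterial_between_capillary_and_shunted(self, baseline_solution):
        s = baseline_solution
        lo = min(s.lung_capillary.total_co2, s.post_ecco2r.total_co2)
        hi = max(s.lung_capillary.total_co2, s.post_ecco2r.total_co2)
        assert lo <= s.arterial.total_co2 <= hi

    def test_venous_admixture_directions(self, baseline_solution):
        s = baseline_solution
        assert s.paco2 > s.alveolar.alveolar_pco2
        assert s.arterial.po2 < s.alveolar.alveolar_po2

    def test_zero_shunt_arterial_equals_capillary(self, calibrated_patient_fx, baseline_vent):
        """Degenerate-lung oracle: fs = 0 makes arterial = end-capillary blood."""
        p0 = replace(calibrated_patient_fx, shunt_fraction=0.0)
        s = solve_steady_state(p0, baseline_vent)
        assert s.arterial.pco2 == pytest.approx(s.lung_capillary.pco2, abs=1e-6)
        assert s.arterial.po2 == pytest.approx(s.lung_capillary.po2, abs=1e-6)

    def test_device_lowers_post_device_pco2(self, calibrated_patient_fx, baseline_vent):
        s = solve_steady_state(calibrated_patient_fx, baseline_vent, Ecco2rDevice(80.0))
        assert s.post_ecco2r.total_co2 < s.venous.total_co2
        assert s.post_ecco2r.pco2 < s.venous.pco2
        assert s.post_ecco2r.po2 == pytest.approx(s.venous.po2)

    def test_near_total_removal_limit(self, calibrated_patient_fx, baseline_vent):
        """Removing almost all production drives alveolar PCO2 towards zero."""
        p = calibrated_patient_fx
        s = solve_steady_state(p, baseline_vent, Ecco2rDevice(p.vco2 * 0.999))
        assert s.alveolar.alveolar_pco2 < 0.1
        assert s.lung_co2_elimination == pytest.approx(p.vco2 * 0.001)

    def test_removal_beyond_production_infeasible(self, calibrated_patient_fx, baseline_vent):
        p = calibrated_patient_fx
        with pytest.raises(InfeasibleError):
            solve_steady_state(p, baseline_vent, Ecco2rDevice(p.vco2 * 1.01))


class TestBodyStores:
    def test_total_matches_hand_summation(self, baseline_solution, calibrated_patient_fx):
        """Whole-body store equals an independent sum of content x volume."""
        s, p = baseline_solution, calibrated_patient_fx
        conc = {
            "arterial": s.arterial.total_co2,
            "venous": s.venous.total_co2,
            "lung_capillary": 0.0,
            "post_ecco2r": 0.0,
            "interstitial": s.interstitial.total_co2,
            "tissue": s.tissue.total_co2,
        }
        by_hand = sum(conc[k] * p.compartment_volume(k) for k in DEFAULT_VOLUME_FRACTIONS)
        assert total_body_co2(s, p) == pytest.approx(by_hand, abs=1e-9)
        assert s.total_body_co2 == pytest.approx(by_hand, abs=1e-9)

    def test_zero_volumes_zero_store(self, baseline_solution):
        empty = PatientParameters(
            78.0, volume_fractions={k: 0.0 for k in DEFAULT_VOLUME_FRACTIONS}
        )
        assert total_body_co2(baseline_solution, empty) == 0.0

    def test_stores_grow_as_tidal_volume_falls(self, calibrated_patient_fx):
        totals = [
            solve_steady_state(calibrated_patient_fx, VentilatorSettings(20.8, vt)).total_body_co2
            for vt in (7.6, 5.0, 3.0)
        ]
        assert totals[0] < totals[1] < totals[2]


class TestMonotonicity:
    def test_paco2_decreases_with_tidal_volume_and_frequency(self, calibrated_patient_fx):
        p = calibrated_patient_fx
        by_vt = [solve_steady_state(p, VentilatorSettings(20.8, vt)).paco2
                 for vt in (3.0, 4.0, 6.0, 7.6)]
        assert by_vt == sorted(by_vt, reverse=True)
        low_f = solve_steady_state(p, VentilatorSettings(20.8, 6.0)).paco2
        high_f = solve_steady_state(p, VentilatorSettings(26.0, 6.0)).paco2
        assert high_f < low_f


class TestRequiredRemovalRate:
    def test_baseline_needs_no_device(self, calibrated_patient_fx, baseline_vent):
        res = find_required_ecco2r(calibrated_patient_fx, baseline_vent, 46.0)
        assert res.removal_rate == 0.0
        assert res.already_below_target

    def test_hits_target_within_tolerance(self, calibrated_patient_fx):
        res = find_required_ecco2r(calibrated_patient_fx, VentilatorSettings(26.0, 4.0), 46.0)
        assert not res.already_below_target
        assert res.solution.paco2 == pytest.approx(46.0, abs=0.05)

    def test_rate_monotone_in_vt_frequency_and_target(self, calibrated_patient_fx):
        p = calibrated_patient_fx
        rate = lambda f, vt, tgt: find_required_ecco2r(
            p, VentilatorSettings(f, vt), tgt
        ).removal_rate
        assert rate(20.8, 4.0, 46.0) > rate(20.8, 5.0, 46.0)   # lower VT needs more
        assert rate(26.0, 4.0, 46.0) < rate(20.8, 4.0, 46.0)   # higher f needs less
        assert rate(20.8, 5.0, 40.0) > rate(20.8, 5.0, 46.0)   # stricter target needs more

    def test_unreachable_target_raises(self, calibrated_patient_fx, baseline_vent):
        with pytest.raises(InfeasibleError):
            find_required_ecco2r(calibrated_patient_fx, baseline_vent, 0.05)
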