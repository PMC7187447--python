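"""Blood acid-base/gas equilibrium: anchors, couplings, inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecco2r.blood import (
    blood_state_from_contents,
    interstitial_from_venous,
    o2_saturation,
    pco2_from_total_co2,
    solve_blood_equilibrium,
    tissue_cell_from_venous,
)
from ecco2r.constants import DEFAULT_CONSTANTS, ChemistryConstants

HCT, BE = 0.30, -3.0


class TestEquilibriumAnchors:
    def test_arterial_operating_point(self):
        """PCO2 46 / PO2 96.6 at BE -3, Hct 0.30 gives pH ~7.32, ~21.8 mM CO2."""
        st_ = solve_blood_equilibrium(46.0, 96.6, BE, HCT)
        assert st_.plasma_ph == pytest.approx(7.32, abs=0.01)
        assert st_.total_co2 == pytest.approx(21.8, abs=0.3)

    def test_base_excess_zero_point(self):
        """BE 0 at PCO2 40 / PO2 100 anchors plasma pH to 7.40."""
        st_ = solve_blood_equilibrium(40.0, 100.0, 0.0, HCT)
        assert st_.plasma_ph == pytest.approx(7.40, abs=0.01)

    def test_vanishing_co2_empties_the_stores(self):
        st_ = solve_blood_equilibrium(1e-6, 96.6, BE, HCT)
        assert st_.hco3_plasma < 1e-4
        assert st_.total_co2 < 1e-3

    def test_phase_weighting_is_exact(self):
        st_ = solve_blood_equilibrium(55.0, 40.0, BE, HCT)
        weighted = (1 - HCT) * st_.plasma_co2_content + HCT * st_.erythrocyte_co2_content
        assert st_.total_co2 == pytest.approx(weighted, abs=1e-12)

    @pytest.mark.parametrize("pco2,po2,hct", [(-1, 90, 0.3), (40, -5, 0.3),
                                              (40, 90, 0.0), (40, 90, 1.0)])
    def test_input_validation(self, pco2, po2, hct):
        with pytest.raises(ValueError):
            solve_blood_equilibrium(pco2, po2, BE, hct)


class TestOxygenSaturation:
    def test_asymptotes(self):
        assert o2_saturation(0.0) == 0.0
        assert o2_saturation(600.0, 7.4, 40.0) > 0.995

    def test_half_saturation_pressure(self):
        """P50 at pH 7.4 / PCO2 40 lies in the physiological 24-29 mmHg band."""
        from scipy.optimize import brentq
        p50 = brentq(lambda p: o2_saturation(p, 7.4, 40.0) - 0.5, 1.0, 200.0)
        assert 24.0 <= p50 <= 29.0

    def test_monotone_in_po2(self):
        po2 = np.linspace(0.0, 600.0, 200)
        sats = [o2_saturation(p, 7.4, 40.0) for p in po2]
        assert np.all(np.diff(sats) >= 0)

    def test_bohr_shift_direction(self):
        """Acidosis raises the PO2 needed for any given saturation."""
        from scipy.optimize import brentq
        p50_acid = brentq(lambda p: o2_saturation(p, 7.2, 40.0) - 0.5, 1.0, 200.0)
        p50_norm = brentq(lambda p: o2_saturation(p, 7.4, 40.0) - 0.5, 1.0, 200.0)
        assert p50_acid > p50_norm
        # and via hypercapnia
        p50_hyper = brentq(lambda p: o2_saturation(p, 7.4, 80.0) - 0.5, 1.0, 200.0)
        assert p50_hyper > p50_norm


class TestBohrHaldaneCoupling:
    def test_haldane_deoxygenation_raises_co2_content(self):
        """At fixed PCO2, deoxygenated blood carries strictly more CO2."""
        deoxy = solve_blood_equilibrium(40.0, 1e-9, BE, HCT)
        oxy = solve_blood_equilibrium(40.0, 600.0, BE, HCT)
        assert deoxy.total_co2 > oxy.total_co2 + 0.5

    def test_po2_changes_co2_content_at_fixed_pco2(self):
        lo = solve_blood_equilibrium(46.0, 40.0, BE, HCT)
        hi = solve_blood_equilibrium(46.0, 200.0, BE, HCT)
        assert lo.total_co2 > hi.total_co2

    def test_pco2_changes_o2_content_at_fixed_po2(self):
        """Bohr: hypercapnia lowers saturation, hence O2 content."""
        lo = solve_blood_equilibrium(30.0, 50.0, BE, HCT)
        hi = solve_blood_equilibrium(70.0, 50.0, BE, HCT)
        assert hi.total_o2 < lo.total_o2


class TestContentCurve:
    def test_strictly_increasing_and_concave_trending(self):
        pco2 = np.linspace(10.0, 150.0, 60)
        c = np.array([solve_blood_equilibrium(p, 96.6, BE, HCT).total_co2 for p in pco2])
        slopes = np.diff(c) / np.diff(pco2)
        assert np.all(np.diff(c) > 0)
        assert slopes[-1] < slopes[0]  # flattening at high PCO2

    def test_round_trip_identity(self):
        for p in (20.0, 46.0, 80.0, 120.0):
            st_ = solve_blood_equilibrium(p, 96.6, BE, HCT)
            back = pco2_from_total_co2(st_.total_co2, 96.6, BE, HCT)
            assert back == pytest.approx(p, abs=1e-6)

    def test_inversion_agrees_with_bisection_oracle(self):
        """pco2_from_total_co2 matches a brute-force bisection to 1e-6 mM."""
        target = 23.0
        lo, hi = 1e-6, 400.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if solve_blood_equilibrium(mid, 96.6, BE, HCT).total_co2 < target:
                lo = mid
            else:
                hi = mid
        oracle = 0.5 * (lo + hi)
        fast = pco2_from_total_co2(target, 96.6, BE, HCT)
        c_or = solve_blood_equilibrium(oracle, 96.6, BE, HCT).total_co2
        c_fast = solve_blood_equilibrium(fast, 96.6, BE, HCT).total_co2
        assert c_fast == pytest.approx(target, abs=1e-6)
        assert c_or == pytest.approx(c_fast, abs=1e-6)

    def test_unreachable_content_names_interval(self):
        with pytest.raises(ValueError, match=r"\[1e-06, 400"):
            pco2_from_total_co2(500.0, 96.6, BE, HCT)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        pco2=st.floats(5.0, 150.0),
        po2=st.floats(20.0, 500.0),
        be=st.floats(-10.0, 10.0),
        hct=st.floats(0.2, 0.5),
    )
    def test_round_trip_property(self, pco2, po2, be, hct):
        st_ = solve_blood_equilibrium(pco2, po2, be, hct)
        back = pco2_from_total_co2(st_.total_co2, po2, be, hct)
        assert back == pytest.approx(pco2, abs=1e-6)

    def test_two_content_inversion(self):
        st_ = solve_blood_equilibrium(55.0, 35.0, BE, HCT)
        rec = blood_state_from_contents(st_.total_co2, st_.total_o2, BE, HCT)
        assert rec.pco2 == pytest.approx(55.0, abs=1e-5)
        assert rec.po2 == pytest.approx(35.0, abs=1e-5)


class TestExtravascularCompartments:
    def _venous(self, pco2=55.95, po2=32.0):
        return solve_blood_equilibrium(pco2, po2, BE, HCT)

    def test_baseline_interstitial_content(self):
        assert interstitial_from_venous(self._venous()).total_co2 == pytest.approx(27.3, abs=0.4)

    def test_baseline_tissue_content(self):
        assert tissue_cell_from_venous(self._venous()).total_co2 == pytest.approx(10.5, abs=0.4)

    def test_tissue_below_interstitial(self):
        v = self._venous()
        assert tissue_cell_from_venous(v).total_co2 < interstitial_from_venous(v).total_co2

    def test_monotone_in_venous_pco2(self):
        lo, hi = self._venous(40.0), self._venous(80.0)
        assert interstitial_from_venous(hi).total_co2 > interstitial_from_venous(lo).total_co2
        assert tissue_cell_from_venous(hi).total_co2 > tissue_cell_from_venous(lo).total_co2

    def test_vanishing_venous_pco2(self):
        v = self._venous(1e-4)
        assert interstitial_from_venous(v).total_co2 < 0.01
        assert tissue_cell_from_venous(v).total_co2 < 0.01


class TestConstants:
    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "constants.json"
        DEFAULT_CONSTANTS.to_json(path)
        loaded = ChemistryConstants.from_json(path)
        assert loaded == DEFAULT_CONSTANTS

    def test_invalid_pk_rejected(self):
        with pytest.raises(ValueError):
            ChemistryConstants(carbonic_acid_pk_plasma=5.0)

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ChemistryConstants.from_json('{"not_a_constant": 1.0}')
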