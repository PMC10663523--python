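"""Membrane-PRE back-calculation: plane integral, oracle, ratios, errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import memstates as ms
from memstates.pre import (
    BuriedReporterWarning,
    PREModelError,
    PREModelParams,
    SpinLabelLayer,
    gamma2_analytic,
    gamma2_discrete,
    intensity_ratio,
    measurement_error,
)

PARAMS = PREModelParams()
CIS_ONLY = SpinLabelLayer(include_trans_leaflet=False)


class TestGamma2Analytic:
    def test_zero_label_density_gives_zero_rate(self):
        layer = SpinLabelLayer(area_density_sigma=0.0)
        assert gamma2_analytic(15.0, layer, PARAMS) == 0.0

    def test_linear_in_density(self):
        g1 = gamma2_analytic(15.0, CIS_ONLY, PARAMS)
        g2 = gamma2_analytic(
            15.0, SpinLabelLayer(area_density_sigma=2 * CIS_ONLY.area_density_sigma,
                                 include_trans_leaflet=False), PARAMS
        )
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_delta_fourth_power_scaling(self):
        # halving the plane separation multiplies the cis term by 16
        z_far, z_near = 22.0, 7.0  # Delta = 30 and 15 with d = 8
        g_far = gamma2_analytic(z_far, CIS_ONLY, PARAMS)
        g_near = gamma2_analytic(z_near, CIS_ONLY, PARAMS)
        assert g_near == pytest.approx(16 * g_far, rel=1e-12)

    def test_trans_leaflet_adds_a_smaller_term(self):
        both = gamma2_analytic(15.0, SpinLabelLayer(), PARAMS)
        cis = gamma2_analytic(15.0, CIS_ONLY, PARAMS)
        assert cis < both < 2 * cis

    def test_reporter_below_label_plane_errors(self):
        with pytest.raises(PREModelError, match="label plane"):
            gamma2_analytic(-8.0, CIS_ONLY, PARAMS)


class TestDiscreteOracle:
    def test_agrees_with_closed_form_at_moderate_separation(self):
        z = 7.0  # Delta = 15 A
        exact = gamma2_analytic(z, CIS_ONLY, PARAMS)
        lattice = gamma2_discrete(z, CIS_ONLY, PARAMS, lattice_spacing=0.5,
                                  cutoff_radius=1500.0)
        assert lattice == pytest.approx(exact, rel=5e-3)

    def test_small_cutoff_truncates_from_below(self):
        z = 7.0
        exact = gamma2_analytic(z, CIS_ONLY, PARAMS)
        truncated = gamma2_discrete(z, CIS_ONLY, PARAMS, 0.5, cutoff_radius=160.0)
        assert truncated < exact

    def test_refinement_monotone_in_cutoff(self):
        z = 12.0
        sums = [
            gamma2_discrete(z, CIS_ONLY, PARAMS, 0.5, cutoff_radius=c)
            for c in (250.0, 500.0, 1000.0, 2000.0)
        ]
        assert all(a <= b for a, b in zip(sums, sums[1:]))


class TestIntensityRatio:
    def test_zero_rate_gives_unity(self):
        assert intensity_ratio(0.0, PARAMS) == 1.0

    def test_large_rate_limit_is_zero(self):
        assert intensity_ratio(1e7, PARAMS) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_midpoint(self):
        # r2 = 20, gamma2 = 20, t = 8 ms -> 0.5 exp(-0.16)
        assert intensity_ratio(20.0, PARAMS) == pytest.approx(0.4261, abs=1e-4)

    def test_negative_rate_rejected(self):
        with pytest.raises(PREModelError):
            intensity_ratio(-1.0, PARAMS)

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_and_bounded(self, g1, g2):
        r1, r2 = intensity_ratio(g1, PARAMS), intensity_ratio(g2, PARAMS)
        assert 0.0 <= r1 <= 1.0
        if g1 < g2:
            assert r1 > r2


class TestMeasurementError:
    def test_zero_ratio_zero_error(self):
        assert measurement_error(0.0, 1000.0, 50.0, 50.0) == 0.0

    def test_unit_ratio_equal_sn(self):
        assert measurement_error(1000.0, 1000.0, 10.0, 10.0) == pytest.approx(
            0.1414213562, abs=1e-9
        )

    def test_half_ratio_mixed_sn(self):
        assert measurement_error(500.0, 1000.0, 10.0, 20.0) == pytest.approx(
            0.0559016994, abs=1e-9
        )

    def test_non_positive_sn_rejected(self):
        with pytest.raises(PREModelError):
            measurement_error(1.0, 1.0, 0.0, 10.0)

    @given(st.floats(0.01, 1.0), st.floats(1, 500), st.floats(1, 500),
           st.floats(1.5, 10))
    @settings(max_examples=50, derandomize=True)
    def test_homogeneous_in_ratio_and_decreasing_in_sn(self, ratio, sn_p, sn_d, k):
        e = measurement_error(ratio * 1000, 1000.0, sn_p, sn_d)
        assert measurement_error(k * ratio * 1000, 1000.0, sn_p, sn_d) == pytest.approx(
            k * e, rel=1e-9
        )
        assert measurement_error(ratio * 1000, 1000.0, k * sn_p, sn_d) < e


class TestPredictProfile:
    def test_far_reporters_have_unit_ratio(self, reference):
        far = reference.transformed(translation=np.array([0.0, 0.0, 100.0]))
        pred = ms.predict_profile(far)
        g_ids = far.reporter_ids("g_domain")
        assert all(pred.ratio[r] > 0.999 for r in g_ids)

    def test_reporter_just_above_label_plane_is_bleached(self):
        table = {"20-CD1": np.array([0.0, 0.0, -7.0]),  # 1 A above the plane at -8
                 "21-CD1": np.array([0.0, 0.0, 30.0]),
                 "22-CD1": np.array([5.0, 0.0, 30.0])}
        roles = {r: "g_domain" for r in table}
        cf = ms.Conformer(id="low", reporter_table=table, reporter_roles=roles)
        pred = ms.predict_profile(cf)
        assert pred.ratio["20-CD1"] < 0.05

    def test_ratios_monotone_in_height(self, reference):
        pred = ms.predict_profile(reference)
        zs = {r: reference.reporter_table[r][2] for r in reference.reporter_ids("g_domain")}
        ordered = sorted(zs, key=zs.get)
        ratios = [pred.ratio[r] for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_invariant_to_lateral_translation(self, reference):
        moved = reference.transformed(translation=np.array([40.0, -15.0, 0.0]))
        a, b = ms.predict_profile(reference), ms.predict_profile(moved)
        for r in a.ratio:
            assert a.ratio[r] == pytest.approx(b.ratio[r], rel=1e-12)

    def test_buried_reporter_warns_and_bleaches(self):
        table = {"20-CD1": np.array([0.0, 0.0, -12.0]),
                 "21-CD1": np.array([0.0, 0.0, 30.0]),
                 "22-CD1": np.array([5.0, 0.0, 30.0])}
        roles = {r: "g_domain" for r in table}
        cf = ms.Conformer(id="buried", reporter_table=table, reporter_roles=roles)
        with pytest.warns(BuriedReporterWarning):
            pred = ms.predict_profile(cf, CIS_ONLY)
        assert pred.ratio["20-CD1"] == pytest.approx(0.0, abs=1e-12)


class TestEnsembleProfile:
    def test_single_member_equals_predict_profile(self, reference):
        single = ms.ensemble_profile([reference], [1.0])
        direct = ms.predict_profile(reference)
        for r in direct.ratio:
            assert single.ratio[r] == pytest.approx(direct.ratio[r], rel=1e-12)

    def test_identical_members_are_idempotent(self, reference):
        pair = ms.ensemble_profile([reference, reference], [0.5, 0.5])
        direct = ms.predict_profile(reference)
        for r in direct.ratio:
            assert pair.ratio[r] == pytest.approx(direct.ratio[r], rel=1e-12)

    def test_fast_exchange_below_intensity_average(self, small_library):
        """Jensen: ratio of the mean rate <= mean of the ratios, per reporter."""
        lib, _ = small_library
        members = lib.conformers[:8]
        w = np.full(8, 1 / 8)
        fast = ms.ensemble_profile(members, w, "fast_exchange")
        inten = ms.ensemble_profile(members, w, "intensity_average")
        for r in fast.ratio:
            assert fast.ratio[r] <= inten.ratio[r] + 1e-12

    def test_bad_weights_rejected(self, reference):
        with pytest.raises(PREModelError):
            ms.ensemble_profile([reference], [0.7])


class TestPREMeasurementTable:
    def _table(self):
        return pd.DataFrame(
            {
                "reporter_id": ["20-CD1", "21-CD1"],
                "I_para": [500.0, 900.0],
                "I_dia": [1000.0, 1000.0],
                "sn_para": [10.0, 50.0],
                "sn_dia": [20.0, 50.0],
            }
        )

    def test_ratio_and_error_computed_on_load(self):
        meas = ms.PREMeasurement(self._table())
        assert meas.ratios[0] == pytest.approx(0.5)
        assert meas.errors[0] == pytest.approx(0.0559016994, abs=1e-9)

    def test_duplicate_reporters_rejected(self):
        tab = self._table()
        tab.loc[1, "reporter_id"] = "20-CD1"
        with pytest.raises(PREModelError, match="duplicate"):
            ms.PREMeasurement(tab)

    def test_nonpositive_intensity_rejected(self):
        tab = self._table()
        tab.loc[0, "I_dia"] = 0.0
        with pytest.raises(PREModelError, match="row 0"):
            ms.PREMeasurement(tab)
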