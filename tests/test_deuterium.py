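"""2H chain order: splitting conversion, smoothing, mean torque, R1Z fits."""

import numpy as np
import pandas as pd
import pytest

import memstates as ms
from memstates.deuterium import (
    CH2,
    CH3,
    DEFAULT_IR_SCHEDULE,
    OrderError,
    OrderProfile,
    RelaxationSeries,
    order_to_splitting,
    splitting_to_order,
)


class TestSplittingToOrder:
    def test_zero_splitting_zero_order(self):
        assert splitting_to_order(0.0, CH2) == 0.0

    def test_hand_inverted_methylene(self):
        # 0.75 * 167 kHz * 0.2 = 25.05 kHz
        assert splitting_to_order(25.05, CH2) == pytest.approx(0.200, abs=1e-12)

    def test_methyl_three_fold_enhancement(self):
        dv = 5.0
        assert splitting_to_order(dv, CH3) == pytest.approx(
            3 * splitting_to_order(dv, CH2), rel=1e-12
        )

    def test_unphysical_order_rejected(self):
        with pytest.raises(OrderError, match="unphysical"):
            splitting_to_order(70.0, CH2)

    @pytest.mark.parametrize("group", [CH2, CH3])
    @pytest.mark.parametrize("s", [0.0, 0.05, 0.125, 0.31, 0.5])
    def test_forward_backward_identity(self, group, s):
        assert splitting_to_order(order_to_splitting(s, group), group) == pytest.approx(
            s, abs=1e-12
        )


class TestSmoothProfile:
    def _truth(self, n=14):
        # plateau then monotone decay toward the terminal methyl
        carbons = np.arange(2, n + 1)
        s = 0.21 * np.minimum(1.0, np.exp(-(carbons - 8) / 4.0))
        return OrderProfile(carbons=carbons, s_cd=s)

    def test_full_monotone_profile_round_trips(self):
        truth = self._truth()
        table = ms.simulate_splittings(truth, noise_khz=0.0)
        out = ms.smooth_profile(table, 14)
        np.testing.assert_allclose(out.s_cd, truth.s_cd, atol=1e-12)

    def test_permuted_input_rows_give_identical_output(self):
        truth = self._truth()
        table = ms.simulate_splittings(truth, noise_khz=0.0)
        perm = np.random.default_rng(0).permutation(len(table.carbons))
        shuffled = ms.SplittingTable(
            table.carbons[perm], table.splittings_khz[perm],
            [table.groups[i] for i in perm],
        )
        a, b = ms.smooth_profile(table, 14), ms.smooth_profile(shuffled, 14)
        np.testing.assert_allclose(a.s_cd, b.s_cd, atol=1e-15)

    def test_masked_positions_interpolated_close_to_truth(self):
        truth = self._truth()
        table = ms.simulate_splittings(truth, noise_khz=0.0, mask=[5, 9, 11])
        out = ms.smooth_profile(table, 14)
        for ci in (5, 9, 11):
            j = np.where(out.carbons == ci)[0][0]
            t = truth.s_cd[np.where(truth.carbons == ci)[0][0]]
            assert abs(out.s_cd[j] - t) < 0.02

    def test_output_always_non_increasing(self):
        truth = self._truth()
        table = ms.simulate_splittings(truth, noise_khz=0.8, seed=4)
        out = ms.smooth_profile(table, 14)
        assert np.all(np.diff(out.s_cd) <= 1e-12)

    def test_chain_shorter_than_table_rejected(self):
        table = ms.simulate_splittings(self._truth(), noise_khz=0.0)
        with pytest.raises(OrderError):
            ms.smooth_profile(table, 5)


class TestChainExtension:
    @pytest.mark.parametrize(
        "s,travel",
        [(0.5, 1.27), (0.125, 0.635), (0.25, 1.00162)],
    )
    def test_mean_torque_closed_form_values(self, s, travel):
        prof = OrderProfile(carbons=np.array([2, 3]), s_cd=np.array([s, s]))
        ext = ms.chain_extension(prof)
        assert ext.travel_A[0] == pytest.approx(travel, abs=1e-5)

    def test_terminal_methyl_sits_at_zero(self):
        prof = OrderProfile(carbons=np.arange(2, 15), s_cd=np.full(13, 0.2))
        ext = ms.chain_extension(prof)
        assert ext.cumulative_A[-1] == 0.0
        assert np.all(np.diff(ext.cumulative_A) <= 0)  # grows toward the carbonyl

    def test_pointwise_larger_order_extends_further(self):
        carbons = np.arange(2, 15)
        lo = OrderProfile(carbons=carbons, s_cd=np.full(13, 0.15))
        hi = OrderProfile(carbons=carbons, s_cd=np.full(13, 0.25))
        e_lo, e_hi = ms.chain_extension(lo), ms.chain_extension(hi)
        assert np.all(e_hi.cumulative_A >= e_lo.cumulative_A - 1e-12)

    def test_sub_eighth_fallback_flagged(self):
        prof = OrderProfile(carbons=np.array([2, 3]), s_cd=np.array([0.3, 0.05]))
        ext = ms.chain_extension(prof)
        assert list(ext.sub_eighth) == [False, True]
        j = list(ext.carbons).index(3)
        assert ext.travel_A[j] == pytest.approx(0.635, abs=1e-12)


class TestInversionRecovery:
    def test_noiseless_recovery_on_printed_schedule(self):
        series = ms.simulate_inversion_recovery(2.0, f=1.0, noise=0.0)
        assert len(series.delays_s) == 11
        fit = ms.fit_inversion_recovery(series)
        assert fit.r1z == pytest.approx(2.0, rel=1e-6)
        assert fit.f == pytest.approx(1.0, rel=1e-6)

    def test_zero_crossing_at_ln2_over_r(self):
        r = 3.0
        series = ms.simulate_inversion_recovery(r, f=1.0, noise=0.0)
        fit = ms.fit_inversion_recovery(series)
        t0 = np.log(2.0) / fit.r1z
        model = fit.i_inf * (1 - 2 * fit.f * np.exp(-fit.r1z * t0))
        assert model == pytest.approx(0.0, abs=1e-9)

    def test_intensity_scale_invariance(self):
        a = ms.simulate_inversion_recovery(1.5, i_inf=100.0, noise=0.0)
        b = ms.simulate_inversion_recovery(1.5, i_inf=1000.0, noise=0.0)
        fa, fb = ms.fit_inversion_recovery(a), ms.fit_inversion_recovery(b)
        assert fa.r1z == pytest.approx(fb.r1z, rel=1e-9)

    def test_noisy_recovery_unbiased(self):
        rates = []
        for seed in range(30):
            series = ms.simulate_inversion_recovery(2.0, noise=0.05, seed=seed)
            rates.append(ms.fit_inversion_recovery(series).r1z)
        assert abs(np.mean(rates) / 2.0 - 1.0) < 0.02

    def test_confidence_interval_brackets_truth_on_clean_data(self):
        fit = ms.fit_inversion_recovery(ms.simulate_inversion_recovery(2.0, noise=0.0))
        lo, hi = fit.r1z_ci95
        assert lo <= 2.0 <= hi

    def test_too_few_points_rejected(self):
        with pytest.raises(OrderError):
            RelaxationSeries(delays_s=[0.01, 0.02, 0.04], intensities=[1, 2, 3])


class TestSquareLaw:
    def test_rows_sorted_by_s_squared_with_squared_values(self):
        prof = OrderProfile(carbons=np.array([2, 3, 4]), s_cd=np.array([0.2, 0.1, 0.15]))
        tab = ms.square_law_table(prof, {2: 30.0, 3: 10.0, 4: 20.0})
        assert list(tab["s_squared"]) == pytest.approx([0.01, 0.0225, 0.04])
        assert list(tab["r1z_s1"]) == [10.0, 20.0, 30.0]

    def test_round_trip_through_csv(self, tmp_path):
        prof = OrderProfile(carbons=np.array([2, 3]), s_cd=np.array([0.2, 0.1]))
        tab = ms.square_law_table(prof, {2: 30.0, 3: 10.0})
        path = tmp_path / "sq.csv"
        tab.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, tab)

    def test_disjoint_carbons_error(self):
        prof = OrderProfile(carbons=np.array([2]), s_cd=np.array([0.2]))
        with pytest.raises(OrderError):
            ms.square_law_table(prof, {9: 1.0})


class TestOrderFromVectors:
    def test_axis_aligned_vectors_give_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        prof = ms.order_from_vectors({2: v})
        assert prof.s_cd[0] == pytest.approx(1.0)
        assert prof.signs[0] == pytest.approx(1.0)

    def test_magic_angle_nulls_the_order(self):
        theta = np.deg2rad(54.7356103)
        v = np.tile([np.sin(theta), 0.0, np.cos(theta)], (10, 1))
        prof = ms.order_from_vectors({2: v})
        assert abs(prof.signs[0]) < 1e-6

    def test_isotropic_sampling_averages_to_zero(self):
        rng = np.random.default_rng(123)
        v = rng.standard_normal((1_000_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        prof = ms.order_from_vectors({2: v})
        assert prof.s_cd[0] < 0.003

    def test_unnormalized_vectors_rejected(self):
        with pytest.raises(OrderError, match="unit"):
            ms.order_from_vectors({2: np.tile([0.0, 0.0, 2.0], (5, 1))})
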