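"""Magnitude, group/phase delay, impulse summaries and noise spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import roiir as rk
from conftest import numerical_group_delay


class TestMagnitudeDb:
    def test_identity_is_zero_db(self, grid):
        curve = rk.magnitude_db(rk.make_filter([1], [1]), grid)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_gain_two_is_six_db(self, grid):
        curve = rk.magnitude_db(rk.make_filter([2], [1]), grid)
        np.testing.assert_allclose(curve.values, 20 * np.log10(2), atol=1e-12)

    def test_roiir_dc_gain_in_db(self, registry):
        curve = rk.magnitude_db(registry["roiir"], np.array([0.0, 0.1]))
        np.testing.assert_allclose(curve.values[0], 20 * np.log10(17 / 41), atol=1e-10)


class TestGroupDelay:
    def test_pure_delay(self, grid):
        curve = rk.group_delay(rk.make_filter([0, 0, 1], [1]), grid)
        np.testing.assert_allclose(curve.values[curve.defined], 2.0, atol=1e-9)

    def test_fir60_linear_phase_constant_thirty(self, registry, grid):
        curve = rk.group_delay(registry["fir60"], grid)
        v = np.real(curve.values[curve.defined])
        np.testing.assert_allclose(v, 30.0, atol=1e-6)

    def test_roiir_two_tap_closed_form_at_dc(self, registry):
        curve = rk.group_delay(registry["roiir"], np.array([0.0, 0.5]))
        # tau(0) = (b1^2 + b0 b1)/(b0 + b1)^2 for a 2-tap FIR
        np.testing.assert_allclose(curve.values[0], 238 / 289, atol=1e-10)

    def test_matches_phase_differentiation_oracle_on_registry(self, registry, grid):
        for name, f in registry.items():
            curve = rk.group_delay(f, grid)
            m = curve.defined.copy()
            m[0] = False  # oracle bracket would leave [0, pi]
            oracle = numerical_group_delay(f, grid.omegas[m])
            np.testing.assert_allclose(
                np.real(curve.values[m]), oracle, atol=1e-6,
                err_msg=f"group delay mismatch for {name}",
            )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 2**31 - 1))
    def test_palindromic_fir_has_constant_group_delay(self, half, seed):
        # A symmetric FIR of order N is linear phase with delay N/2.
        rng = np.random.default_rng(seed)
        head = rng.normal(size=half)
        mid = rng.normal(size=1)
        taps = np.concatenate([head, mid, head[::-1]])
        order = len(taps) - 1
        curve = rk.group_delay(rk.make_filter(taps, [1]), rk.default_grid(128))
        v = np.real(curve.values[curve.defined])
        np.testing.assert_allclose(v, order / 2, atol=1e-6)

    def test_constant_delay_shift_moves_summary_not_swing(self, registry, grid):
        f = registry["roiir"]
        shifted = rk.make_filter((0.0,) + f.b, f.a)
        s0 = rk.group_delay_summary(rk.group_delay(f, grid))
        s1 = rk.group_delay_summary(rk.group_delay(shifted, grid))
        assert s1.mean_gd == pytest.approx(s0.mean_gd + 1, abs=1e-9)
        assert s1.max_gd == pytest.approx(s0.max_gd + 1, abs=1e-9)
        assert s1.min_gd == pytest.approx(s0.min_gd + 1, abs=1e-9)
        assert s1.ptp_swing == pytest.approx(s0.ptp_swing, abs=1e-9)

    def test_roiir_swing_below_sixteen_order_iir(self, registry, grid):
        swing = {
            name: rk.group_delay_summary(rk.group_delay(registry[name], grid)).ptp_swing
            for name in ("roiir", "iir16")
        }
        assert swing["roiir"] < swing["iir16"]


class TestGroupDelaySummary:
    def test_constant_curve(self):
        grid = rk.default_grid(16)
        curve = rk.ResponseCurve(
            grid=grid, values=np.full(16, 3.5), defined=np.ones(16, dtype=bool)
        )
        s = rk.group_delay_summary(curve)
        assert (s.mean_gd, s.max_gd, s.min_gd, s.ptp_swing) == (3.5, 3.5, 3.5, 0.0)

    def test_small_example(self):
        grid = rk.FrequencyGrid(omegas=np.array([0.0, 1.0, 2.0]))
        curve = rk.ResponseCurve(
            grid=grid, values=np.array([1.0, 2.0, 4.0]), defined=np.ones(3, dtype=bool)
        )
        s = rk.group_delay_summary(curve)
        assert s.mean_gd == pytest.approx(7 / 3)
        assert (s.max_gd, s.min_gd, s.ptp_swing) == (4.0, 1.0, 3.0)

    def test_roiir_summary_matches_closed_form(self, registry, grid):
        s = rk.group_delay_summary(rk.group_delay(registry["roiir"], grid))
        assert s.min_gd == pytest.approx(14 / 17, abs=1e-4)
        assert s.max_gd == pytest.approx(154 / 121, abs=1e-4)
        assert s.ptp_swing == pytest.approx(154 / 121 - 14 / 17, abs=2e-4)

    def test_all_undefined_curve_errors(self):
        grid = rk.default_grid(8)
        curve = rk.ResponseCurve(
            grid=grid, values=np.full(8, np.nan), defined=np.zeros(8, dtype=bool)
        )
        with pytest.raises(ValueError):
            rk.group_delay_summary(curve)


class TestPhaseDelay:
    def test_pure_delay_phase_equals_group_delay(self, grid):
        f = rk.make_filter([0, 0, 0, 1], [1])
        pd = rk.phase_delay(f, grid)
        gd = rk.group_delay(f, grid)
        np.testing.assert_allclose(
            pd.values[pd.defined], gd.values[gd.defined], atol=1e-9
        )
        np.testing.assert_allclose(pd.values[pd.defined], 3.0, atol=1e-9)

    def test_zero_phase_filter_has_zero_phase_delay(self, grid):
        pd = rk.phase_delay(rk.make_filter([2.5], [1]), grid)
        np.testing.assert_allclose(pd.values, 0.0, atol=1e-12)

    def test_roiir_at_quarter_band(self, registry):
        pd = rk.phase_delay(registry["roiir"], np.array([0.0, np.pi / 2]))
        expected = -np.arctan2(-14, 3) / (np.pi / 2)
        assert pd.values[1] == pytest.approx(expected, abs=1e-10)
        assert pd.values[1] == pytest.approx(0.86561, abs=1e-5)
        # the omega=0 limit is the DC group delay
        assert pd.values[0] == pytest.approx(14 / 17, abs=1e-10)


class TestPhaseShift:
    @pytest.mark.parametrize("td,p,expected", [(0.25, 1.0, 90.0), (0.0, 1.0, 0.0), (2.0, 2.0, 360.0)])
    def test_formula(self, td, p, expected):
        assert rk.phase_shift_degrees(td, p) == pytest.approx(expected)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            rk.phase_shift_degrees(1.0, 0.0)


class TestImpulseSummary:
    def test_roiir(self, registry):
        s = rk.impulse_summary(registry["roiir"])
        assert s.max_coeff == pytest.approx(14 / 41, abs=1e-12)
        assert s.decayed

    def test_fir60_center_tap(self, registry):
        s = rk.impulse_summary(registry["fir60"])
        assert s.max_coeff == pytest.approx(0.8331, abs=1e-12)

    def test_identity(self):
        s = rk.impulse_summary(rk.make_filter([1], [1]))
        assert (s.max_coeff, s.min_coeff, s.ptp) == (1.0, 0.0, 1.0)

    def test_unstable_filter_flagged_not_raised(self, registry):
        s = rk.impulse_summary(registry["iir16"])
        assert not s.decayed
        assert np.isfinite(s.max_coeff)

    def test_ptp_is_max_minus_min(self, registry):
        for name in ("bpf", "fir60", "roiir"):
            s = rk.impulse_summary(registry[name])
            assert s.ptp == pytest.approx(s.max_coeff - s.min_coeff)


class TestNoisePowerSpectrum:
    def test_allpass_gain_is_flat(self, grid):
        curve = rk.noise_power_spectrum(rk.make_filter([3], [1]), 2.0, grid)
        np.testing.assert_allclose(curve.values, 18.0, atol=1e-9)

    def test_roiir_parseval_total_power(self, registry, grid):
        # Band-mean of sigma^2 |H|^2 equals sigma^2 * sum h^2 = 205/1681.
        curve = rk.noise_power_spectrum(registry["roiir"], 1.0, rk.default_grid(4096))
        assert np.mean(curve.values[curve.defined]) == pytest.approx(205 / 1681, rel=1e-3)

    def test_monte_carlo_agrees_within_three_se(self, registry):
        mc = rk.noise_power_monte_carlo(registry["roiir"], 1.0, n=2**16, seed=0)
        assert abs(mc["variance"] - 205 / 1681) < 3 * mc["variance_se"]

    def test_welch_psd_tracks_analytic_shape(self, registry):
        # Single Welch bins fluctuate ~10%; compare block-averaged bands.
        f = registry["roiir"]
        mc = rk.noise_power_monte_carlo(f, 1.0, n=2**16, seed=0)
        om = mc["omegas"][1:-1]
        psd = mc["psd"][1:-1]
        analytic = np.abs(rk.frequency_response(f, om).values) ** 2
        block = 32
        nblocks = len(om) // block
        emp = psd[: nblocks * block].reshape(nblocks, block).mean(axis=1)
        ana = analytic[: nblocks * block].reshape(nblocks, block).mean(axis=1)
        np.testing.assert_allclose(emp, ana, rtol=0.10)

    def test_negative_variance_rejected(self, registry, grid):
        with pytest.raises(ValueError):
            rk.noise_power_spectrum(registry["roiir"], -1.0, grid)
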