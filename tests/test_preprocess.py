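"""Filter response oracles, normalization, alignment recovery, derivatives."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from pulse2abp.preprocess import (
    GlobalNormParams,
    NormParams,
    PreprocessError,
    align,
    aligned_pair,
    apply_norm,
    bandpass_filter,
    central_difference,
    fit_global_norm,
    invert_norm,
    make_feature_stack,
    zscore,
)
from pulse2abp.synth import SynthConfig, generate_segment

FS = 125.0


def _zero_phase_gain(freq_hz: float) -> float:
    """Magnitude response of the forward-backward order-3 Butterworth."""
    sos = sps.butter(3, [0.5, 8.0], btype="bandpass", fs=FS, output="sos")
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq_hz / FS])
    return float(np.abs(h[0]) ** 2)  # filtfilt squares the magnitude


def _measured_gain(freq_hz: float, duration_s: float = 40.0) -> float:
    t = np.arange(int(duration_s * FS)) / FS
    out = bandpass_filter(np.sin(2 * np.pi * freq_hz * t))
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    return float(np.max(np.abs(out[mid])))


class TestBandpassFilter:
    def test_zero_signal_maps_to_zero(self):
        assert np.allclose(bandpass_filter(np.zeros(1000)), 0.0)

    def test_midband_sine_passes_within_5_percent(self):
        oracle = _zero_phase_gain(2.0)
        measured = _measured_gain(2.0)
        assert measured == pytest.approx(oracle, rel=0.01)
        assert abs(measured - 1.0) <= 0.05

    def test_stopband_sine_attenuated_at_least_20_db(self):
        oracle = _zero_phase_gain(0.1)
        measured = _measured_gain(0.1, duration_s=120.0)
        assert measured <= 0.1
        assert oracle <= 0.1

    def test_passband_filtering_is_nearly_idempotent(self):
        t = np.arange(int(40 * FS)) / FS
        once = bandpass_filter(np.sin(2 * np.pi * 2.0 * t))
        twice = bandpass_filter(once)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amp_once = np.max(np.abs(once[mid]))
        amp_twice = np.max(np.abs(twice[mid]))
        assert abs(amp_twice - amp_once) / amp_once < 0.10

    def test_too_short_signal_raises_length_error(self):
        with pytest.raises(PreprocessError, match="too short"):
            bandpass_filter(np.ones(10))


class TestZscore:
    def test_hand_computed_three_point_example(self):
        out, p = zscore(np.array([1.0, 2.0, 3.0]))
        assert p.mu == pytest.approx(2.0)
        assert p.sigma == pytest.approx(np.sqrt(2.0 / 3.0))
        np.testing.assert_allclose(out, [-1.224744871, 0.0, 1.224744871])

    def test_constant_signal_rejected(self):
        with pytest.raises(PreprocessError, match="constant"):
            zscore(np.full(16, 5.0))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_normalize_invert_round_trip(self, seed):
        x = np.random.default_rng(seed).standard_normal(64) * 3.0 + 1.5
        out, p = zscore(x)
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=0) - 1.0) < 1e-12
        np.testing.assert_allclose(invert_norm(out, p), x, atol=1e-12)


class TestGlobalNorm:
    def test_mean_of_two_parameter_sets(self):
        g = fit_global_norm([NormParams(1, 2), NormParams(3, 4)])
        assert (g.mu_bar, g.sigma_bar) == (2.0, 3.0)

    def test_single_element_is_identity(self):
        g = fit_global_norm([NormParams(0.5, 1.5)])
        assert (g.mu_bar, g.sigma_bar) == (0.5, 1.5)

    def test_recovers_known_means_from_many_draws(self, rng):
        mus = rng.normal(10.0, 2.0, 100)
        sigmas = rng.uniform(1.0, 3.0, 100)
        g = fit_global_norm([NormParams(m, s) for m, s in zip(mus, sigmas)])
        assert g.mu_bar == pytest.approx(float(np.mean(mus)), abs=1e-12)
        assert g.sigma_bar == pytest.approx(float(np.mean(sigmas)), abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(PreprocessError, match="empty"):
            fit_global_norm([])

    def test_global_params_apply_and_invert(self):
        g = GlobalNormParams(mu_bar=100.0, sigma_bar=20.0)
        x = np.array([80.0, 100.0, 140.0])
        np.testing.assert_allclose(apply_norm(x, g), [-1.0, 0.0, 2.0])
        np.testing.assert_allclose(invert_norm(apply_norm(x, g), g), x)


class TestAlign:
    def test_identical_signals_have_zero_lag(self, clean_segment):
        res = align(clean_segment.abp, clean_segment.abp, max_lag=80)
        assert res.delta_t == 0

    def test_recovers_paper_example_lag_of_35_samples(self):
        seg = generate_segment(SynthConfig(seed=3, lag_samples=35))
        res = align(seg.ppg, seg.abp, max_lag=100)
        assert res.delta_t == 35

    def test_score_equals_brute_force_maximum(self):
        seg = generate_segment(SynthConfig(seed=4, lag_samples=10, hr_jitter=0.0))
        ppg, abp = seg.ppg, seg.abp
        res = align(ppg, abp, max_lag=100)
        # independent brute force with explicit python loop
        p = ppg - ppg.mean()
        a = abp - abp.mean()
        best_lag, best_score = None, -np.inf
        for d in range(100):
            s = sum(a[t] * p[t + d] for t in range(len(p) - d))
            if s > best_score:
                best_lag, best_score = d, s
        assert res.delta_t == best_lag == 10
        assert res.score == pytest.approx(best_score, rel=1e-9)

    def test_exhaustive_lag_recovery_over_a_full_pulse_period(self):
        period = round(SynthConfig().pulse_period_samples)
        for lag in range(period):
            seg = generate_segment(
                SynthConfig(seed=3, lag_samples=lag, hr_jitter=0.0)
            )
            res = align(seg.ppg, seg.abp, max_lag=period)
            assert res.delta_t == lag, f"lag {lag} recovered as {res.delta_t}"

    def test_shift_drops_trailing_samples_and_trims_both_channels(self):
        seg = generate_segment(SynthConfig(seed=3, lag_samples=20, hr_jitter=0.0))
        ppg_al, abp_al, res = aligned_pair(seg.ppg, seg.abp, max_lag=80)
        assert res.delta_t == 20
        assert len(ppg_al) == len(abp_al) == len(seg) - 20
        np.testing.assert_array_equal(ppg_al, seg.ppg[20:])
        np.testing.assert_array_equal(abp_al, seg.abp[: len(seg) - 20])

    def test_zero_energy_input_is_flagged(self):
        with pytest.raises(PreprocessError, match="zero-energy"):
            align(np.zeros(100), np.zeros(100), max_lag=10)


class TestCentralDifference:
    def test_linear_ramp_gives_exact_constant_slope(self):
        x = 3.5 * np.arange(50, dtype=float) * 0.008
        d = central_difference(x, h=0.008)
        np.testing.assert_allclose(d, 3.5, atol=1e-10)

    def test_constant_signal_gives_zeros(self):
        assert np.allclose(central_difference(np.full(20, 2.0), 0.008), 0.0)

    def test_sine_derivative_within_taylor_bound(self):
        h = 0.008
        t = np.arange(500) * h
        d = central_difference(np.sin(2 * np.pi * t), h)
        truth = 2 * np.pi * np.cos(2 * np.pi * t)
        bound = (2 * np.pi) ** 3 * h**2 / 6.0
        assert np.max(np.abs(d[1:-1] - truth[1:-1])) <= bound

    def test_operator_is_linear(self, rng):
        x = rng.standard_normal(128)
        y = rng.standard_normal(128)
        lhs = central_difference(2.0 * x - 3.0 * y, 0.008)
        rhs = 2.0 * central_difference(x, 0.008) - 3.0 * central_difference(y, 0.008)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(PreprocessError, match="3 samples"):
            central_difference(np.array([1.0, 2.0]), 0.008)


class TestFeatureStack:
    def test_three_equal_length_channels_with_ppg_first(self, rng):
        x = rng.standard_normal(200)
        stack = make_feature_stack(x, h=1 / FS)
        assert stack.channels.shape == (3, 200)
        np.testing.assert_array_equal(stack.channels[0], x)
        assert stack.step_h == 1 / FS

    def test_second_channel_is_derivative_of_first(self, rng):
        x = rng.standard_normal(100)
        stack = make_feature_stack(x, h=0.008)
        np.testing.assert_array_equal(
            stack.channels[1], central_difference(x, 0.008)
        )
        np.testing.assert_array_equal(
            stack.channels[2], central_difference(stack.channels[1], 0.008)
        )

    def test_sine_acceleration_matches_analytic_second_derivative(self):
        h = 0.008
        t = np.arange(600) * h
        stack = make_feature_stack(np.sin(2 * np.pi * t), h)
        truth = -((2 * np.pi) ** 2) * np.sin(2 * np.pi * t)
        bound = 2 * (2 * np.pi) ** 4 * h**2 / 6.0
        assert np.max(np.abs(stack.channels[2][2:-2] - truth[2:-2])) <= bound

    def test_as_input_is_time_major(self, rng):
        stack = make_feature_stack(rng.standard_normal(50), 0.008)
        assert stack.as_input().shape == (50, 3)
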