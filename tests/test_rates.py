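"""Gaussian-convolved firing rate and windowed response statistics."""

import numpy as np
import pytest
from scipy.special import erf

from joencode import (
    SpikeRaster,
    baseline_rate,
    baseline_sd,
    classify_direction,
    gcfr,
    peak_rate,
    response_metrics,
    single_trial_rate,
    steady_state_rate,
)
from joencode.errors import FitError, WindowError
from joencode.rates import RateEstimate

FS = 10_000.0

#: analytic peak of the truncated (±100 ms), renormalized 30-ms Gaussian
SINGLE_SPIKE_PEAK = (1 / (0.03 * np.sqrt(2 * np.pi))) / erf((0.1 / 0.03) / np.sqrt(2))


def _raster(trials, duration):
    return SpikeRaster([np.asarray(t, float) for t in trials], duration_s=duration)


class TestGCFR:
    def test_single_spike_peak_matches_truncated_gaussian(self):
        r = single_trial_rate(np.array([1.0]), FS, int(2 * FS))
        assert r.max() == pytest.approx(SINGLE_SPIKE_PEAK, rel=1e-4)
        assert np.argmax(r) == int(1.0 * FS)

    def test_empty_trial_rate_is_zero(self):
        est = gcfr(_raster([[]], 2.0), FS)
        assert np.all(est.mean_hz == 0)

    def test_identical_trials_have_zero_sd(self):
        est = gcfr(_raster([[1.0], [1.0]], 2.0), FS)
        assert est.mean_hz.max() == pytest.approx(SINGLE_SPIKE_PEAK, rel=1e-4)
        assert np.all(est.sd_hz == 0)

    def test_integral_equals_spike_count(self, rng):
        spikes = np.sort(rng.uniform(0.5, 9.5, 200))
        r = single_trial_rate(spikes, FS, int(10 * FS))
        assert r.sum() / FS == pytest.approx(200, rel=0.005)

    def test_linearity_merging_rasters(self, rng):
        a = [np.sort(rng.uniform(0.2, 1.8, 20)) for _ in range(2)]
        b = [np.sort(rng.uniform(0.2, 1.8, 20)) for _ in range(3)]
        ra, rb = gcfr(_raster(a, 2.0), FS), gcfr(_raster(b, 2.0), FS)
        merged = gcfr(_raster(a + b, 2.0), FS)
        expect = (2 * ra.mean_hz + 3 * rb.mean_hz) / 5
        assert np.allclose(merged.mean_hz, expect, atol=1e-9)

    def test_kernel_too_short_errors(self):
        with pytest.raises(FitError):
            gcfr(_raster([[0.5]], 1.0), 5.0)


class TestWindows:
    def test_baseline_window_arithmetic(self):
        t = np.arange(int(4 * FS)) / FS
        mean = np.where((t >= 1.0) & (t < 2.0), 50.0, 10.0)
        est = RateEstimate(t, mean, np.zeros_like(mean), FS, 1)
        # window [onset-1.5, onset-0.5] = [1.0, 2.0] for onset 2.5
        assert baseline_rate(est, 2.5) == pytest.approx(50.0, rel=1e-3)

    def test_baseline_needs_pre_stimulus_data(self):
        est = RateEstimate(np.arange(int(FS)) / FS, np.zeros(int(FS)),
                           np.zeros(int(FS)), FS, 1)
        with pytest.raises(WindowError):
            baseline_rate(est, 1.0)

    def test_steady_state_is_seconds_2p5_to_3p5_of_a_4s_hold(self):
        t = np.arange(int(8 * FS)) / FS
        mean = np.where((t >= 4.5) & (t < 5.5), 46.0, 0.0)
        est = RateEstimate(t, mean, np.zeros_like(mean), FS, 1)
        # hold [2, 6]: window is [4.5, 5.5], i.e. hold seconds 2.5-3.5
        assert steady_state_rate(est, (2.0, 6.0)) == pytest.approx(46.0, rel=1e-3)

    def test_hold_too_short_for_steady_state(self):
        est = RateEstimate(np.arange(int(2 * FS)) / FS, np.zeros(int(2 * FS)),
                           np.zeros(int(2 * FS)), FS, 1)
        with pytest.raises(WindowError):
            steady_state_rate(est, (0.0, 1.0))

    def test_peak_confined_to_ramp_window(self):
        t = np.arange(int(4 * FS)) / FS
        mean = t * 10.0  # keeps rising after the ramp ends
        est = RateEstimate(t, mean, np.zeros_like(mean), FS, 1)
        assert peak_rate(est, (1.0, 2.0)) == pytest.approx(20.0, rel=1e-3)

    def test_windowed_stats_robust_to_small_jitter(self, rng):
        spikes = [np.sort(rng.uniform(0.1, 7.9, 300)) for _ in range(5)]
        est = gcfr(_raster(spikes, 8.0), FS)
        jittered = [np.sort(s + rng.normal(0, 1e-3, s.size)) for s in spikes]
        est_j = gcfr(_raster(jittered, 8.0), FS)
        b0, b1 = baseline_rate(est, 3.0), baseline_rate(est_j, 3.0)
        s0 = steady_state_rate(est, (3.0, 7.0))
        s1 = steady_state_rate(est_j, (3.0, 7.0))
        assert abs(b1 - b0) / b0 < 1e-3
        assert abs(s1 - s0) / s0 < 1e-3


class TestDirection:
    def test_ventral_preferring(self):
        assert classify_direction([80.0], [30.0], 40.0, 5.0) == "ventral_preferring"

    def test_dorsal_preferring(self):
        assert classify_direction([30.0], [80.0], 40.0, 5.0) == "dorsal_preferring"

    def test_flat_neuron_ambiguous(self):
        assert classify_direction([41.0], [39.0], 40.0, 5.0) == "ambiguous"

    def test_missing_direction_errors(self):
        with pytest.raises(FitError):
            classify_direction([], [50.0], 40.0, 5.0)

    def test_response_metrics_classifies_from_trace(self, ramp_hold_trace, rng):
        """A rate profile elevated during the ventral ramp only."""
        n = ramp_hold_trace.n_samples
        t = np.arange(n) / FS
        mean = np.full(n, 40.0)
        ramp = ramp_hold_trace.ramps()[0]
        mean[ramp.start:ramp.stop] = 90.0
        mean += rng.normal(0, 1.0, n)
        est = RateEstimate(t, mean, np.zeros(n), FS, 5)
        m = response_metrics(est, ramp_hold_trace)
        assert m.direction_label == "ventral_preferring"
        assert m.baseline_hz == pytest.approx(40.0, abs=1.0)
        assert len(m.steady_states) == 1
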