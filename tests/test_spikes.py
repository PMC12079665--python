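"""Voltage filtering, trial QC and spike detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from joencode import (
    TrialRecording,
    bandpass_voltage,
    build_raster,
    detect_spikes,
    qc_trial,
)
from joencode.errors import FilterDesignError, QCError, RasterError
from joencode.synthetic_data import synthesize_voltage

FS = 10_000.0


def _sine_gain(freq, fs=FS, amp=10.0, dur=4.0):
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    y = bandpass_voltage(x, fs)
    mid = slice(int(1.0 * fs), int(3.0 * fs))
    return np.sqrt(np.mean(y[mid] ** 2)) / np.sqrt(np.mean(x[mid] ** 2))


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass_voltage(np.full(5000, 7.3), FS)
        assert np.max(np.abs(out)) < 1e-6

    def test_slow_drift_attenuated_beyond_40_db(self):
        assert _sine_gain(0.5) < 10 ** (-40 / 20)

    def test_spike_band_gain_near_unity(self):
        assert _sine_gain(300.0) == pytest.approx(1.0, abs=0.01)

    def test_sample_rate_guard(self):
        with pytest.raises(FilterDesignError):
            bandpass_voltage(np.zeros(100), 3000.0)


class TestQC:
    @pytest.mark.parametrize("peak,ok", [(4.9, False), (20.0, True), (5.0, True)])
    def test_five_millivolt_criterion_is_strict(self, peak, ok):
        trace = np.zeros(1000)
        trace[500] = peak
        assert qc_trial(trace)[0] is ok

    def test_empty_trace_errors(self):
        with pytest.raises(QCError):
            qc_trial(np.array([]))


class TestDetect:
    def test_three_spikes_recovered_in_noise(self, rng):
        truth = np.array([0.2, 0.5, 0.8])
        v = synthesize_voltage(truth, 1.0, FS, rng, amp_mv=20.0, noise_sd_mv=0.5)
        det = detect_spikes(bandpass_voltage(v, FS), FS)
        assert len(det) == 3
        assert np.max(np.abs(det - truth)) < 0.5e-3

    def test_flat_trace_gives_empty_list(self):
        assert detect_spikes(np.zeros(1000), FS).size == 0

    def test_refractory_guard_keeps_larger_peak(self):
        x = np.zeros(200)
        x[100] = 10.0
        x[110] = 8.0  # 1 ms later at 10 kHz
        det = detect_spikes(x, FS, refractory_ms=2.0)
        assert np.allclose(det, [100 / FS])

    def test_matches_local_maxima_enumeration_on_noiseless_trace(self, rng):
        """Exhaustive oracle: every strict local maximum above 30% of the
        trace maximum, on a noiseless well-separated spike train."""
        truth = np.sort(rng.uniform(0.05, 0.95, 40))
        truth = truth[np.concatenate([[True], np.diff(truth) > 5e-3])]
        v = synthesize_voltage(truth, 1.0, FS, rng, noise_sd_mv=0.0, resting_mv=0.0)
        thr = 0.3 * v.max()
        oracle = [i for i in range(1, len(v) - 1)
                  if v[i] > thr and v[i] > v[i - 1] and v[i] >= v[i + 1]]
        det = detect_spikes(v, FS)
        assert np.allclose(det, np.array(oracle) / FS)

    @given(st.floats(0.1, 50.0))
    def test_threshold_scales_with_signal(self, k):
        rng = np.random.default_rng(7)
        truth = np.sort(rng.uniform(0.05, 0.95, 20))
        v = synthesize_voltage(truth, 1.0, FS, rng, noise_sd_mv=0.3, resting_mv=0.0)
        base = detect_spikes(v, FS)
        assert np.array_equal(base, detect_spikes(k * v, FS))

    def test_count_invariant_to_offset_and_slow_drift(self, rng):
        truth = np.sort(rng.uniform(0.3, 4.7, 160))
        truth = truth[np.concatenate([[True], np.diff(truth) > 5e-3])][:100]
        assert len(truth) == 100
        v = synthesize_voltage(truth, 5.0, FS, rng, noise_sd_mv=0.5)
        t = np.arange(len(v)) / FS
        drifted = v + 6.0 + 10.0 * np.sin(2 * np.pi * 0.4 * t)
        n0 = len(detect_spikes(bandpass_voltage(v, FS), FS))
        n1 = len(detect_spikes(bandpass_voltage(drifted, FS), FS))
        assert n0 == n1 == 100


class TestRaster:
    def _recs(self, rng, n=5, amp=20.0, stim=None):
        truth = np.sort(rng.uniform(0.3, 1.7, 30))
        t = np.arange(int(2.0 * FS)) / FS
        recs = []
        for i in range(n):
            v = synthesize_voltage(truth, 2.0, FS, rng, amp_mv=amp, noise_sd_mv=0.3)
            recs.append(TrialRecording(t, v, trial_id=f"t{i}", stimulus=stim))
        return truth, recs

    def test_identical_trials_identical_rows(self, rng):
        truth, recs = self._recs(rng)
        for rec in recs:
            rec.voltage_mv = recs[0].voltage_mv
        raster = build_raster(recs)
        assert raster.n_trials == 5
        for row in raster.trials[1:]:
            assert np.array_equal(row, raster.trials[0])

    def test_low_amplitude_trial_rejected(self, rng):
        _, recs = self._recs(rng)
        truth2 = np.sort(rng.uniform(0.3, 1.7, 30))
        small = synthesize_voltage(truth2, 2.0, FS, rng, amp_mv=4.0, noise_sd_mv=0.3)
        recs[2].voltage_mv = small
        raster = build_raster(recs)
        assert raster.n_trials == 4
        assert list(raster.rejected) == ["t2"]

    def test_mixed_stimuli_rejected(self, rng, ramp_hold_trace, stair_trace):
        _, recs = self._recs(rng, n=2, stim=ramp_hold_trace)
        recs[1].stimulus = stair_trace
        with pytest.raises(RasterError):
            build_raster(recs)

    def test_all_rejected_is_error(self, rng):
        # 2-mV templates stay under the 5-mV QC bound even where they overlap
        _, recs = self._recs(rng, n=3, amp=2.0)
        with pytest.raises(RasterError):
            build_raster(recs)
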