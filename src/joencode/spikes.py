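"""Spike extraction from intracellular membrane-voltage recordings.

Raw voltage is bandpass filtered (8th-order Butterworth, 10-2000 Hz,
zero-phase) to strip slow drift, DC offset and high-frequency noise.  Spikes
are the local maxima of the filtered trace above 30% of its within-trial
maximum, with a short refractory guard against double-counting biphasic
waveforms.  Trials whose filtered spike amplitude is below 5 mV are
discarded: such small spikes are indistinguishable from extracellular pickup
of neighbouring axons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FilterDesignError, QCError, RasterError
from .stimulus import StimulusTrace

SPIKE_BAND_HZ = (10.0, 2000.0)
QC_MIN_AMPLITUDE_MV = 5.0
THRESHOLD_FRACTION = 0.30
DEFAULT_REFRACTORY_MS = 2.0


@dataclass
class TrialRecording:
    """One trial's membrane voltage, optionally tied to its stimulus."""

    t: np.ndarray
    voltage_mv: np.ndarray
    trial_id: str = "trial"
    stimulus: StimulusTrace | None = None

    def __post_init__(self):
        if len(self.t) != len(self.voltage_mv):
            raise QCError("t and voltage_mv must have equal length")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class SpikeRaster:
    """Per-trial spike times (s, aligned to stimulus onset)."""

    trials: list
    duration_s: float
    rejected: dict = field(default_factory=dict)
    stimulus: StimulusTrace | None = None

    def __post_init__(self):
        for times in self.trials:
            times = np.asarray(times, float)
            if times.size and (np.any(np.diff(times) <= 0) or times[0] < 0 or times[-1] > self.duration_s):
                raise RasterError("spike times must be strictly increasing within the trace")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def bandpass_voltage(voltage_mv: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Zero-phase 8th-order Butterworth bandpass, 10-2000 Hz.

    Removes DC (output mean ~ 0) and sub-10-Hz drift while keeping the
    spike band untouched.
    """
    if sample_rate_hz <= 2 * SPIKE_BAND_HZ[1]:
        raise FilterDesignError(
            f"sample rate {sample_rate_hz} Hz too low for the {SPIKE_BAND_HZ[1]} Hz band edge"
        )
    voltage_mv = np.asarray(voltage_mv, dtype=float)
    sos = sps.butter(8, SPIKE_BAND_HZ, btype="bandpass", fs=sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, voltage_mv)


def qc_trial(filtered_mv: np.ndarray) -> tuple[bool, str | None]:
    """Accept a filtered trial iff its peak spike amplitude is >= 5 mV.

    The criterion is strict ("lower than 5 mV" rejected), so exactly 5 mV
    is accepted.
    """
    filtered_mv = np.asarray(filtered_mv, dtype=float)
    if filtered_mv.size == 0:
        raise QCError("empty trace")
    peak = float(np.max(filtered_mv))
    if peak < QC_MIN_AMPLITUDE_MV:
        return False, f"peak filtered amplitude {peak:.2f} mV < {QC_MIN_AMPLITUDE_MV} mV"
    return True, None


def detect_spikes(
    filtered_mv: np.ndarray,
    sample_rate_hz: float,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> np.ndarray:
    """Spike times: local maxima above 30% of the trace maximum.

    The threshold scales with the signal, so spike times are invariant to
    multiplying the voltage by any positive constant.  Peaks closer than
    the refractory guard are resolved in favour of the larger one.  A trace
    with no supra-threshold samples yields an empty array.
    """
    filtered_mv = np.asarray(filtered_mv, dtype=float)
    peak = np.max(filtered_mv) if filtered_mv.size else 0.0
    if peak <= 0:
        return np.array([])
    threshold = THRESHOLD_FRACTION * peak
    distance = max(1, int(round(refractory_ms / 1000.0 * sample_rate_hz)))
    idx, _ = sps.find_peaks(filtered_mv, height=threshold, distance=distance)
    return idx / sample_rate_hz


def build_raster(
    recs: list[TrialRecording],
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> SpikeRaster:
    """Filter, QC and detect over a set of trials sharing one stimulus.

    Rejected trials are listed with their reason; zero accepted trials or
    mixed stimuli are errors.
    """
    if not recs:
        raise RasterError("no trials supplied")
    stim = recs[0].stimulus
    for rec in recs[1:]:
        a, b = rec.stimulus, stim
        same = (a is b) or (
            a is not None and b is not None and np.array_equal(a.position_deg, b.position_deg)
        )
        if not same:
            raise RasterError("trials reference different stimuli")
    trials, rejected = [], {}
    fs = recs[0].sample_rate_hz
    for rec in recs:
        filtered = bandpass_voltage(rec.voltage_mv, fs)
        ok, reason = qc_trial(filtered)
        if not ok:
            rejected[rec.trial_id] = reason
            continue
        trials.append(detect_spikes(filtered, fs, refractory_ms))
    if not trials:
        raise RasterError("all trials rejected by QC")
    duration = len(recs[0].voltage_mv) / fs
    return SpikeRaster(trials, duration_s=duration, rejected=rejected, stimulus=stim)


def write_spikes_csv(path, raster: SpikeRaster, trial_ids: list[str] | None = None) -> None:
    """Tidy spike table ``trial_id,spike_time_s``."""
    rows = []
    for i, times in enumerate(raster.trials):
        tid = trial_ids[i] if trial_ids else f"trial{i}"
        rows.extend({"trial_id": tid, "spike_time_s": t} for t in times)
    pd.DataFrame(rows, columns=["trial_id", "spike_time_s"]).to_csv(path, index=False)


def read_spikes_csv(path, duration_s: float) -> SpikeRaster:
    df = pd.read_csv(path, float_precision="round_trip")
    trials = [
        np.sort(g["spike_time_s"].to_numpy(float))
        for _, g in df.groupby("trial_id", sort=True)
    ]
    return SpikeRaster(trials, duration_s=duration_s)
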