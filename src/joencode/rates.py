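"""Gaussian-convolved firing rate (GCFR) and windowed response statistics.

The raster is convolved with a Gaussian kernel of 30 ms standard deviation
truncated to a total support of 200 ms and renormalized to unit area, so the
integral of a single-trial rate equals its spike count and rate estimates
stay unbiased.  Response statistics follow fixed windows relative to the
protocol phases:

* baseline -- mean rate over the 1 s ending 0.5 s before ramp onset,
* peak -- maximum of the trial-averaged rate within the ramp,
* steady state -- mean rate over the 1 s ending 0.5 s before hold end
  (seconds 2.5-3.5 of a 4-s hold).

Direction preference compares mean ramp-phase rates against baseline,
using the temporal SD of the baseline window as the noise scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import FitError, WindowError
from .spikes import SpikeRaster
from .stimulus import RAMP, DORSAL, VENTRAL, PhaseSpan, StimulusTrace

KERNEL_SD_MS = 30.0
KERNEL_WIDTH_MS = 200.0

VENTRAL_PREFERRING = "ventral_preferring"
DORSAL_PREFERRING = "dorsal_preferring"
AMBIGUOUS = "ambiguous"


@dataclass
class RateEstimate:
    """Trial-averaged GCFR with its across-trial dispersion."""

    t: np.ndarray
    mean_hz: np.ndarray
    sd_hz: np.ndarray
    sample_rate_hz: float
    n_trials: int
    kernel_sd_ms: float = KERNEL_SD_MS
    kernel_width_ms: float = KERNEL_WIDTH_MS


def gaussian_kernel(sample_rate_hz: float, sd_ms: float = KERNEL_SD_MS,
                    width_ms: float = KERNEL_WIDTH_MS) -> np.ndarray:
    """Truncated, renormalized Gaussian kernel (sums to the sample rate, so
    convolving per-sample spike counts yields a rate in Hz)."""
    half = int(round(width_ms / 2000.0 * sample_rate_hz))
    if half < 1:
        raise FitError("kernel support shorter than 2 samples at this rate")
    x = np.arange(-half, half + 1) / sample_rate_hz
    g = np.exp(-0.5 * (x / (sd_ms / 1000.0)) ** 2)
    return g / g.sum() * sample_rate_hz


def single_trial_rate(spike_times_s: np.ndarray, sample_rate_hz: float, n_samples: int,
                      kernel: np.ndarray | None = None) -> np.ndarray:
    """GCFR of one spike train (Hz), clamped at zero."""
    if kernel is None:
        kernel = gaussian_kernel(sample_rate_hz)
    counts = np.zeros(n_samples)
    if len(spike_times_s):
        idx = np.clip(np.round(np.asarray(spike_times_s) * sample_rate_hz).astype(int),
                      0, n_samples - 1)
        np.add.at(counts, idx, 1.0)
    rate = sps.fftconvolve(counts, kernel, mode="same")
    return np.maximum(rate, 0.0)


def gcfr(raster: SpikeRaster, sample_rate_hz: float) -> RateEstimate:
    """Pointwise mean and SD (ddof=1) of the per-trial GCFRs.

    GCFR is linear in the raster, so merging rasters averages their rates
    with trial-count weights.
    """
    if raster.n_trials == 0:
        raise FitError("empty raster")
    n = int(round(raster.duration_s * sample_rate_hz))
    kernel = gaussian_kernel(sample_rate_hz)
    acc = np.zeros(n)
    acc2 = np.zeros(n)
    for times in raster.trials:
        r = single_trial_rate(times, sample_rate_hz, n, kernel)
        acc += r
        acc2 += r * r
    m = acc / raster.n_trials
    if raster.n_trials > 1:
        var = (acc2 - raster.n_trials * m**2) / (raster.n_trials - 1)
        sd = np.sqrt(np.maximum(var, 0.0))
    else:
        sd = np.zeros(n)
    t = np.arange(n) / sample_rate_hz
    return RateEstimate(t, np.maximum(m, 0.0), sd, sample_rate_hz, raster.n_trials)


def _window_slice(rate: RateEstimate, start_s: float, end_s: float) -> slice:
    if start_s < -1e-9 or end_s > rate.t[-1] + 1.5 / rate.sample_rate_hz:
        raise WindowError(f"window [{start_s:.3f}, {end_s:.3f}] s outside the trace")
    i0 = int(np.ceil(start_s * rate.sample_rate_hz - 1e-9))
    i1 = int(np.floor(end_s * rate.sample_rate_hz + 1e-9)) + 1
    if i1 <= i0:
        raise WindowError("empty window")
    return slice(max(i0, 0), min(i1, len(rate.t)))


def baseline_rate(rate: RateEstimate, ramp_onset_s: float) -> float:
    """Mean rate over [onset - 1.5 s, onset - 0.5 s]."""
    if ramp_onset_s < 1.5 - 1e-9:
        raise WindowError("need >= 1.5 s of pre-stimulus data for the baseline window")
    return float(np.mean(rate.mean_hz[_window_slice(rate, ramp_onset_s - 1.5, ramp_onset_s - 0.5)]))


def baseline_sd(rate: RateEstimate, ramp_onset_s: float) -> float:
    """Temporal SD of the trial-averaged rate in the baseline window (the
    noise scale used by the direction rule)."""
    if ramp_onset_s < 1.5 - 1e-9:
        raise WindowError("need >= 1.5 s of pre-stimulus data for the baseline window")
    return float(np.std(rate.mean_hz[_window_slice(rate, ramp_onset_s - 1.5, ramp_onset_s - 0.5)]))


def peak_rate(rate: RateEstimate, ramp_window_s: tuple[float, float]) -> float:
    """Maximum of the trial-averaged rate within the ramp window."""
    return float(np.max(rate.mean_hz[_window_slice(rate, *ramp_window_s)]))


def ramp_plateau_rate(rate: RateEstimate, ramp_window_s: tuple[float, float]) -> float:
    """Plateau rate during a constant-velocity ramp.

    For a sustained-velocity response the rate is constant once the kernel
    has risen, so the median over the ramp's steady segment estimates the
    same quantity as the peak but without the positive bias that taking a
    maximum over a noisy window incurs.  The segment starts 100 ms after
    ramp onset (the kernel rise) and stops 60 ms (two kernel SDs) before
    ramp end to avoid the falling edge; ramps too short for that leave the
    full window.
    """
    start, end = ramp_window_s
    lo, hi = start + 0.1, end - 0.06
    if hi - lo < 0.05:
        lo, hi = start, end
    return float(np.median(rate.mean_hz[_window_slice(rate, lo, hi)]))


def steady_state_rate(rate: RateEstimate, hold_window_s: tuple[float, float]) -> float:
    """Mean rate over [hold_end - 1.5 s, hold_end - 0.5 s]."""
    start, end = hold_window_s
    if end - start < 1.5 - 1e-9:
        raise WindowError("hold must last >= 1.5 s for the steady-state window")
    return float(np.mean(rate.mean_hz[_window_slice(rate, end - 1.5, end - 0.5)]))


def classify_direction(
    ventral_ramp_hz,
    dorsal_ramp_hz,
    baseline_hz: float,
    baseline_sd_hz: float,
    k: float = 2.0,
) -> str:
    """Direction preference from mean ramp-phase rates.

    ``ventral_preferring`` if the mean ventral-ramp rate exceeds baseline by
    more than ``k`` baseline SDs while the dorsal-ramp rate does not (and
    symmetrically for ``dorsal_preferring``); anything else is ambiguous.
    """
    ventral = np.asarray(ventral_ramp_hz, float)
    dorsal = np.asarray(dorsal_ramp_hz, float)
    if ventral.size == 0 or dorsal.size == 0:
        raise FitError("both ramp directions are required for classification")
    cut = baseline_hz + k * baseline_sd_hz
    v_up, d_up = ventral.mean() > cut, dorsal.mean() > cut
    if v_up and not d_up:
        return VENTRAL_PREFERRING
    if d_up and not v_up:
        return DORSAL_PREFERRING
    return AMBIGUOUS


@dataclass
class ResponseMetrics:
    """Windowed response statistics for one protocol trace.

    ``peaks`` holds (direction, window_s, peak_hz) per ramp phase and
    ``steady_states`` (window_s, rate_hz) per hold phase.
    """

    baseline_hz: float
    baseline_sd_hz: float
    peaks: list = field(default_factory=list)
    steady_states: list = field(default_factory=list)
    direction_label: str | None = None


def response_metrics(rate: RateEstimate, stim: StimulusTrace, k: float = 2.0) -> ResponseMetrics:
    """Baseline, per-ramp peaks and per-hold steady states for one trace;
    classifies direction when both ramp directions are present."""
    ramps = stim.ramps()
    if not ramps:
        raise WindowError("stimulus has no ramp phase")
    onset = ramps[0].start / stim.sample_rate_hz
    m = ResponseMetrics(baseline_rate(rate, onset), baseline_sd(rate, onset))
    ramp_means = {DORSAL: [], VENTRAL: []}
    for ph in ramps:
        w = stim.phase_window_s(ph)
        m.peaks.append((ph.direction, w, peak_rate(rate, w)))
        ramp_means[ph.direction].append(float(np.mean(rate.mean_hz[_window_slice(rate, *w)])))
    for ph in stim.holds():
        w = stim.phase_window_s(ph)
        if w[1] - w[0] >= 1.5:
            m.steady_states.append((w, steady_state_rate(rate, w)))
    if ramp_means[VENTRAL] and ramp_means[DORSAL]:
        m.direction_label = classify_direction(
            ramp_means[VENTRAL], ramp_means[DORSAL], m.baseline_hz, m.baseline_sd_hz, k
        )
    return m


def ramp_mean_rates(rate: RateEstimate, stim: StimulusTrace) -> dict:
    """Mean trial-averaged rate within each ramp phase, grouped by direction."""
    out = {DORSAL: [], VENTRAL: []}
    for ph in stim.ramps():
        w = stim.phase_window_s(ph)
        out[ph.direction].append(float(np.mean(rate.mean_hz[_window_slice(rate, *w)])))
    return out
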