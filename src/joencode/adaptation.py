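"""Spike-frequency adaptation to constant velocity and constant position.

Adaptation of the trial-averaged firing rate is quantified with two separate
single-exponential fits

    y(t) = a exp(-t / tau) (+ offset)

one over the tail of the ramp (from where the rate first falls to 90% of its
ramp-phase maximum, to ramp end) and one over the hold (from 100 ms after
ramp end to 500 ms before hold end).  tau > 0 is adaptation; tau < 0 an
increasing response.  Ramp-phase fits are screened at r2 >= 0.75, hold-phase
fits at a configurable 0.5 (exploratory) or 0.75.

An additive offset is fitted by default because rates decay towards a
steady state rather than zero; a strict two-parameter mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, WindowError
from .rates import RateEstimate

RAMP_R2_SCREEN = 0.75
HOLD_R2_SCREEN = 0.5
HOLD_START_OFFSET_S = 0.1
HOLD_END_OFFSET_S = 0.5
PEAK_FRACTION = 0.9


@dataclass(frozen=True)
class ExpAdaptationFit:
    """Single-exponential adaptation fit over one window."""

    a_hz: float
    tau_s: float
    offset_hz: float
    r2: float
    phase: str
    window_s: tuple
    accepted: bool
    degenerate: bool = False

    @property
    def adapting(self) -> bool:
        """True for a decaying (adapting) response.

        In the two-coefficient form tau > 0 is adaptation and tau < 0 an
        increasing response.  With an offset, a rise toward saturation fits
        as a negative amplitude with positive tau, so the initial slope
        (-a/tau) is the unambiguous classifier in both modes.
        """
        return (
            np.isfinite(self.tau_s)
            and self.tau_s != 0
            and np.isfinite(self.a_hz)
            and self.a_hz / self.tau_s > 0
        )


def ramp_adaptation_window(rate: RateEstimate, ramp_window_s: tuple) -> tuple | None:
    """Window from the first post-peak fall to 90% of the ramp maximum,
    to ramp end.

    Returns None when the rate never falls to 90% before ramp end (e.g. a
    monotonically rising response) -- the fit is then skipped.  A rate flat
    at its maximum starts the window at the peak.
    """
    fs = rate.sample_rate_hz
    i0 = int(np.ceil(ramp_window_s[0] * fs - 1e-9))
    i1 = min(int(np.floor(ramp_window_s[1] * fs + 1e-9)) + 1, len(rate.mean_hz))
    if i1 <= i0:
        raise WindowError("empty ramp window")
    seg = rate.mean_hz[i0:i1]
    peak_idx = int(np.argmax(seg))
    peak = seg[peak_idx]
    below = np.flatnonzero(seg[peak_idx:] <= PEAK_FRACTION * peak)
    if below.size:
        start_idx = peak_idx + int(below[0])
    elif np.all(seg[peak_idx:] <= peak + 1e-12):
        start_idx = peak_idx  # plateau at the maximum
    else:  # pragma: no cover - argmax guarantees the branch above
        return None
    start_s = (i0 + start_idx) / fs
    if ramp_window_s[1] - start_s <= 2.0 / fs:
        return None
    return (start_s, ramp_window_s[1])


def hold_adaptation_window(hold_window_s: tuple) -> tuple:
    """[hold_start + 100 ms, hold_end - 500 ms]; the hold must exceed 0.6 s."""
    start, end = hold_window_s
    if end - start <= HOLD_START_OFFSET_S + HOLD_END_OFFSET_S:
        raise WindowError("hold too short for the adaptation window (needs > 0.6 s)")
    return (start + HOLD_START_OFFSET_S, end - HOLD_END_OFFSET_S)


def _exp_model(p, t):
    a, k, c = p
    return a * np.exp(-k * t) + c


def fit_exponential(
    rate: RateEstimate,
    window_s: tuple,
    phase: str,
    with_offset: bool = True,
    r2_screen: float | None = None,
) -> ExpAdaptationFit:
    """Least-squares exponential fit of the trial-averaged rate over a window.

    Time is re-zeroed at the window start, so shifting the window's absolute
    position changes only the implied scaling coefficient, never tau.
    Non-convergence yields a fit-failure result with r2 = NaN.
    """
    fs = rate.sample_rate_hz
    i0 = int(np.ceil(window_s[0] * fs - 1e-9))
    i1 = min(int(np.floor(window_s[1] * fs + 1e-9)) + 1, len(rate.mean_hz))
    if i1 - i0 < 20:
        raise FitError("adaptation window must contain >= 20 samples")
    t = (np.arange(i0, i1) - i0) / fs
    y = rate.mean_hz[i0:i1]
    if r2_screen is None:
        r2_screen = RAMP_R2_SCREEN if phase == "ramp" else HOLD_R2_SCREEN

    span = float(np.ptp(y))
    if span < 1e-9:
        return ExpAdaptationFit(0.0, np.inf, float(np.mean(y)), np.nan, phase,
                                window_s, accepted=False, degenerate=True)

    L = t[-1]
    c0 = float(np.mean(y[int(0.9 * len(y)):])) if with_offset else 0.0
    a0 = float(y[0] - c0)
    if abs(a0) < 1e-12:
        a0 = span if y[0] >= y[-1] else -span

    def resid(p):
        if with_offset:
            return _exp_model(p, t) - y
        return p[0] * np.exp(-p[1] * t) - y

    best = None
    for k0 in (3.0 / L, 1.0 / L, 0.3 / L, 0.1 / L, -0.3 / L, -1.0 / L, -3.0 / L):
        p0 = np.array([a0, k0, c0]) if with_offset else np.array([a0, k0])
        try:
            sol = optimize.least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return ExpAdaptationFit(np.nan, np.nan, np.nan, np.nan, phase, window_s,
                                accepted=False)
    if with_offset:
        a, k, c = best.x
    else:
        (a, k), c = best.x, 0.0
    yhat = a * np.exp(-k * t) + c
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - np.sum((y - yhat) ** 2) / ss_tot) if ss_tot > 0 else np.nan
    tau = np.inf if k == 0 else 1.0 / k
    degenerate = abs(a) < 1e-6 * max(abs(c), 1.0) or k == 0
    accepted = bool(np.isfinite(r2) and r2 >= r2_screen and not degenerate)
    return ExpAdaptationFit(float(a), float(tau), float(c), r2, phase, window_s,
                            accepted=accepted, degenerate=degenerate)


@dataclass
class TauVelocityTable:
    """Per-neuron (velocity, tau) pairs from accepted positive-tau ramp fits."""

    velocities_deg_s: np.ndarray
    taus_s: np.ndarray
    spearman_rho: float
    included: bool
    reason: str | None = None


def tau_vs_velocity(fits, velocities_deg_s, min_quantifications: int = 3) -> TauVelocityTable:
    """Pair accepted, adapting (tau > 0) ramp fits with their ramp velocities.

    Neurons with fewer than three accepted quantifications (or none with a
    positive time constant) are excluded, mirroring the population screen
    for the tau-vs-velocity comparison.
    """
    fits = list(fits)
    velocities = np.asarray(velocities_deg_s, float)
    if len(fits) != velocities.size:
        raise FitError("one velocity per fit is required")
    keep = [i for i, f in enumerate(fits) if f.accepted and f.adapting]
    v = velocities[keep]
    taus = np.array([fits[i].tau_s for i in keep])
    if len(keep) < min_quantifications:
        return TauVelocityTable(v, taus, np.nan, included=False,
                                reason=f"only {len(keep)} accepted positive-tau fits")
    rho = float(stats.spearmanr(v, taus).statistic)
    return TauVelocityTable(v, taus, rho, included=True)
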