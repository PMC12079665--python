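"""Position- and velocity-tuning fits.

Position encoding is screened with Spearman's correlation between hold
position and steady-state rate (|rho| > 0.8) and described by an ordinary
least-squares line (r2 >= 0.8 for the encoder flag).

Velocity tuning of the peak ramp rate is modelled as a three-parameter
logistic

    y(v) = a / (1 + exp(-b (v - c)))

with ``a`` the saturation rate (Hz), ``b`` the steepness (s/deg) and ``c``
the half-activation velocity (deg/s), fitted by bounded nonlinear least
squares with multistart initialization.  Linear, power-law and semilog
alternatives from the proprioceptor literature are fitted for comparison;
a power law is flagged as unsupported when the sampled velocity range spans
less than two decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError

POSITION_RHO_THRESHOLD = 0.8
ENCODER_R2_THRESHOLD = 0.8
TWO_DECADES = 100.0


@dataclass(frozen=True)
class LinearPositionFit:
    slope_hz_per_deg: float
    intercept_hz: float
    r2: float
    spearman_rho: float
    n_points: int
    degenerate: bool = False

    @property
    def is_position_encoder(self) -> bool:
        return (
            not self.degenerate
            and abs(self.spearman_rho) > POSITION_RHO_THRESHOLD
            and self.r2 >= ENCODER_R2_THRESHOLD
        )


@dataclass(frozen=True)
class LogisticVelocityFit:
    a_hz: float
    b: float
    c_deg_s: float
    r2: float
    n_points: int
    converged: bool = True
    degenerate: bool = False

    @property
    def is_velocity_encoder(self) -> bool:
        return self.converged and not self.degenerate and self.r2 >= ENCODER_R2_THRESHOLD

    def predict(self, v):
        return logistic(np.asarray(v, float), self.a_hz, self.b, self.c_deg_s)


@dataclass(frozen=True)
class ModelFit:
    name: str
    params: tuple
    r2: float
    note: str | None = None


@dataclass
class VelocityModelComparison:
    fits: dict = field(default_factory=dict)
    best_model: str | None = None
    narrow_range_caveat: bool = False


def logistic(v, a, b, c):
    return a / (1.0 + np.exp(-b * (v - c)))


def _r2(y, yhat) -> float:
    y = np.asarray(y, float)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def fit_position_linear(positions_deg, ss_rates_hz) -> LinearPositionFit:
    """OLS line of steady-state rate on hold position plus Spearman screen."""
    x = np.asarray(positions_deg, float)
    y = np.asarray(ss_rates_hz, float)
    if x.size != y.size or np.unique(x).size < 4:
        raise FitError("need >= 4 distinct hold positions")
    res = stats.linregress(x, y)
    if np.ptp(y) == 0:
        # constant rates: rho undefined, reported as 0 with the degenerate flag
        return LinearPositionFit(0.0, float(y[0]), 0.0, 0.0, x.size, degenerate=True)
    rho = stats.spearmanr(x, y).statistic
    r2 = float(res.rvalue**2)
    return LinearPositionFit(float(res.slope), float(res.intercept), r2, float(rho), x.size)


def _logistic_starts(v, y, rng):
    a0 = max(float(np.max(y)), 1e-6)
    c0 = float(np.median(v))
    iqr = max(float(np.subtract(*np.percentile(v, [75, 25]))), 1e-6)
    b0 = np.clip(4.0 * float(np.ptp(y)) / (a0 * iqr), 0.1, 50.0)
    starts = [(a0, b0, c0)]
    for _ in range(9):
        c_j = c0 * float(rng.uniform(0.3, 3.0))
        b_j = b0 * float(rng.uniform(0.3, 3.0))
        starts.append((a0 * float(rng.uniform(0.8, 1.5)), b_j, c_j))
    return starts


def fit_velocity_logistic(velocities_deg_s, peak_rates_hz, rng=None) -> LogisticVelocityFit:
    """Bounded multistart least squares of the logistic on preferred-direction
    velocity magnitudes.

    Non-convergence yields a fit-failure result (r2 = NaN), not an exception.
    The fit is scale-equivariant: scaling the rates by k scales ``a`` by k
    and leaves ``b`` and ``c`` unchanged.
    """
    v = np.asarray(velocities_deg_s, float)
    y = np.asarray(peak_rates_hz, float)
    if v.size != y.size or np.unique(v).size < 5:
        raise FitError("need >= 5 distinct velocity levels")
    if np.any(v <= 0):
        raise FitError("velocities must be positive magnitudes")
    if np.max(v) / np.min(v) < 10.0:
        raise FitError("velocity levels must span at least one decade")
    if np.ptp(y) == 0:
        return LogisticVelocityFit(float(y[0]), 0.0, float(np.median(v)), np.nan,
                                   v.size, degenerate=True)
    rng = np.random.default_rng(0) if rng is None else rng
    lo = np.array([1e-9, 1e-6, np.min(v) / 10.0])
    hi = np.array([5.0 * max(np.max(y), 1e-6), 100.0, 10.0 * np.max(v)])

    def resid(p):
        return logistic(v, *p) - y

    best = None
    for start in _logistic_starts(v, y, rng):
        p0 = np.clip(start, lo + 1e-12, hi - 1e-12)
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return LogisticVelocityFit(np.nan, np.nan, np.nan, np.nan, v.size, converged=False)
    a, b, c = best.x
    return LogisticVelocityFit(float(a), float(b), float(c),
                               _r2(y, logistic(v, a, b, c)), v.size)


def compare_velocity_models(velocities_deg_s, peak_rates_hz, rng=None) -> VelocityModelComparison:
    """Fit linear, power-law, semilog and logistic models and rank by r2.

    Power and semilog fits are least squares in their transformed spaces
    (log-log and semilog-x) with r2 recomputed on the original scale, for
    comparability with the literature they come from.
    """
    v = np.asarray(velocities_deg_s, float)
    y = np.asarray(peak_rates_hz, float)
    comp = VelocityModelComparison()
    comp.narrow_range_caveat = bool(np.max(v) / np.min(v) < TWO_DECADES)

    res = stats.linregress(v, y)
    comp.fits["linear"] = ModelFit("linear", (float(res.intercept), float(res.slope)),
                                   _r2(y, res.intercept + res.slope * v))

    if np.all(v > 0):
        lres = stats.linregress(np.log(v), y)
        comp.fits["semilog"] = ModelFit(
            "semilog", (float(lres.intercept), float(lres.slope)),
            _r2(y, lres.intercept + lres.slope * np.log(v)))
    else:
        comp.fits["semilog"] = ModelFit("semilog", (), np.nan, note="non-positive velocities")

    if np.all(v > 0) and np.all(y > 0):
        pres = stats.linregress(np.log(v), np.log(y))
        alpha, beta = float(np.exp(pres.intercept)), float(pres.slope)
        comp.fits["power_law"] = ModelFit("power_law", (alpha, beta), _r2(y, alpha * v**beta))
    else:
        comp.fits["power_law"] = ModelFit("power_law", (), np.nan,
                                          note="non-positive velocities or rates")

    lf = fit_velocity_logistic(v, y, rng=rng)
    comp.fits["logistic"] = ModelFit("logistic", (lf.a_hz, lf.b, lf.c_deg_s), lf.r2)

    ranked = [(name, f.r2) for name, f in comp.fits.items() if np.isfinite(f.r2)]
    if ranked:
        comp.best_model = max(ranked, key=lambda nf: nf[1])[0]
    return comp
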