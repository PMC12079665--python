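"""Ramp-and-hold and stair stimulus protocols for the antennal flagellum.

The flagellum is rotated about the pedicel-flagellum joint along the
dorsoventral axis; positive angles are dorsal, negative ventral.  Three
protocols probe the mechanosensory afferents:

* ``variable_position`` -- ramp at a fixed angular velocity to different hold
  positions (decouples position from velocity),
* ``variable_velocity`` -- ramp at different velocities to the same hold
  position,
* ``stair`` -- a staircase of hold levels traversed slowly in both
  directions, probing history dependence.

The actual movement delivered to the joint is read out by a Hall-effect
sensor next to a magnet on the capillary that holds the flagellum; a
voltage-to-displacement calibration plus the lever arm (joint to attachment
annulus) converts sensor voltage to joint angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import (
    CalibrationRangeError,
    FilterDesignError,
    InvalidSpecError,
    WindowError,
)

REST = "rest"
RAMP = "ramp"
HOLD = "hold"
DORSAL = "dorsal"
VENTRAL = "ventral"
NONE = "none"

#: Upper edge (Hz) of the spike bandpass; stimulus sampling must exceed twice this.
SPIKE_BAND_UPPER_HZ = 2000.0


@dataclass(frozen=True)
class PhaseSpan:
    """Half-open sample window ``[start, stop)`` with a phase label.

    ``direction`` is ``dorsal``/``ventral`` for ramps (sign of the commanded
    angular change) and ``none`` otherwise.
    """

    label: str
    start: int
    stop: int
    direction: str = NONE

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class HallCalibration:
    """Voltage-to-displacement calibration of the sensor-magnet pair.

    Parameters
    ----------
    voltage_v, displacement_mm
        Ordered table of matched (sensor voltage, capillary displacement)
        samples; both strictly monotone.  Interpolation is piecewise linear
        and extrapolation is forbidden.
    lever_arm_mm
        Distance from the pedicel-flagellum joint to the attachment annulus
        on the capillary; converts linear displacement to joint angle via
        ``angle = arctan(displacement / lever_arm)``.
    """

    voltage_v: np.ndarray
    displacement_mm: np.ndarray
    lever_arm_mm: float

    def __post_init__(self):
        v = np.asarray(self.voltage_v, dtype=float)
        d = np.asarray(self.displacement_mm, dtype=float)
        if v.ndim != 1 or v.shape != d.shape or v.size < 2:
            raise InvalidSpecError("calibration table needs >= 2 matched samples")
        order = np.argsort(v)
        v, d = v[order], d[order]
        if not np.all(np.diff(v) > 0):
            raise InvalidSpecError("calibration voltages must be strictly monotone")
        dd = np.diff(d)
        if not (np.all(dd > 0) or np.all(dd < 0)):
            raise InvalidSpecError("calibration displacements must be strictly monotone")
        if not self.lever_arm_mm > 0:
            raise InvalidSpecError("lever_arm_mm must be positive")
        object.__setattr__(self, "voltage_v", v)
        object.__setattr__(self, "displacement_mm", d)

    def displacement_at(self, volts: np.ndarray) -> np.ndarray:
        """Interpolate displacement (mm); out-of-range voltage is an error."""
        volts = np.asarray(volts, dtype=float)
        bad = (volts < self.voltage_v[0]) | (volts > self.voltage_v[-1])
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise CalibrationRangeError(
                f"voltage {volts.flat[idx]:.4g} V outside calibration range "
                f"[{self.voltage_v[0]:.4g}, {self.voltage_v[-1]:.4g}] at sample {idx}",
                index=idx,
            )
        return np.interp(volts, self.voltage_v, self.displacement_mm)

    def voltage_at(self, displacement_mm: np.ndarray) -> np.ndarray:
        """Inverse interpolation: displacement (mm) -> sensor voltage (V)."""
        disp = np.asarray(displacement_mm, dtype=float)
        d, v = self.displacement_mm, self.voltage_v
        if d[0] > d[-1]:  # make displacement axis ascending for np.interp
            d, v = d[::-1], v[::-1]
        bad = (disp < d[0]) | (disp > d[-1])
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise CalibrationRangeError(
                f"displacement {disp.flat[idx]:.4g} mm outside calibration range at sample {idx}",
                index=idx,
            )
        return np.interp(disp, d, v)

    @classmethod
    def default(cls) -> "HallCalibration":
        """A linear table spanning +-0.25 mm over +-2.5 V, lever arm 5.729 mm.

        With this lever arm a 0.1 mm displacement corresponds to 1.000 deg.
        """
        volts = np.linspace(-2.5, 2.5, 11)
        return cls(volts, 0.1 * volts, lever_arm_mm=5.729)


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one stimulus protocol.

    ``hold_positions_deg`` lists the target hold angles (dorsal positive).
    For ``variable_velocity`` protocols one spec describes one velocity;
    build a family with :func:`variable_velocity_family`.
    """

    kind: str
    hold_positions_deg: tuple = (-1.0,)
    ramp_velocity_deg_s: float = 1.0
    hold_duration_s: float = 4.0
    rest_duration_s: float = 6.0
    step_deg: float = 0.4
    span_deg: float = 2.0
    sample_rate_hz: float = 10_000.0

    def __post_init__(self):
        if self.kind not in ("variable_position", "variable_velocity", "stair"):
            raise InvalidSpecError(f"unknown protocol kind {self.kind!r}")
        if not self.hold_duration_s > 0:
            raise InvalidSpecError("hold_duration_s must be positive")
        if not self.ramp_velocity_deg_s > 0:
            raise InvalidSpecError("ramp_velocity_deg_s must be positive")
        if not self.rest_duration_s > 0:
            raise InvalidSpecError("rest_duration_s must be positive")
        if not self.sample_rate_hz > 2 * SPIKE_BAND_UPPER_HZ:
            raise InvalidSpecError(
                f"sample_rate_hz must exceed {2 * SPIKE_BAND_UPPER_HZ:.0f} Hz "
                "(twice the spike-band upper cutoff)"
            )
        object.__setattr__(self, "hold_positions_deg", tuple(self.hold_positions_deg))

    @classmethod
    def variable_position(cls, **kw) -> "ProtocolSpec":
        """Holds at +-0.5 and +-1 deg, ramped at 1 deg/s, held 4 s."""
        kw.setdefault("hold_positions_deg", (-1.0, -0.5, 0.5, 1.0))
        kw.setdefault("ramp_velocity_deg_s", 1.0)
        return cls(kind="variable_position", **kw)

    @classmethod
    def stair(cls, **kw) -> "ProtocolSpec":
        kw.setdefault("ramp_velocity_deg_s", 0.04)
        return cls(kind="stair", **kw)


def variable_velocity_family(
    velocities_deg_s: Sequence[float] | None = None,
    hold_deg: float = -1.0,
    **kw,
) -> list[ProtocolSpec]:
    """One ``variable_velocity`` spec per ramp speed (default: 7 speeds,
    log-spaced 0.2-3.2 deg/s, ventral 1-deg excursion)."""
    if velocities_deg_s is None:
        velocities_deg_s = np.geomspace(0.2, 3.2, 7)
    return [
        ProtocolSpec(
            kind="variable_velocity",
            hold_positions_deg=(hold_deg,),
            ramp_velocity_deg_s=float(v),
            **kw,
        )
        for v in velocities_deg_s
    ]


@dataclass
class StimulusTrace:
    """Sampled angular position/velocity with phase annotations.

    ``phases`` tile the trace without overlap; ramps carry the movement
    direction.  ``velocity_deg_s`` is the analytic derivative for commanded
    traces and the filtered numerical derivative for measured ones.
    """

    t: np.ndarray
    position_deg: np.ndarray
    velocity_deg_s: np.ndarray
    phases: tuple
    sample_rate_hz: float
    protocol: ProtocolSpec | None = None

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.position_deg) == len(self.velocity_deg_s) == n):
            raise InvalidSpecError("trace arrays must have equal length")
        pos = 0
        for ph in self.phases:
            if ph.start != pos or ph.stop <= ph.start:
                raise InvalidSpecError("phases must tile the trace without overlap")
            pos = ph.stop
        if self.phases and pos != n:
            raise InvalidSpecError("phases must cover the full trace")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def phase_window_s(self, ph: PhaseSpan) -> tuple[float, float]:
        """Phase boundaries in seconds (half-open)."""
        return ph.start / self.sample_rate_hz, ph.stop / self.sample_rate_hz

    def ramps(self) -> list[PhaseSpan]:
        return [p for p in self.phases if p.label == RAMP]

    def holds(self) -> list[PhaseSpan]:
        return [p for p in self.phases if p.label == HOLD]


def _assemble(segments, fs, protocol=None) -> StimulusTrace:
    """Build a trace from (duration_s, start_deg, end_deg, label, direction)."""
    bounds = [0]
    for dur, *_ in segments:
        bounds.append(bounds[-1] + dur)
    idx = [int(round(b * fs)) for b in bounds]
    n = idx[-1]
    t = np.arange(n) / fs
    position = np.zeros(n)
    velocity = np.zeros(n)
    phases = []
    for (dur, y0, y1, label, direction), i0, i1 in zip(segments, idx[:-1], idx[1:]):
        if i1 <= i0:
            continue
        if label == RAMP:
            slope = (y1 - y0) / dur
            # time referenced to the segment's own start
            position[i0:i1] = y0 + slope * (t[i0:i1] - i0 / fs)
            velocity[i0:i1] = slope
        else:
            position[i0:i1] = y0
        phases.append(PhaseSpan(label, i0, i1, direction))
    return StimulusTrace(t, position, velocity, tuple(phases), fs, protocol)


def _ramp_dir(delta: float) -> str:
    return DORSAL if delta > 0 else VENTRAL


def make_ramp_hold(spec: ProtocolSpec, hold_deg: float | None = None) -> StimulusTrace:
    """Commanded ramp-and-hold trace: rest, ramp to ``hold_deg``, hold,
    return ramp at the same speed, trailing rest.

    The rest budget is split evenly before and after the movement so that
    back-to-back trials are separated by the full inter-trial rest.
    A zero hold position yields a null stimulus (a single rest phase).
    """
    if spec.kind not in ("variable_position", "variable_velocity"):
        raise InvalidSpecError("make_ramp_hold requires a ramp-and-hold spec")
    if hold_deg is None:
        if len(spec.hold_positions_deg) != 1:
            raise InvalidSpecError("pass hold_deg explicitly for multi-position specs")
        hold_deg = spec.hold_positions_deg[0]
    fs = spec.sample_rate_hz
    rest_half = spec.rest_duration_s / 2
    if hold_deg == 0:
        total = spec.rest_duration_s + spec.hold_duration_s
        return _assemble([(total, 0.0, 0.0, REST, NONE)], fs, spec)
    ramp_dur = abs(hold_deg) / spec.ramp_velocity_deg_s
    segs = [
        (rest_half, 0.0, 0.0, REST, NONE),
        (ramp_dur, 0.0, hold_deg, RAMP, _ramp_dir(hold_deg)),
        (spec.hold_duration_s, hold_deg, hold_deg, HOLD, NONE),
        (ramp_dur, hold_deg, 0.0, RAMP, _ramp_dir(-hold_deg)),
        (rest_half, 0.0, 0.0, REST, NONE),
    ]
    return _assemble(segs, fs, spec)


def stair_levels(spec: ProtocolSpec) -> np.ndarray:
    """Hold levels of the stair, centred on baseline 0."""
    n_steps = spec.span_deg / spec.step_deg
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidSpecError("step_deg must divide span_deg")
    n_steps = int(round(n_steps))
    return -spec.span_deg / 2 + spec.step_deg * np.arange(n_steps + 1)


def stair_hold_sequence(spec: ProtocolSpec) -> list[float]:
    """Order of hold levels: descend from baseline to the most ventral level,
    ascend to the most dorsal, descend back to the most ventral, then ascend
    to baseline.  The lead-in and lead-out legs are what the first/last-three
    hold exclusion removes during hysteresis quantification."""
    levels = stair_levels(spec)
    below = sorted([float(l) for l in levels if l < 0], reverse=True)
    up = [float(l) for l in levels[1:]]
    down = [float(l) for l in levels[:-1][::-1]]
    tail = sorted([float(l) for l in levels if levels.min() < l < 0])
    return below + up + down + tail


def make_stair(spec: ProtocolSpec) -> StimulusTrace:
    """Commanded stair trace: 4-s holds joined by constant-velocity ramps.

    A zero span degenerates to a single hold at baseline.
    """
    if spec.kind != "stair":
        raise InvalidSpecError("make_stair requires a stair spec")
    fs = spec.sample_rate_hz
    rest_half = spec.rest_duration_s / 2
    if spec.span_deg == 0:
        segs = [
            (rest_half, 0.0, 0.0, REST, NONE),
            (spec.hold_duration_s, 0.0, 0.0, HOLD, NONE),
            (rest_half, 0.0, 0.0, REST, NONE),
        ]
        return _assemble(segs, fs, spec)
    seq = stair_hold_sequence(spec)
    v = spec.ramp_velocity_deg_s
    segs = [(rest_half, 0.0, 0.0, REST, NONE)]
    prev = 0.0
    for level in seq:
        segs.append((abs(level - prev) / v, prev, level, RAMP, _ramp_dir(level - prev)))
        segs.append((spec.hold_duration_s, level, level, HOLD, NONE))
        prev = level
    segs.append((abs(prev) / v, prev, 0.0, RAMP, _ramp_dir(-prev)))
    segs.append((rest_half, 0.0, 0.0, REST, NONE))
    return _assemble(segs, fs, spec)


def hall_to_angle(hall_voltage_v: np.ndarray, cal: HallCalibration) -> np.ndarray:
    """Sensor voltage -> joint angle (deg): interpolate displacement through
    the calibration table, then ``arctan(displacement / lever_arm)``."""
    disp = cal.displacement_at(hall_voltage_v)
    return np.degrees(np.arctan(disp / cal.lever_arm_mm))


def velocity_trace(position_deg: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Angular velocity from a measured position trace.

    Numerical derivative followed by a zero-phase 3rd-order Butterworth
    lowpass at 4 Hz.  The filtering attenuates velocity peaks, which is why
    ramp speed is reported from a straight-line fit rather than this trace.
    """
    position_deg = np.asarray(position_deg, dtype=float)
    if len(position_deg) < 10:
        raise WindowError("velocity_trace needs at least 10 samples")
    if sample_rate_hz <= 8:
        raise FilterDesignError("sample rate must exceed 8 Hz for the 4 Hz lowpass")
    deriv = np.gradient(position_deg) * sample_rate_hz
    sos = sps.butter(3, 4.0, btype="low", fs=sample_rate_hz, output="sos")
    padlen = min(len(deriv) - 1, 3 * (2 * sos.shape[0] + 1))
    return sps.sosfiltfilt(sos, deriv, padlen=padlen)


@dataclass(frozen=True)
class RampFit:
    """Straight-line fit over a ramp window; the slope is the reported
    angular velocity.  ``accepted`` requires r2 > 0.9."""

    slope_deg_s: float
    intercept_deg: float
    r2: float
    window: tuple[int, int]

    @property
    def accepted(self) -> bool:
        return bool(self.r2 > 0.9)


def fit_ramp_velocity(
    t: np.ndarray, position_deg: np.ndarray, window: tuple[int, int]
) -> RampFit:
    """OLS line of position on time over ``window`` (sample indices)."""
    i0, i1 = window
    if i0 < 0 or i1 > len(t) or i1 - i0 < 3:
        raise WindowError("ramp-fit window needs >= 3 samples inside the trace")
    tw, pw = np.asarray(t[i0:i1], float), np.asarray(position_deg[i0:i1], float)
    if tw[-1] == tw[0]:
        raise WindowError("degenerate (constant-time) ramp-fit window")
    res = stats.linregress(tw, pw)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return RampFit(float(res.slope), float(res.intercept), r2, (i0, i1))


def ramp_fit_window(phase: PhaseSpan, margin: float = 0.05) -> tuple[int, int]:
    """Central portion of a ramp phase (default 90%) for the velocity fit,
    leaving a settle margin at each end."""
    n = phase.n_samples
    trim = int(round(margin * n))
    return phase.start + trim, phase.stop - trim


def segment_phases(commanded: StimulusTrace, measured_position_deg: np.ndarray) -> StimulusTrace:
    """Copy phase annotations from a commanded trace onto a measured one.

    The measured trace must share sample rate and onset alignment; a length
    mismatch greater than one sample is an error.
    """
    measured = np.asarray(measured_position_deg, dtype=float)
    if abs(len(measured) - commanded.n_samples) > 1:
        raise WindowError(
            f"length mismatch {len(measured)} vs {commanded.n_samples} exceeds 1 sample"
        )
    n = min(len(measured), commanded.n_samples)
    phases = tuple(
        PhaseSpan(p.label, p.start, min(p.stop, n), p.direction)
        for p in commanded.phases
        if p.start < n
    )
    vel = velocity_trace(measured[:n], commanded.sample_rate_hz)
    return StimulusTrace(
        commanded.t[:n], measured[:n], vel, phases, commanded.sample_rate_hz, commanded.protocol
    )


# ---------------------------------------------------------------------------
# Text interfaces

def write_trace_csv(path, trace: StimulusTrace, column: str = "position_deg") -> None:
    pd.DataFrame({"time_s": trace.t, column: trace.position_deg}).to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    # round_trip parsing so written float64 values are recovered bit-exactly
    return pd.read_csv(path, float_precision="round_trip")


def protocol_to_json_dict(spec: ProtocolSpec) -> dict:
    return {
        "kind": spec.kind,
        "hold_positions_deg": list(spec.hold_positions_deg),
        "ramp_velocity_deg_s": spec.ramp_velocity_deg_s,
        "hold_duration_s": spec.hold_duration_s,
        "rest_duration_s": spec.rest_duration_s,
        "step_deg": spec.step_deg,
        "span_deg": spec.span_deg,
        "sample_rate_hz": spec.sample_rate_hz,
    }


def protocol_from_json_dict(d: dict) -> ProtocolSpec:
    d = dict(d)
    d["hold_positions_deg"] = tuple(d.get("hold_positions_deg", (-1.0,)))
    return ProtocolSpec(**d)
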