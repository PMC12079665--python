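"""Stimulus construction, Hall conversion and ramp-speed estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from joencode import (
    HallCalibration,
    ProtocolSpec,
    fit_ramp_velocity,
    hall_to_angle,
    make_ramp_hold,
    make_stair,
    segment_phases,
    velocity_trace,
)
from joencode.errors import (
    CalibrationRangeError,
    FilterDesignError,
    InvalidSpecError,
    WindowError,
)
from joencode.stimulus import DORSAL, RAMP, REST, VENTRAL, ramp_fit_window


def spec_for(hold, v, **kw):
    return ProtocolSpec(kind="variable_position", hold_positions_deg=(hold,),
                        ramp_velocity_deg_s=v, **kw)


class TestRampHold:
    @pytest.mark.parametrize(
        "hold,v,ramp_s",
        [(-1.0, 1.0, 1.0), (-0.7, 3.16, 0.2215), (0.5, 1.0, 0.5)],
    )
    def test_ramp_duration_is_excursion_over_speed(self, hold, v, ramp_s, fs):
        trace = make_ramp_hold(spec_for(hold, v))
        ramp = trace.ramps()[0]
        assert ramp.n_samples / fs == pytest.approx(ramp_s, abs=1.5 / fs)
        hold_ph = trace.holds()[0]
        assert hold_ph.n_samples / fs == pytest.approx(4.0, abs=1.5 / fs)

    def test_zero_hold_is_null_stimulus(self):
        trace = make_ramp_hold(spec_for(0.0, 1.0))
        assert np.all(trace.position_deg == 0)
        assert len(trace.phases) == 1 and trace.phases[0].label == REST

    def test_ramp_directions_and_phase_tiling(self, ramp_hold_trace):
        labels = [(p.label, p.direction) for p in ramp_hold_trace.phases]
        assert labels == [
            (REST, "none"), (RAMP, VENTRAL), ("hold", "none"), (RAMP, DORSAL), (REST, "none"),
        ]
        assert ramp_hold_trace.phases[-1].stop == ramp_hold_trace.n_samples

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            ProtocolSpec(kind="variable_position", hold_duration_s=0.0)
        with pytest.raises(InvalidSpecError):
            ProtocolSpec(kind="variable_position", ramp_velocity_deg_s=0.0)
        with pytest.raises(InvalidSpecError):
            ProtocolSpec(kind="nonsense")
        with pytest.raises(InvalidSpecError):
            ProtocolSpec(kind="stair", sample_rate_hz=3000.0)


class TestStair:
    def test_transition_and_hold_durations(self, stair_trace, fs):
        # full 0.4-deg transitions at 0.04 deg/s last 10 s; every hold 4 s
        interior_ramps = stair_trace.ramps()[1:-1]
        assert all(r.n_samples / fs == pytest.approx(10.0, abs=1.5 / fs)
                   for r in interior_ramps)
        assert all(h.n_samples / fs == pytest.approx(4.0, abs=1.5 / fs)
                   for h in stair_trace.holds())

    def test_direction_alternates_at_turning_points(self, stair_trace):
        dirs = [r.direction for r in stair_trace.ramps()]
        # descend, ascend to most dorsal, descend, ascend back
        assert dirs[:3] == [VENTRAL] * 3
        assert dirs[3:8] == [DORSAL] * 5
        assert dirs[8:13] == [VENTRAL] * 5

    def test_zero_span_single_hold(self):
        trace = make_stair(ProtocolSpec.stair(span_deg=0.0))
        assert [p.label for p in trace.phases] == [REST, "hold", REST]
        assert np.all(trace.position_deg == 0)

    def test_step_must_divide_span(self):
        with pytest.raises(InvalidSpecError):
            make_stair(ProtocolSpec.stair(step_deg=0.3))


class TestHallConversion:
    def test_arctan_oracle(self, cal):
        # 0.1 mm over a 5.729 mm lever arm is 1.000 deg
        volts = np.array([0.0, 1.0, 0.5])
        expect = np.degrees(np.arctan(np.array([0.0, 0.1, 0.05]) / 5.729))
        assert np.allclose(hall_to_angle(volts, cal), expect, atol=1e-9)

    def test_out_of_range_voltage_reports_index(self, cal):
        with pytest.raises(CalibrationRangeError) as exc:
            hall_to_angle(np.array([0.0, 7.0]), cal)
        assert exc.value.index == 1

    @given(st.lists(st.floats(-2.4, 2.4), min_size=2, max_size=8))
    def test_monotone_in_displacement(self, volts):
        cal = HallCalibration.default()
        v = np.sort(np.asarray(volts))
        ang = hall_to_angle(v, cal)
        assert np.all(np.diff(ang) >= 0)

    def test_calibration_table_must_be_monotone(self):
        with pytest.raises(InvalidSpecError):
            HallCalibration(np.array([0.0, 1.0, 0.5]), np.array([0.0, 0.1, 0.2]), 5.0)


class TestVelocityTrace:
    def test_constant_position_zero_velocity(self, fs):
        assert np.allclose(velocity_trace(np.ones(1000), fs), 0.0, atol=1e-9)

    def test_ramp_interior_recovers_speed(self, ramp_hold_trace, fs):
        vel = velocity_trace(ramp_hold_trace.position_deg, fs)
        ramp = ramp_hold_trace.ramps()[0]
        mid = slice(ramp.start + ramp.n_samples // 3, ramp.stop - ramp.n_samples // 3)
        assert np.allclose(vel[mid], -1.0, atol=0.01)

    def test_lowpass_attenuates_step_edge(self, fs):
        pos = np.zeros(5000)
        pos[2500:] = 1.0
        raw_peak = np.max(np.abs(np.gradient(pos) * fs))
        filt_peak = np.max(np.abs(velocity_trace(pos, fs)))
        assert filt_peak < raw_peak

    def test_sample_rate_too_low(self):
        with pytest.raises(FilterDesignError):
            velocity_trace(np.zeros(100), 8.0)

    def test_integrates_back_to_position(self, ramp_hold_trace, fs):
        vel = velocity_trace(ramp_hold_trace.position_deg, fs)
        recon = np.cumsum(vel) / fs
        hold = ramp_hold_trace.holds()[0]
        # after the 4-Hz filter's corner transient (~0.25 s) has settled
        settle = int(0.5 * fs)
        err = np.abs(recon[hold.start + settle:hold.stop - settle] -
                     ramp_hold_trace.position_deg[hold.start + settle:hold.stop - settle])
        assert np.max(err) < 0.01  # within 1% of the 1-deg ramp amplitude


class TestRampFit:
    def test_exact_line_recovered(self, fs):
        t = np.arange(10_000) / fs
        pos = 0.2 - 0.46 * t
        fit = fit_ramp_velocity(t, pos, (0, len(t)))
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_deg_s == pytest.approx(-0.46, rel=1e-9)
        assert fit.accepted

    def test_noisy_line_slope_within_one_percent(self, fs, rng):
        t = np.arange(10_000) / fs
        pos = -0.46 * t + rng.normal(0, 0.001, t.size)
        fit = fit_ramp_velocity(t, pos, (0, len(t)))
        assert abs(fit.slope_deg_s + 0.46) / 0.46 < 0.01

    def test_poor_fit_flagged_below_point_nine(self, rng):
        t = np.linspace(0, 1, 200)
        pos = 0.05 * t + rng.normal(0, 0.05, t.size)
        fit = fit_ramp_velocity(t, pos, (0, len(t)))
        assert fit.r2 < 0.9 and not fit.accepted

    def test_degenerate_window_errors(self):
        with pytest.raises(WindowError):
            fit_ramp_velocity(np.zeros(10), np.zeros(10), (0, 10))
        with pytest.raises(WindowError):
            fit_ramp_velocity(np.arange(10.0), np.zeros(10), (0, 2))

    def test_central_window_lies_inside_ramp(self, ramp_hold_trace):
        ramp = ramp_hold_trace.ramps()[0]
        i0, i1 = ramp_fit_window(ramp)
        assert ramp.start < i0 < i1 < ramp.stop


class TestSegmentPhases:
    def test_phases_copied_onto_measurement(self, ramp_hold_trace, rng):
        measured = ramp_hold_trace.position_deg + rng.normal(0, 1e-3,
                                                             ramp_hold_trace.n_samples)
        seg = segment_phases(ramp_hold_trace, measured)
        assert [p.label for p in seg.phases] == [p.label for p in ramp_hold_trace.phases]
        assert seg.ramps()[0].direction == VENTRAL

    def test_null_stimulus_single_rest(self):
        trace = make_ramp_hold(spec_for(0.0, 1.0))
        seg = segment_phases(trace, trace.position_deg.copy())
        assert len(seg.phases) == 1 and seg.phases[0].label == REST

    def test_length_mismatch_rejected(self, ramp_hold_trace):
        with pytest.raises(WindowError):
            segment_phases(ramp_hold_trace, ramp_hold_trace.position_deg[:-5])
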