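"""The adapting-encoder generator: closed-form behaviour and round trips."""

import numpy as np
import pytest

from joencode import (
    HallCalibration,
    NeuronModelParams,
    ProtocolSpec,
    hall_to_angle,
    make_ramp_hold,
    simulate_rate,
    simulate_spikes,
    synthesize_hall,
    synthesize_voltage,
)
from joencode.errors import InvalidSpecError
from joencode.stimulus import StimulusTrace, PhaseSpan
from joencode.synthetic_data import generate_dataset, load_manifest, load_params

FS = 10_000.0


def _const_stim(theta, duration, fs=FS):
    n = int(duration * fs)
    pos = np.full(n, theta)
    return StimulusTrace(np.arange(n) / fs, pos, np.zeros(n),
                         (PhaseSpan("hold", 0, n),), fs)


class TestSimulateRate:
    def test_rest_gives_baseline(self):
        params = NeuronModelParams()
        lam = simulate_rate(params, _const_stim(0.0, 2.0))
        assert np.allclose(lam, params.r0_hz, atol=1e-9)

    def test_position_step_relaxes_with_tau_p(self):
        """With full position adaptation, the excess over baseline is 1/e of
        its initial value one time constant after a step."""
        params = NeuronModelParams(alpha_p=1.0, tau_p_s=2.0, g_p_hz_per_deg=30.0,
                                   a_hz=50.0)
        stim = _const_stim(-1.0, 10.0)  # ventral step for a ventral-preferring cell
        lam = simulate_rate(params, stim)
        excess = lam - params.r0_hz
        i_tau = int(params.tau_p_s * FS)
        assert excess[0] == pytest.approx(30.0, rel=1e-3)
        assert excess[i_tau] == pytest.approx(30.0 / np.e, rel=1e-2)

    def test_ramp_plateau_velocity_drive_closed_form(self):
        params = NeuronModelParams(g_p_hz_per_deg=0.0, alpha_v=0.5, tau_v_s=10.0)
        spec = ProtocolSpec(kind="variable_velocity", hold_positions_deg=(-1.0,),
                            ramp_velocity_deg_s=1.0)
        stim = make_ramp_hold(spec)
        lam = simulate_rate(params, stim)
        ramp = stim.ramps()[0]
        T = ramp.n_samples / FS
        s0 = 1 / (1 + np.exp(params.b * params.c_deg_s))
        l_v = params.a_hz * (1 / (1 + np.exp(-params.b * (1.0 - params.c_deg_s))) - s0)
        expect = params.r0_hz + l_v * (1 - params.alpha_v * (1 - np.exp(-T / params.tau_v_s)))
        assert lam[ramp.stop - 2] == pytest.approx(expect, rel=1e-3)

    def test_intensity_never_negative(self):
        params = NeuronModelParams(g_p_hz_per_deg=100.0, r0_hz=5.0)
        stim = _const_stim(1.0, 2.0)  # anti-preferred position, strong suppression
        assert np.all(simulate_rate(params, stim) >= 0)


class TestSimulateSpikes:
    def test_zero_intensity_no_spikes(self, rng):
        assert simulate_spikes(np.zeros(1000), FS, 2.0, rng).size == 0

    def test_homogeneous_count_within_poisson_band(self):
        lam = np.full(int(100 * FS), 40.0)
        spk = simulate_spikes(lam, FS, 2.0, np.random.default_rng(11))
        assert abs(len(spk) - 4000) < 3 * np.sqrt(4000)

    def test_identical_seed_identical_spikes(self):
        lam = np.full(int(5 * FS), 60.0)
        a = simulate_spikes(lam, FS, 2.0, np.random.default_rng(5))
        b = simulate_spikes(lam, FS, 2.0, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_refractory_period_enforced(self):
        lam = np.full(int(20 * FS), 200.0)
        spk = simulate_spikes(lam, FS, 2.0, np.random.default_rng(3))
        assert np.min(np.diff(spk)) > 2e-3


class TestVoltageAndHall:
    def test_no_spikes_flat_at_rest(self, rng):
        v = synthesize_voltage(np.array([]), 1.0, FS, rng, noise_sd_mv=0.0)
        assert np.allclose(v, -50.0)

    def test_spike_beyond_trace_errors(self, rng):
        with pytest.raises(InvalidSpecError):
            synthesize_voltage(np.array([2.5]), 1.0, FS, rng)

    def test_hall_round_trip_noiseless(self, cal, ramp_hold_trace, rng):
        volts = synthesize_hall(ramp_hold_trace.position_deg, cal, rng, noise_sd_v=0.0)
        back = hall_to_angle(volts, cal)
        assert np.max(np.abs(back - ramp_hold_trace.position_deg)) < 1e-6

    def test_hall_round_trip_noise_mostly_within_3_sigma(self, cal, ramp_hold_trace, rng):
        noise_v = 0.002
        sigma_deg = np.degrees(noise_v * 0.1 / cal.lever_arm_mm)  # 0.1 mm/V table slope
        volts = synthesize_hall(ramp_hold_trace.position_deg, cal, rng, noise_sd_v=noise_v)
        err = np.abs(hall_to_angle(volts, cal) - ramp_hold_trace.position_deg)
        assert np.mean(err < 3 * sigma_deg) > 0.99


class TestDataset:
    def _protocols(self):
        return {"pos": ProtocolSpec(kind="variable_position", hold_positions_deg=(-1.0,),
                                    hold_duration_s=2.0, rest_duration_s=4.0)}

    def test_round_trip_bit_identical(self, tmp_path):
        params = {"n0": NeuronModelParams()}
        manifest_path = generate_dataset(params, self._protocols(), 3, seed=1,
                                         out_dir=tmp_path)
        manifest = load_manifest(manifest_path)
        entry = manifest["neurons"][0]
        assert load_params(entry["truth"]) == params["n0"]
        import pandas as pd

        df1 = pd.read_csv(entry["protocols"][0]["trials"][0])
        df2 = pd.read_csv(entry["protocols"][0]["trials"][0])
        assert df1.equals(df2)
        assert set(df1.columns) == {"time_s", "voltage_mV", "hall_V"}

    def test_two_trials_warns(self, tmp_path):
        with pytest.warns(UserWarning):
            generate_dataset({"n0": NeuronModelParams()}, self._protocols(), 2,
                             seed=1, out_dir=tmp_path)

    def test_seeds_change_spikes_not_stimuli(self, tmp_path, rng):
        import pandas as pd

        p1 = generate_dataset({"n0": NeuronModelParams()}, self._protocols(), 3,
                              seed=1, out_dir=tmp_path / "a")
        p2 = generate_dataset({"n0": NeuronModelParams()}, self._protocols(), 3,
                              seed=2, out_dir=tmp_path / "b")
        d1 = pd.read_csv(load_manifest(p1)["neurons"][0]["protocols"][0]["trials"][0])
        d2 = pd.read_csv(load_manifest(p2)["neurons"][0]["protocols"][0]["trials"][0])
        assert not np.array_equal(d1["voltage_mV"], d2["voltage_mV"])
        assert np.array_equal(d1["time_s"], d2["time_s"])
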