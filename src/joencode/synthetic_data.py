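"""Ground-truth generator: a parametric adapting encoder of flagellar motion.

The generator produces the statistical structure the analysis assumes --
baseline firing in the tens of Hz, direction selectivity (excitation for
preferred-direction ramps, suppression opposite), linear steady-state
position tuning, sigmoidal peak-rate velocity tuning, and first-order
(single-exponential) adaptation in both the position and velocity pathways
-- so that the downstream estimators can be validated by parameter recovery.

Model intensity (Hz), with d = -1 for ventral-preferring neurons:

    theta_s(t) = d * theta(t)                 signed position drive
    v_s(t)     = d * dtheta/dt                signed velocity
    L_v(t)     = a / (1 + exp(-b (v_s - c))) - a / (1 + exp(b c))
    lambda(t)  = max(0, r0 + g_p (theta_s - alpha_p theta_bar)
                        + L_v - alpha_v L_v_bar)

where theta_bar and L_v_bar are first-order low-pass filtered copies of
their inputs with time constants tau_p and tau_v.  Under a constant
stimulus the excess rate therefore decays as a single exponential with the
stated time constant, which makes the single-exponential adaptation fits
exactly correct in the noiseless limit.

Spikes are an inhomogeneous point process obtained by thinning.  The accept
hazard is dead-time compensated, h = lambda / (1 - lambda * refractory), so
the realized rate equals lambda(t) despite the absolute refractory period;
recovery tests then measure estimator error, not generator bias.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidSpecError
from .stimulus import (
    HallCalibration,
    ProtocolSpec,
    StimulusTrace,
    make_ramp_hold,
    make_stair,
    protocol_from_json_dict,
    protocol_to_json_dict,
)

VENTRAL = "ventral"
DORSAL = "dorsal"


@dataclass(frozen=True)
class NeuronModelParams:
    """Ground-truth parameters of one synthetic neuron.

    Defaults mirror the response scales of the recorded population: ~40 Hz
    baseline, peak rates approaching ~145 Hz at the fastest tested
    velocities, position gains of tens of Hz/deg, and adaptation time
    constants of seconds to tens of seconds.
    """

    r0_hz: float = 40.0
    g_p_hz_per_deg: float = 20.0
    alpha_p: float = 0.6
    tau_p_s: float = 15.0
    a_hz: float = 110.0
    b: float = 3.0
    c_deg_s: float = 1.0
    alpha_v: float = 0.5
    tau_v_s: float = 10.0
    preferred_direction: str = VENTRAL
    refractory_ms: float = 2.0

    def __post_init__(self):
        if self.preferred_direction not in (VENTRAL, DORSAL):
            raise InvalidSpecError("preferred_direction must be 'ventral' or 'dorsal'")
        for name in ("r0_hz", "tau_p_s", "a_hz", "b", "c_deg_s", "tau_v_s"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be positive")
        if not (0 <= self.alpha_p <= 1 and 0 <= self.alpha_v <= 1):
            raise InvalidSpecError("adaptation fractions must lie in [0, 1]")
        if self.refractory_ms < 0:
            raise InvalidSpecError("refractory_ms must be non-negative")

    @property
    def sign(self) -> float:
        return -1.0 if self.preferred_direction == VENTRAL else 1.0


@dataclass
class SyntheticTrial:
    stimulus: StimulusTrace
    true_rate_hz: np.ndarray
    true_spike_times: np.ndarray
    params: NeuronModelParams
    voltage_mv: np.ndarray | None = None
    hall_v: np.ndarray | None = None


def _first_order_lowpass(x: np.ndarray, tau_s: float, sample_rate_hz: float) -> np.ndarray:
    """Exact discrete first-order relaxation toward x with time constant tau."""
    coef = np.exp(-1.0 / (tau_s * sample_rate_hz))
    return sps.lfilter([1.0 - coef], [1.0, -coef], x)


def simulate_rate(params: NeuronModelParams, stim: StimulusTrace) -> np.ndarray:
    """Model intensity lambda(t) in Hz for a stimulus trace (see module docs)."""
    d = params.sign
    theta_s = d * stim.position_deg
    v_s = d * stim.velocity_deg_s
    fs = stim.sample_rate_hz

    theta_bar = _first_order_lowpass(theta_s, params.tau_p_s, fs)
    rest_level = params.a_hz / (1.0 + np.exp(params.b * params.c_deg_s))
    l_v = params.a_hz / (1.0 + np.exp(-params.b * (v_s - params.c_deg_s))) - rest_level
    l_v_bar = _first_order_lowpass(l_v, params.tau_v_s, fs)

    lam = (
        params.r0_hz
        + params.g_p_hz_per_deg * (theta_s - params.alpha_p * theta_bar)
        + l_v
        - params.alpha_v * l_v_bar
    )
    return np.maximum(lam, 0.0)


def simulate_spikes(
    lambda_hz: np.ndarray,
    sample_rate_hz: float,
    refractory_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous spike times by thinning with an absolute refractory period.

    Candidates are a homogeneous Poisson stream at the peak compensated
    hazard; each is accepted with probability h(t)/h_max, where
    h = lambda/(1 - lambda*dead_time) cancels the rate loss from the dead
    time.  Candidates inside a dead time are discarded.  Deterministic under
    a fixed generator.
    """
    lam = np.asarray(lambda_hz, float)
    if np.any(lam < 0):
        raise InvalidSpecError("intensity must be non-negative")
    T = len(lam) / sample_rate_hz
    dead = refractory_ms / 1000.0
    lam_max = float(lam.max())
    if lam_max == 0:
        return np.array([])
    occupancy = np.minimum(lam * dead, 0.9)
    hazard = lam / (1.0 - occupancy)
    h_max = float(hazard.max())

    n_cand = rng.poisson(h_max * T)
    if n_cand == 0:
        return np.array([])
    cand = np.sort(rng.uniform(0.0, T, n_cand))
    idx = np.minimum((cand * sample_rate_hz).astype(int), len(lam) - 1)
    accepted = cand[rng.random(n_cand) < hazard[idx] / h_max]

    if dead <= 0:
        return accepted
    spikes = []
    last = -np.inf
    for t in accepted:
        if t - last > dead:
            spikes.append(t)
            last = t
    return np.asarray(spikes)


def spike_template(sample_rate_hz: float, amp_mv: float = 20.0,
                   width_ms: float = 1.5) -> np.ndarray:
    """Biphasic intracellular spike waveform: a sharp depolarizing peak
    followed by a shallower hyperpolarizing after-lobe."""
    half_ms = 2.0 * width_ms
    n = int(round(half_ms / 1000.0 * sample_rate_hz))
    t = np.arange(-n, n + 1) / sample_rate_hz * 1000.0  # ms
    sigma_up = width_ms / 6.0
    pos = np.exp(-0.5 * (t / sigma_up) ** 2)
    neg = 0.30 * np.exp(-0.5 * ((t - 0.8 * width_ms) / (width_ms / 2.0)) ** 2)
    return amp_mv * (pos - neg)


def synthesize_voltage(
    spike_times_s: np.ndarray,
    duration_s: float,
    sample_rate_hz: float,
    rng: np.random.Generator,
    amp_mv: float = 20.0,
    width_ms: float = 1.5,
    noise_sd_mv: float = 0.5,
    drift: tuple[float, float] | None = None,
    resting_mv: float = -50.0,
) -> np.ndarray:
    """Membrane-voltage trace: spike templates at the given times, Gaussian
    noise, optional slow sinusoidal drift (amp_mV, freq_Hz with freq < 1 Hz)
    and a resting offset.  Overlapping templates sum."""
    n = int(round(duration_s * sample_rate_hz))
    v = np.full(n, resting_mv, dtype=float)
    template = spike_template(sample_rate_hz, amp_mv, width_ms)
    half = len(template) // 2
    for t_spk in np.asarray(spike_times_s, float):
        if not 0 <= t_spk <= duration_s:
            raise InvalidSpecError(f"spike at {t_spk:.4f} s lies beyond the trace")
        center = int(round(t_spk * sample_rate_hz))
        i0, i1 = center - half, center + half + 1
        j0, j1 = max(i0, 0), min(i1, n)
        v[j0:j1] += template[j0 - i0 : len(template) - (i1 - j1)]
    if noise_sd_mv > 0:
        v += rng.normal(0.0, noise_sd_mv, n)
    if drift is not None:
        amp, freq = drift
        t = np.arange(n) / sample_rate_hz
        v += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return v


def synthesize_hall(
    position_deg: np.ndarray,
    cal: HallCalibration,
    rng: np.random.Generator,
    noise_sd_v: float = 0.002,
) -> np.ndarray:
    """Hall-sensor voltage for an angular trajectory: inverse of the
    calibration reading (displacement = lever_arm * tan(theta)), plus
    Gaussian sensor noise."""
    disp = cal.lever_arm_mm * np.tan(np.radians(np.asarray(position_deg, float)))
    volts = cal.voltage_at(disp)
    if noise_sd_v > 0:
        volts = volts + rng.normal(0.0, noise_sd_v, len(volts))
    return volts


def simulate_trial(
    params: NeuronModelParams,
    stim: StimulusTrace,
    rng: np.random.Generator,
    with_voltage: bool = False,
    with_hall: bool = False,
    cal: HallCalibration | None = None,
    lambda_hz: np.ndarray | None = None,
) -> SyntheticTrial:
    """One trial: intensity, spikes and (optionally) raw voltage/Hall traces.

    Pass ``lambda_hz`` to reuse a precomputed intensity across trials.
    """
    lam = simulate_rate(params, stim) if lambda_hz is None else lambda_hz
    spikes = simulate_spikes(lam, stim.sample_rate_hz, params.refractory_ms, rng)
    trial = SyntheticTrial(stim, lam, spikes, params)
    if with_voltage:
        trial.voltage_mv = synthesize_voltage(
            spikes, stim.duration_s, stim.sample_rate_hz, rng
        )
    if with_hall:
        cal = cal or HallCalibration.default()
        trial.hall_v = synthesize_hall(stim.position_deg, cal, rng)
    return trial


def build_stimulus(spec: ProtocolSpec, hold_deg: float | None = None) -> StimulusTrace:
    if spec.kind == "stair":
        return make_stair(spec)
    return make_ramp_hold(spec, hold_deg)


def generate_dataset(
    params_by_neuron: dict[str, NeuronModelParams],
    protocols: dict[str, ProtocolSpec],
    n_trials: int,
    seed: int,
    out_dir: str | Path,
    cal: HallCalibration | None = None,
) -> Path:
    """Write a file-based cohort: per-trial CSVs (time_s,voltage_mV,hall_V),
    a ground-truth sidecar per neuron and a manifest JSON.

    Returns the manifest path.  Fewer than three trials per protocol is
    allowed but warned about, since downstream analysis requires >= 3.
    """
    if n_trials < 3:
        warnings.warn("fewer than 3 trials per protocol; downstream analysis requires >= 3")
    cal = cal or HallCalibration.default()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = {"calibration": {
        "voltage_v": cal.voltage_v.tolist(),
        "displacement_mm": cal.displacement_mm.tolist(),
        "lever_arm_mm": cal.lever_arm_mm,
    }, "neurons": []}
    for neuron_id, params in params_by_neuron.items():
        ndir = out_dir / neuron_id
        ndir.mkdir(exist_ok=True)
        truth_path = ndir / "truth.json"
        truth_path.write_text(json.dumps(asdict(params), indent=1))
        entry = {"neuron_id": neuron_id, "truth": str(truth_path), "protocols": []}
        for proto_id, spec in protocols.items():
            if spec.kind == "variable_position":
                stims = [(f"{proto_id}_h{h:+.2f}", make_ramp_hold(spec, h))
                         for h in spec.hold_positions_deg]
            else:
                stims = [(proto_id, build_stimulus(spec))]
            for stim_id, stim in stims:
                lam = simulate_rate(params, stim)
                trial_files = []
                for k in range(n_trials):
                    trial = simulate_trial(params, stim, rng, with_voltage=True,
                                           with_hall=True, cal=cal, lambda_hz=lam)
                    path = ndir / f"{stim_id}_trial{k}.csv"
                    pd.DataFrame({
                        "time_s": stim.t,
                        "voltage_mV": trial.voltage_mv,
                        "hall_V": trial.hall_v,
                    }).to_csv(path, index=False, float_format="%.5f")
                    trial_files.append(str(path))
                entry["protocols"].append({
                    "protocol_id": stim_id,
                    "spec": protocol_to_json_dict(spec),
                    "hold_deg": (float(np.median(stim.position_deg[stim.holds()[0].start:
                                                                   stim.holds()[0].stop]))
                                 if stim.holds() else 0.0),
                    "trials": trial_files,
                })
        manifest["neurons"].append(entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_params(path: str | Path) -> NeuronModelParams:
    return NeuronModelParams(**json.loads(Path(path).read_text()))
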