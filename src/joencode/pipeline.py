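"""End-to-end orchestration: ingest trials, detect spikes, estimate rates,
fit tuning and adaptation, quantify hysteresis, and emit tidy tables.

The pipeline consumes a manifest (as written by
:func:`joencode.synthetic_data.generate_dataset`) listing per-neuron
protocol entries with trial CSVs, runs every analysis stage in order and
returns one :class:`NeuronReport` per neuron plus a cohort summary table.
All configuration constants live in :class:`AnalysisConfig`; every output
row carries a hash of the configuration so that threshold changes are
visible in provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptation import (
    fit_exponential,
    hold_adaptation_window,
    ramp_adaptation_window,
    tau_vs_velocity,
)
from .encoding_fits import (
    LinearPositionFit,
    LogisticVelocityFit,
    VelocityModelComparison,
    compare_velocity_models,
    fit_position_linear,
    fit_velocity_logistic,
)
from .errors import JoEncodeError
from .hysteresis import HysteresisResult, extract_branches, loop_area
from .rates import (
    RateEstimate,
    baseline_rate,
    baseline_sd,
    classify_direction,
    gcfr,
    peak_rate,
    ramp_mean_rates,
    steady_state_rate,
)
from .spikes import TrialRecording, build_raster
from .stimulus import (
    HallCalibration,
    StimulusTrace,
    fit_ramp_velocity,
    hall_to_angle,
    make_ramp_hold,
    make_stair,
    protocol_from_json_dict,
    ramp_fit_window,
    segment_phases,
)

logger = logging.getLogger("joencode")

MIN_TRIALS = 3


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis constants in one place.

    Defaults equal the printed constants of the protocol the package
    implements; any override changes :meth:`config_hash` and is therefore
    visible in output provenance.
    """

    sample_rate_hz: float = 10_000.0
    spike_band_hz: tuple = (10.0, 2000.0)
    velocity_lowpass_hz: float = 4.0
    kernel_sd_ms: float = 30.0
    kernel_width_ms: float = 200.0
    baseline_window_s: float = 1.0
    baseline_offset_s: float = 0.5
    steady_state_window_s: float = 1.0
    steady_state_offset_s: float = 0.5
    hold_adapt_start_offset_s: float = 0.1
    hold_adapt_end_offset_s: float = 0.5
    ramp_fit_r2: float = 0.9
    encoder_r2: float = 0.8
    spearman_rho: float = 0.8
    ramp_adapt_r2: float = 0.75
    hold_adapt_r2: float = 0.5
    direction_k: float = 2.0
    refractory_guard_ms: float = 2.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class NeuronReport:
    """Per-neuron results with QC bookkeeping."""

    neuron_id: str
    direction_label: str | None = None
    baseline_hz: float | None = None
    position_fit: LinearPositionFit | None = None
    velocity_fit: LogisticVelocityFit | None = None
    model_comparison: VelocityModelComparison | None = None
    adaptation_rows: list = field(default_factory=list)
    tau_velocity_rho: float | None = None
    hysteresis: HysteresisResult | None = None
    rejected_trials: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = {
            "neuron_id": self.neuron_id,
            "direction_label": self.direction_label,
            "baseline_hz": self.baseline_hz,
            "rejected_trials": self.rejected_trials,
            "skipped": self.skipped,
            "errors": self.errors,
            "tau_velocity_rho": self.tau_velocity_rho,
        }
        if self.position_fit:
            d["position_fit"] = asdict(self.position_fit)
            d["is_position_encoder"] = self.position_fit.is_position_encoder
        if self.velocity_fit:
            d["velocity_fit"] = asdict(self.velocity_fit)
            d["is_velocity_encoder"] = self.velocity_fit.is_velocity_encoder
        if self.hysteresis:
            d["hysteresis"] = asdict(self.hysteresis)
        d["adaptation"] = self.adaptation_rows
        return d


def _load_protocol_entry(entry: dict, cal: HallCalibration) -> tuple[StimulusTrace, list]:
    """Build the commanded stimulus and the trial recordings for one entry."""
    spec = protocol_from_json_dict(entry["spec"])
    if spec.kind == "stair":
        commanded = make_stair(spec)
    else:
        commanded = make_ramp_hold(spec, entry.get("hold_deg"))
    recs = []
    measured = None
    for path in entry["trials"]:
        df = pd.read_csv(path)
        n = min(len(df), commanded.n_samples)
        rec = TrialRecording(
            t=df["time_s"].to_numpy(float)[:n],
            voltage_mv=df["voltage_mV"].to_numpy(float)[:n],
            trial_id=Path(path).stem,
            stimulus=commanded,
        )
        recs.append(rec)
        if measured is None and "hall_V" in df:
            measured = hall_to_angle(df["hall_V"].to_numpy(float)[:n], cal)
    stim = segment_phases(commanded, measured) if measured is not None else commanded
    return stim, recs


def _analyze_protocol(stim: StimulusTrace, recs: list, config: AnalysisConfig):
    raster = build_raster(recs, refractory_ms=config.refractory_guard_ms)
    rate = gcfr(raster, config.sample_rate_hz)
    return raster, rate


def run_pipeline(
    manifest: dict | str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[NeuronReport], pd.DataFrame]:
    """Run every analysis stage for every neuron in a manifest.

    Stage failures are recorded per neuron and the pipeline continues.
    Given the same manifest and configuration the outputs are identical
    across runs.
    """
    config = config or AnalysisConfig()
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    cal_d = manifest.get("calibration")
    cal = (
        HallCalibration(np.asarray(cal_d["voltage_v"]), np.asarray(cal_d["displacement_mm"]),
                        cal_d["lever_arm_mm"])
        if cal_d
        else HallCalibration.default()
    )
    chash = config.config_hash()
    reports = []
    for neuron in manifest["neurons"]:
        report = NeuronReport(neuron_id=neuron["neuron_id"])
        positions, ss_rates = [], []
        velocities, peaks = [], []
        ramp_fits, ramp_fit_velocities = [], []
        ventral_means, dorsal_means = [], []
        base, base_sd_v = None, None
        for entry in neuron["protocols"]:
            if len(entry["trials"]) < MIN_TRIALS:
                report.skipped.append(
                    f"{entry['protocol_id']}: {len(entry['trials'])} trials < {MIN_TRIALS}")
                logger.warning("%s %s skipped: too few trials",
                               neuron["neuron_id"], entry["protocol_id"])
                continue
            try:
                stim, recs = _load_protocol_entry(entry, cal)
                raster, rate = _analyze_protocol(stim, recs, config)
            except JoEncodeError as exc:
                report.errors.append(f"{entry['protocol_id']}: {exc}")
                continue
            report.rejected_trials.update(raster.rejected)
            kind = entry["spec"]["kind"]
            ramps = stim.ramps()
            holds = stim.holds()
            if ramps:
                onset = ramps[0].start / stim.sample_rate_hz
                if base is None:
                    base = baseline_rate(rate, onset)
                    base_sd_v = baseline_sd(rate, onset)
                    report.baseline_hz = base
                means = ramp_mean_rates(rate, stim)
                ventral_means.extend(means["ventral"])
                dorsal_means.extend(means["dorsal"])
            if kind == "variable_position" and holds:
                hold_w = stim.phase_window_s(holds[0])
                level = float(np.median(stim.position_deg[holds[0].start:holds[0].stop]))
                positions.append(level)
                ss_rates.append(steady_state_rate(rate, hold_w))
                try:
                    fit = fit_exponential(rate, hold_adaptation_window(hold_w), "hold",
                                          r2_screen=config.hold_adapt_r2)
                    report.adaptation_rows.append({
                        "protocol_id": entry["protocol_id"], "phase": "hold",
                        "a_hz": fit.a_hz, "tau_s": fit.tau_s, "offset_hz": fit.offset_hz,
                        "r2": fit.r2, "accepted": fit.accepted, "config": chash,
                    })
                except JoEncodeError as exc:
                    report.skipped.append(f"{entry['protocol_id']} hold fit: {exc}")
            if kind == "variable_velocity" and ramps:
                ramp = ramps[0]
                rfit = fit_ramp_velocity(stim.t, stim.position_deg, ramp_fit_window(ramp))
                speed = abs(rfit.slope_deg_s) if rfit.accepted else abs(
                    protocol_from_json_dict(entry["spec"]).ramp_velocity_deg_s)
                if not rfit.accepted:
                    report.skipped.append(
                        f"{entry['protocol_id']}: ramp fit r2 {rfit.r2:.3f} <= "
                        f"{config.ramp_fit_r2}, commanded speed used")
                velocities.append(speed)
                ramp_w = stim.phase_window_s(ramp)
                peaks.append(peak_rate(rate, ramp_w))
                adapt_w = ramp_adaptation_window(rate, ramp_w)
                if adapt_w is None:
                    report.skipped.append(
                        f"{entry['protocol_id']}: rate never fell to 90% of ramp max")
                else:
                    try:
                        fit = fit_exponential(rate, adapt_w, "ramp",
                                              r2_screen=config.ramp_adapt_r2)
                        ramp_fits.append(fit)
                        ramp_fit_velocities.append(speed)
                        report.adaptation_rows.append({
                            "protocol_id": entry["protocol_id"], "phase": "ramp",
                            "a_hz": fit.a_hz, "tau_s": fit.tau_s,
                            "offset_hz": fit.offset_hz, "r2": fit.r2,
                            "accepted": fit.accepted, "config": chash,
                        })
                    except JoEncodeError as exc:
                        report.skipped.append(f"{entry['protocol_id']} ramp fit: {exc}")
            if kind == "stair":
                try:
                    report.hysteresis = loop_area(extract_branches(rate, stim))
                except JoEncodeError as exc:
                    report.errors.append(f"{entry['protocol_id']} hysteresis: {exc}")

        if ventral_means and dorsal_means and base is not None:
            report.direction_label = classify_direction(
                ventral_means, dorsal_means, base, base_sd_v, k=config.direction_k)
        if len(set(positions)) >= 4:
            try:
                report.position_fit = fit_position_linear(positions, ss_rates)
            except JoEncodeError as exc:
                report.errors.append(f"position fit: {exc}")
        if len(set(velocities)) >= 5:
            try:
                fit_rng = np.random.default_rng(config.seed)
                report.velocity_fit = fit_velocity_logistic(velocities, peaks, rng=fit_rng)
                report.model_comparison = compare_velocity_models(
                    velocities, peaks, rng=np.random.default_rng(config.seed))
            except JoEncodeError as exc:
                report.errors.append(f"velocity fit: {exc}")
        if ramp_fits:
            table = tau_vs_velocity(ramp_fits, ramp_fit_velocities)
            report.tau_velocity_rho = table.spearman_rho if table.included else None
        reports.append(report)
        logger.info("neuron %s done (%d rejections, %d skips)",
                    report.neuron_id, len(report.rejected_trials), len(report.skipped))

    cohort = _cohort_table(reports, chash)
    if out_dir is not None:
        _write_outputs(reports, cohort, Path(out_dir))
    return reports, cohort


def _cohort_table(reports: list[NeuronReport], chash: str) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "neuron_id": r.neuron_id,
            "direction_label": r.direction_label,
            "baseline_hz": r.baseline_hz,
            "is_position_encoder": bool(r.position_fit and r.position_fit.is_position_encoder),
            "is_velocity_encoder": bool(r.velocity_fit and r.velocity_fit.is_velocity_encoder),
            "velocity_fit_r2": r.velocity_fit.r2 if r.velocity_fit else np.nan,
            "loop_area_hz_deg": r.hysteresis.loop_area_hz_deg if r.hysteresis else np.nan,
            "tau_velocity_rho": r.tau_velocity_rho if r.tau_velocity_rho is not None else np.nan,
            "n_rejected_trials": len(r.rejected_trials),
            "n_errors": len(r.errors),
            "config": chash,
        })
    return pd.DataFrame(rows)


def _write_outputs(reports, cohort: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out_dir / "cohort_summary.csv", index=False)
    adapt_rows = [dict(row, neuron_id=r.neuron_id)
                  for r in reports for row in r.adaptation_rows]
    pd.DataFrame(adapt_rows).to_csv(out_dir / "adaptation.csv", index=False)
    hyst = cohort[["neuron_id", "loop_area_hz_deg", "config"]]
    hyst.to_csv(out_dir / "hysteresis.csv", index=False)
    fits = []
    for r in reports:
        if r.model_comparison:
            for name, f in r.model_comparison.fits.items():
                fits.append({"neuron_id": r.neuron_id, "model": name,
                             "params": list(f.params), "r2": f.r2})
    pd.DataFrame(fits).to_csv(out_dir / "fits.csv", index=False)
    for r in reports:
        (out_dir / f"{r.neuron_id}.json").write_text(
            json.dumps(r.to_json_dict(), indent=1, default=float))
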