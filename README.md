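# joencode

Analysis of how mechanosensory neurons of the insect antennal Johnston's
organ (JO) encode the **angular position** and **angular velocity** of the
flagellum, from raw per-trial signals to population summaries — together
with a synthetic adapting-neuron generator that validates every estimator
by parameter recovery.

The JO sits at the pedicel–flagellum joint and senses passive flagellar
deflections. Ramp-and-hold stimuli decouple the two kinematic variables: a
ramp imposes a constant angular velocity, a hold a constant position.
`joencode` implements the full analysis chain used for intracellular
recordings from JO afferents:

* **Stimulus** — generation of the three protocols (variable hold position,
  variable ramp velocity, stair), conversion of Hall-sensor voltage to joint
  angle via `θ = arctan(d / L)` (displacement `d` from a calibration table,
  lever arm `L`), velocity traces (3rd-order Butterworth lowpass at 4 Hz on
  the derivative), and ramp-speed estimation by a straight-line fit
  (accepted at r² > 0.9).
* **Spikes** — zero-phase 8th-order Butterworth bandpass (10–2000 Hz),
  trial QC (filtered spike amplitude ≥ 5 mV), detection at 30% of the
  within-trial maximum with a refractory guard, raster assembly.
* **Rates** — Gaussian-convolved firing rate (GCFR; 30 ms SD kernel,
  200 ms support, unit area), baseline / peak / steady-state statistics in
  the standard windows (1-s windows offset 0.5 s from ramp onset and hold
  end), and direction-preference classification.
* **Encoding fits** — steady-state rate vs position (OLS + Spearman screen,
  |ρ| > 0.8, r² ≥ 0.8) and peak rate vs velocity as a logistic
  `y(v) = a / (1 + e^{−b(v−c)})`, ranked against linear, power-law and
  semilog alternatives.
* **Adaptation** — two separate single-exponential fits
  `y(t) = a·e^{−t/τ} (+ offset)` for the ramp phase (from the 90%-of-peak
  crossing to ramp end, screened at r² ≥ 0.75) and the hold phase
  (100 ms after ramp end to 500 ms before hold end), plus τ-vs-velocity
  tables.
* **Hysteresis** — stair-protocol branch overlay at matched hold levels
  (first/last three holds excluded) and the absolute shoelace area of the
  (position, steady-state rate) loop, in Hz·deg.
* **Synthetic data** — a first-order adapting encoder (baseline rate,
  linear position gain, logistic velocity tuning, separate position and
  velocity adaptation states) driving dead-time-compensated Poisson
  spiking, synthetic membrane voltage and Hall-sensor traces, and
  file-based cohort generation.
* **Pipeline** — `run_pipeline(manifest, config)` orchestrates every stage
  over a cohort and emits tidy CSV/JSON tables with a configuration hash in
  every row.

## Worked example

`examples/05_hysteresis.py` simulates a memoryless and an adapting neuron
through the stair protocol and quantifies the loop:

```
memoryless neuron (alpha_p=0.0):
  -0.6 deg: up  61.2 Hz, down  58.2 Hz
  -0.2 deg: up  48.3 Hz, down  48.5 Hz
  +0.2 deg: up  33.6 Hz, down  30.5 Hz
  +0.6 deg: up  22.7 Hz, down  20.2 Hz
  +1.0 deg: up  11.5 Hz, down  11.5 Hz
  loop area = 2.7 Hz.deg over 5 levels

adapting neuron (alpha_p=0.8):
  -0.6 deg: up  40.8 Hz, down  51.3 Hz
  -0.2 deg: up  35.0 Hz, down  48.0 Hz
  +0.2 deg: up  31.2 Hz, down  41.5 Hz
  +0.6 deg: up  30.4 Hz, down  38.6 Hz
  +1.0 deg: up  23.7 Hz, down  23.7 Hz
  loop area = 14.7 Hz.deg over 5 levels
```

Each line gives the steady-state rate at one hold level reached while
ascending (`up`) versus descending (`down`); for the adapting neuron the
branch visited second sits ~10 Hz away from the first because the
position-adaptation state lags the stimulus, and the enclosed loop area
(14.7 Hz·deg) quantifies that history dependence. The memoryless control
collapses to a loop indistinguishable from estimation noise. The other
examples cover protocol construction, spike detection, velocity tuning,
adaptation fitting and the full file-based pipeline, each printing the
numbers it computes.

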