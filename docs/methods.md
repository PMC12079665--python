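# Methods

This note documents the models, windows, numerical choices and known
limitations behind `joencode`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Stimuli and geometry

The stimulus variable is the angle θ of the flagellum about the
pedicel–flagellum joint, dorsal positive and ventral negative. Three
protocols are generated as piecewise-linear commanded traces with exact
analytic velocity:

* **variable position** — ramps at a fixed speed (default 1 deg/s) to hold
  levels of ±0.5 and ±1 deg, 4-s holds;
* **variable velocity** — 1-deg excursions at speeds spanning
  0.2–3.2 deg/s (seven log-spaced levels by default), 4-s holds;
* **stair** — levels spanning 2 deg in 0.4-deg steps traversed at
  0.04 deg/s with 4-s holds. The hold sequence descends from baseline to
  the most ventral level, ascends to the most dorsal, descends back, and
  returns to baseline via two more holds. The lead-in and lead-out legs
  are exactly what the first/last-three-hold exclusion removes during
  hysteresis quantification, leaving one clean ascending+descending cycle.
  Whether the physical rig began its stair at baseline or at the most
  ventral level is not recoverable from the protocol description; the
  quantified cycle is identical under both readings.

Inter-trial rest defaults to 6 s (of the 6–10 s range) and is split evenly
before and after the movement so concatenated trials keep full rests.

The delivered stimulus is read back through a Hall-effect sensor. Sensor
voltage maps to capillary displacement through a monotone calibration table
(piecewise-linear interpolation, extrapolation forbidden) and to angle as
`θ = arctan(d / L)` with lever arm `L` the joint-to-annulus distance. The
equation's algebraic form is taken as the arctangent because `d` is a linear
displacement of a point at distance `L` from the hinge; at the ±1 deg used
here the small-angle error is below 0.01%, so this choice is inconsequential
in practice. Velocity traces are the numerical derivative lowpassed at 4 Hz
(3rd-order Butterworth); because that filter attenuates the velocity peaks,
ramp speed is always reported as the slope of a straight-line fit over the
central 90% of the ramp (a 5% settle margin at each end), accepted at
r² > 0.9.

All filters in the package run zero-phase (forward–backward) so phase
windows and spike times remain aligned; a causal implementation would shift
every windowed statistic by the filter group delay.

## Spike detection

Membrane voltage is bandpass filtered (8th-order Butterworth, 10–2000 Hz,
zero-phase), which removes DC offset and sub-10-Hz drift. Trials whose
filtered spike amplitude is below 5 mV are rejected (such spikes cannot be
distinguished from extracellular pickup); exactly 5 mV is accepted, reading
the criterion strictly. Spikes are local maxima above 30% of the
within-trial maximum of the filtered trace — the threshold therefore scales
with the recording and detection is invariant to gain. A 2-ms refractory
guard (the minimum peak separation) prevents double-counting biphasic
waveforms; when two peaks fall inside the guard the larger is kept. The
guard value is a package default; no minimum inter-spike interval is
prescribed by the protocol itself.

## Firing rates and windows

The Gaussian-convolved firing rate (GCFR) uses a kernel of 30 ms standard
deviation truncated to a **total support of 200 ms** (±100 ms ≈ ±3.3 SD)
and renormalized to unit area. "Width" is read as total support rather than
FWHM, since a 200-ms FWHM would contradict the stated 30-ms SD; the
renormalization keeps the rate unbiased, so the integral of a single-trial
GCFR equals the trial's spike count and the analytic single-spike peak is
`1/(0.03·√(2π))/0.99912 ≈ 13.31 Hz`. Mean and across-trial SD are taken
pointwise; rates are clamped at zero.

Windowed statistics:

* baseline — mean over [ramp onset − 1.5 s, onset − 0.5 s];
* peak — maximum of the trial-averaged GCFR inside the ramp window (the
  mean-then-max order follows the trial-averaged presentation of the
  analysis; the alternative max-then-mean is slightly positively biased);
* steady state — mean over [hold end − 1.5 s, hold end − 0.5 s], i.e.
  seconds 2.5–3.5 of a 4-s hold.

A second ramp statistic, `ramp_plateau_rate`, returns the median of the
trial-averaged GCFR over the ramp's steady segment (100 ms after onset to
60 ms before the end). For a sustained-velocity response this estimates the
same plateau as the peak but without the order-statistic bias of a maximum
taken over a long noisy window (up to +2.5 pointwise SDs for a 5-s ramp);
the recovery studies use it for exactly that reason, while per-neuron
reports keep the literal peak.

Direction preference compares mean ramp-phase rates against
baseline + k·SD, with k = 2 by default and SD the temporal standard
deviation of the trial-averaged rate in the baseline window. A neuron is
ventral-preferring when ventral ramps exceed the bound and dorsal ramps do
not (symmetrically for dorsal); anything else is ambiguous. No numeric
criterion is prescribed for this classification, so k is configurable.

## Tuning fits

Position encoding: ordinary least squares of steady-state rate on hold
position, screened by Spearman's |ρ| > 0.8 and r² ≥ 0.8 (both required for
the encoder flag). Constant rates give an undefined ρ, reported as 0 with a
degenerate flag.

Velocity encoding: the three-parameter logistic
`y(v) = a/(1 + e^{−b(v−c)})` — `a` the saturation rate (Hz), `b` the
steepness (s/deg), `c` the half-activation velocity (deg/s) — fitted by
bounded nonlinear least squares on preferred-direction velocity magnitudes.
Initialization: `a₀ = max y`, `c₀ = median v`,
`b₀ = 4·range(y)/(a₀·IQR(v))`, with ten multistarts jittering `b` and `c`;
bounds `a ∈ (0, 5·max y]`, `b ∈ (0, 100]`, `c ∈ [min v/10, 10·max v]`.
Non-convergence returns a flagged failure (r² = NaN) rather than raising.
The exact parameterization used historically for this relationship is not
recoverable; the canonical three-coefficient sigmoid is adopted, consistent
with the coefficient names and log-axis sigmoid shape. Fits in the pipeline
use raw peak rates (not baseline-subtracted): the published baseline
subtraction is described as a visual-comparison device only.

Model comparison fits linear, power-law (`y = α·v^β`, least squares in
log–log space), semilog (`y = α + β·ln v`) and the logistic, with r² for
the transformed fits recomputed on the original scale, and ranks by r².
A caveat flag marks velocity ranges under two decades, where a power law
cannot be established.

## Adaptation

Two separate single-exponential fits, `y(t) = a·e^{−t/τ} + offset`:

* **ramp phase** — from the first time after the peak at which the rate
  falls to 90% of the ramp maximum, to ramp end; screened at r² ≥ 0.75. A
  monotonically rising rate never crosses 90% and is skipped; a plateau at
  the maximum starts the window at the peak.
* **hold phase** — from 100 ms after ramp end to 500 ms before hold end;
  the screen is configurable between 0.75 (the headline screen) and 0.5
  (the exploratory screen used for position-series fits), since both appear
  in the source analysis.

The named coefficients are only `a` and τ; an additive offset is
nevertheless fitted by default because hold rates decay to a steady state,
not to zero, and without it r² on plateauing data is spuriously poor. A
strict two-parameter mode is provided. Sign convention: in the
two-parameter form τ > 0 is adaptation and τ < 0 an increasing response;
with an offset a rise toward saturation fits exactly as a < 0 with τ > 0,
so the `adapting` classifier uses the initial slope (sign of a/τ), which
reduces to the τ-sign rule in the two-parameter form. Time is re-zeroed at
the window start, making τ̂ invariant to the window's absolute position.
Initialization τ₀ = window/3 with multistarts over ±{0.1,0.3,1,3}/window;
offset₀ = mean of the last 10% of the window.

τ-vs-velocity tables keep only accepted, adapting fits and require at least
three quantifications per neuron, mirroring the population screen.

## Hysteresis

Steady-state rates per stair hold are grouped by approach direction
(ascending = reached by a dorsal-going ramp). The first and last three
holds of the protocol are excluded — interpreted as three holds of the
whole time course, not three per branch, which matches the colour-sequence
description of the quantified cycle. Levels are paired across branches
within 0.05 deg (the delivered-stimulus repeatability); the dorsal-most
turning hold is visited once and is kept as a shared vertex closing the
loop polygon, while any unpaired non-turning level is an error. The loop
area is the absolute signed shoelace area of the polygon (up-branch by
ascending position, then down-branch descending), which equals
|∫up − ∫down| exactly, so identical branches give zero and figure-eight
loops accumulate their lobes with cancellation — the same convention as
integrating the branch difference.

## The synthetic adapting encoder

The generator produces the statistical structure the analysis assumes, with
one first-order adaptation state per pathway:

```
θs = d·θ,  vs = d·v            (d = −1 for ventral-preferring neurons)
Lv(t) = a/(1+e^{−b(vs−c)}) − a/(1+e^{bc})      (zero drive at rest)
λ(t) = max(0, r0 + g_p(θs − α_p·θ̄) + Lv − α_v·L̄v)
```

with θ̄ and L̄v first-order lowpassed copies (time constants τ_p, τ_v,
implemented as exact discrete relaxations). Under a constant stimulus the
excess rate decays as a single exponential with the stated time constant,
so the exponential fits are exactly correct in the noiseless limit and the
recovery studies measure estimator error, not model mismatch.

Spikes are generated by thinning a homogeneous candidate stream in
continuous time with an absolute refractory period (2 ms default, matching
the detection guard). The accept hazard is dead-time compensated,
`h = λ/(1 − λ·t_ref)`, so the realized rate equals λ(t): without
compensation a 150-Hz neuron with a 2-ms dead time would fire ~23% below
its nominal intensity and every recovery comparison would measure that
bias instead of the estimators. Thinning (rather than time rescaling) is
exact under the rectified, discontinuous intensities the model produces.

Default parameters bracket the recorded population's scales: 40 Hz
baseline, velocity-tuning amplitude 110 Hz with c = 1 deg/s and b = 3
(peak ≈ 145 Hz at 3.2 deg/s), position gain 20 Hz/deg, adaptation
fractions 0.5–0.6 with time constants 10–15 s. Synthetic voltage places a
biphasic template (20 mV depolarizing peak, ~1.5 ms wide, with a
hyperpolarizing after-lobe) at spike times over Gaussian noise, optional
sub-1-Hz sinusoidal drift and a −50 mV resting offset; synthetic Hall
traces invert the calibration and add Gaussian sensor noise (0.002 V
default, ≈ 0.002 deg).

What the generator does **not** emulate: bursting, spike-shape variability
and amplitude adaptation, electrode drift faster than 1 Hz, mechanical
resonance of the stimulus linkage, acceleration sensitivity, and any
cross-neuron correlation. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to every
feature of real recordings.

## Recovery-study designs

All studies run at the default 10 kHz sampling with five trials per
protocol unless noted, simulating spike trains directly from λ(t) (the
voltage round trip is validated separately).

* **Velocity tuning (50 neurons)** — pure velocity encoders with
  a ~ U(50, 200) Hz, b ~ U(2, 5), c ~ U(0.5, 2) deg/s, baseline
  U(20, 60) Hz; seven velocities 0.2–3.2 deg/s. The per-velocity response
  is the baseline-subtracted ramp-plateau rate: subtracting the measured
  baseline is required because the generator's additive `r0` is not part
  of the three-parameter logistic being recovered, and the plateau median
  avoids the max-over-window bias discussed above.
* **Hold-phase τ (30 neurons)** — fully adapting position encoders
  (α_p = 1, gains 60–80 Hz/deg, no velocity adaptation so the hold decay is
  a single exponential), 1-deg ventral excursion at 4 deg/s. The fast ramp
  keeps the adaptation state small at hold onset; the fit uses the
  two-parameter mode on baseline-subtracted rates because a 3.4-s window
  cannot separate a free offset from τ of a few seconds at five-trial
  noise.
* **Direction (20 + 20 neurons)** — default gains, excursions to ±1 deg,
  ramp means pooled across both traces before classification.
* **Hysteresis** — memoryless neurons (α = 0, 10 trials, 20 replicates)
  bound the no-memory loop area; the α_p sweep (20 neurons, 0.05–0.95 at
  τ_p = 15 s, 10 trials, 30 Hz/deg gain) checks that loop area rises with
  the adapted fraction. The sweep's trial count and gain are set so the
  per-level estimation noise (≈ 2 Hz·deg of area) sits well below the
  swept signal (≈ 1–23 Hz·deg); at lower power the low-α half of the
  ordering is decided by noise rather than by α_p.

## Numerical notes and degenerate inputs

* GCFR convolution via FFT (overlap-add); tiny negative ripple is clamped.
* Window endpoints are converted to sample indices with ±1e−9 s guards so
  quoted offsets (0.1/0.5/1.5 s) land on exact samples at 10 kHz.
* Least-squares fits run with tight tolerances (1e−12…1e−14) and
  multistarts; degenerate data (constant segments, zero-variance rates)
  return flagged results instead of raising.
* The pandas CSV readers use round-trip float parsing so written traces
  reload bit-exactly.
* Protocol sampling must exceed 4 kHz (twice the spike-band edge);
  10 kHz is the default throughout.

## Limitations

Single-unit intracellular data are assumed (no spike sorting); only GCFR
rate estimation is provided (no adaptive or ISI-based estimators);
power-law adaptation models and multi-exponential decompositions are out of
scope, as are information-theoretic encoding measures and
frequency-response characterization. Supplementary coefficient tables for
the comparison models are not available, so only the model forms are
implemented. The published population values (hysteresis areas, τ values,
neuron counts) derive from recordings that are not deposited and are
therefore not reproduced; validation is property-based as described above.
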