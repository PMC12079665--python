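"""Velocity tuning of a synthetic neuron: peak ramp rates vs ramp speed.

The peak firing rate during constant-velocity ramps saturates with speed;
a three-parameter logistic y(v) = a / (1 + exp(-b(v - c))) describes the
relationship, and linear/power-law/semilog alternatives are ranked by r2.
"""

import numpy as np

from joencode import compare_velocity_models, fit_velocity_logistic, gcfr, peak_rate
from joencode.experiments import raster_from_intensity
from joencode.stimulus import make_ramp_hold, variable_velocity_family
from joencode.synthetic_data import NeuronModelParams, simulate_rate

rng = np.random.default_rng(1)
params = NeuronModelParams(a_hz=110.0, b=3.0, c_deg_s=1.0)
velocities = np.geomspace(0.2, 3.2, 7)

peaks = []
for spec in variable_velocity_family(velocities):
    stim = make_ramp_hold(spec)
    lam = simulate_rate(params, stim)
    raster = raster_from_intensity(lam, stim, 5, params.refractory_ms, rng)
    rate = gcfr(raster, stim.sample_rate_hz)
    peaks.append(peak_rate(rate, stim.phase_window_s(stim.ramps()[0])))

print("velocity (deg/s) -> peak rate (Hz):")
for v, p in zip(velocities, peaks):
    print(f"  {v:5.2f} -> {p:6.1f}")

fit = fit_velocity_logistic(velocities, peaks)
print(f"\nlogistic fit: a={fit.a_hz:.1f} Hz, b={fit.b:.2f}, c={fit.c_deg_s:.2f} deg/s, "
      f"r2={fit.r2:.3f}")
comp = compare_velocity_models(velocities, peaks)
print(f"best of four models: {comp.best_model} "
      f"(velocity range under two decades: {comp.narrow_range_caveat})")
# The fitted half-activation velocity c sits near the generator's 1 deg/s
# and the logistic usually out-ranks the power-law and semilog forms.
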