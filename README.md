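# motionmap

Neural processing is slow: by the time visual information about a moving
object reaches any given cortical stage, the object has moved on. `motionmap`
is a Python toolkit for asking whether — and by how much — the brain's
position code compensates for those delays. It decodes the angular position
of a stimulus moving on a circle from epoched EEG-like recordings, builds
probabilistic spatio-temporal maps of where the stimulus is represented at
each stage of processing, quantifies the forward ("extrapolated") shift of
those representations, and simulates a hierarchical spiking-rate network in
which the same shifts emerge from STDP-shaped feedforward connectivity.

It is aimed at cognitive/computational neuroscientists working with M/EEG
decoding of spatial codes, and at modellers studying neural delay
compensation.

## What it computes

**Circular decoding.** A stimulus at polar angle θ on an invisible circle
(40 positions, 9° apart) is decoded by L2-regularised linear maps onto
(sin θ, cos θ), with the prediction θ̂ = atan2(ŝ, ĉ). Accuracy is the
fractional inverse absolute angular error

  score = (2/π) · (π/2 − ⟨|θ̂ − θ|_circ⟩),

which is 1 for perfect prediction, 0 at chance (mean error 90°) and −1 at
maximal error. Cross-validated timecourses, temporal generalization
matrices, electrode searchlights, frequency-specific and
sequential-stimulus analyses are built on the same stratified folds.

**Probabilistic position maps.** Multiclass LDA classifiers trained per
timepoint on localizer flashes (each position a class) emit 40-way
posterior probabilities for smooth-motion epochs. Point read-outs of a
position distribution w over angles a_j:

* centroid — arg Σ_j w_j e^{i a_j} (certainty = resultant length),
* peak — argmax (ties to the smallest index, flagged),
* FWHM — full width at half maximum of the above-chance region.

**Latency-shift analysis.** Posteriors from decoders trained at each
timepoint of the evoked cascade are recentred on the real-time stimulus
position. Without delay compensation, representations at training time T
lag by velocity × T (the *No-Compensation* line); with perfect
compensation they sit at the real-time position (*Full Compensation*).
The displacement of the peaks/centroids from the No-Compensation line,
and an OLS slope-interaction test against an autocorrelation-only control
(synthesised from lagged localizer responses), quantify progressive
extrapolation. On synthetic data the injected per-stage shift δ_s is a
known ground truth and is recovered to within a few milliseconds.

**STDP network.** A 5-layer firing-rate hierarchy (1,000 neurons/layer, 21
velocity-tuned subpopulations on [−2, 2] cycles/s) driven by a stimulus
bump moving at 1 cycle/s, with leaky dynamics
r(t) = r(t−Δt)·e^{−Δt/τ_m} + (Δt/τ_m)·W·r_below(t−t_delay) (τ_m = 10 ms,
t_delay = 11 ms). Feedforward Gaussian weights are shifted opposite to each
subpopulation's preferred motion direction by β·STDP(v, l), mimicking
receptive-field shifts learned by spike-timing-dependent plasticity. The
*extrapolation magnitude* — how far the activity peak moves from the β = 0
control toward the real-time position — is fitted over a β grid.

## Worked example

```python
import numpy as np
from motionmap import (StimulusGeometry, EvokedCascadeModel,
                       simulate_localizers, simulate_motion, fit_lda_bank,
                       traintime_shift_map, recover_shift_ms)
from motionmap.network import (ExtrapolationNetwork, NetworkConfig,
                               extrapolation_magnitude)

geometry = StimulusGeometry()                   # 40 positions, 360 deg/s
model = EvokedCascadeModel().with_shift(50.0)   # inject a 50 ms shift
localizers = simulate_localizers(geometry, EvokedCascadeModel(), n_reps=5, seed=1)
motion = simulate_motion(geometry, model, n_trials=24, seed=2,
                         reversal_prob=0.0, lock="offset")
bank = fit_lda_bank(localizers, np.arange(75.0, 391.0, 15.0), geometry=geometry)
shift_map = traintime_shift_map(bank, motion, test_window_ms=(-900.0, 0.0),
                                decim=4, geometry=geometry)
v = abs(geometry.velocity_deg_s) / 1000.0
print(f"recovered stage shift: {recover_shift_ms(shift_map.estimates, v):.1f} ms")

net = ExtrapolationNetwork(NetworkConfig(t_delay_ms=11.0))
control = net.simulate(beta=0.0)
run = net.simulate(beta=0.95)
magnitude, per_layer = extrapolation_magnitude(run, control)
print(f"extrapolation magnitude: {magnitude:.3f}")
print("per-layer ratios:", np.round(per_layer[1:], 3))
```

prints

```
recovered stage shift: 53.5 ms
extrapolation magnitude: 0.367
per-layer ratios: [0.37  0.367 0.366 0.365]
```

The injected 50 ms extrapolation shift comes back as 53.5 ms from the
decoding pipeline alone, and the network with β = 0.95 shifts its activity
peaks ~37 % of the way from the no-compensation locus to the real-time
stimulus position, consistently across layers 2–5.

A command-line interface mirrors the library
(`motionmap synth|decode|ldamap|clusterstat|stdpnet|run`); `motionmap run
config.yaml --out results/` executes the whole pipeline with per-stage
caching and a seed/config manifest.

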