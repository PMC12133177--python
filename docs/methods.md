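# Methods

This note documents the models, conventions and numerical choices behind
`motionmap`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Conventions

Angles are degrees of polar angle at the API surface (radians internally
where convenient). Position index 0 sits at 12 o'clock and indices
increase clockwise; positive velocity is clockwise motion. All angular
differences are reduced to (−180°, 180°]; absolute angular errors are
therefore bounded by 180°. The stimulus circle has 40 positions (9°
spacing); smooth motion runs at 360°/s (1 cycle/s), i.e. 3° per frame at
120 Hz and 25 ms between adjacent positions.

Epoched data live in an `EpochSet` (trials × channels × samples, times in
ms relative to the locking event, per-trial event table, channel montage
with adjacency and posterior flags). The interchange format is a NumPy
`.npz` archive plus a JSON sidecar; the round trip is bit-exact.
Re-referencing, artifact rejection and bad-channel interpolation are out
of scope: the generator produces already-clean data, and real recordings
are expected to be preprocessed upstream (an optional EDF reader is
provided for import).

## Decoding model

The circular decoder is a pair of ridge regressions (features → sin θ,
features → cos θ) with the prediction atan2(ŝ, ĉ). Any L2-regularised
linear family satisfies the contract; the regularisation strength defaults
to α = 1.0 and is deliberately not tuned — decoding scores are compared
within analyses run at identical settings, never across regularisers. The
sin/cos predictions are not renormalised before atan2: the two components
are fed in as-is, so a common positive rescaling of both leaves the angle
unchanged but no unit-norm projection is applied.

Cross-validation uses 5 seeded folds stratified by position; a fold
missing any position is an error rather than a silent degradation. PCA
denoising (components covering 99% of variance) is fitted per training
timepoint on the training folds only and applied unchanged to test data.
The temporal generalization matrix is computed under the same folds, so
its diagonal equals the cross-validated timecourse exactly. The
searchlight decodes each channel together with its immediate neighbours
and summarises the timecourse as the mean over 75–250 ms (the summary
window is a documented choice; a peak-over-time summary is available).
Frequency-specific decoding z-scores power across channels per trial,
frequency and timepoint, so only the relative spatial pattern of
oscillatory power carries information and global gain changes are
invisible. There is no monotonicity guarantee relating searchlight
neighbourhood scores to the all-channel score.

Morlet power uses L2-normalised complex wavelets (default 20 linear
frequencies on [2, 40] Hz, cycle counts log-spaced from 3 to 10); the
implementation is checked against mne's `tfr_array_morlet` in the tests.

## LDA position maps

A bank of multiclass LDA classifiers, one per training timepoint, is
fitted on localizer epochs over the posterior channel subset (for a
standard 64-channel montage this is the 17 occipito-parietal electrodes;
for synthetic montages the posterior flags). LDA uses the `lsqr` solver
with analytic covariance shrinkage, so 40-class fits remain stable at
modest trial counts and with degenerate (duplicated) trials. Posterior
vectors sum to one by construction; "position evidence" subtracts the
1/40 = 0.025 chance level and sums to zero.

Recentring maps the absolute position bins onto bins relative to the
real-time stimulus angle using circular linear interpolation (which
preserves the unit sum); counter-clockwise trials are mirrored so that the
positive relative axis always points ahead of the stimulus — without this
mirroring, averaging over motion directions would cancel the directional
shift. Peaks and centroids are extracted from direction-merged,
trial-averaged distributions at 15 ms training-time steps. Ties in the
peak break to the smallest index and are flagged; a flat distribution has
an undefined centroid/FWHM and is flagged rather than guessed. FWHM
interpolates the half-maximum crossings linearly between bins and handles
the circular wrap; if the whole circle stays above half maximum the width
saturates at 360°.

The No-Compensation locus for the EEG-style maps is kinematic:
relative lag = −velocity × training time. The shift-recovery estimator
averages (displacement from that locus)/velocity over training times,
weighted by read-out certainty, after discarding training times whose
certainty falls below half the session maximum — decoders trained between
cascade stages see no pattern, and their read-outs are circularly wrapped
noise whose shift estimates are unbounded (±1 cycle/velocity). The
slope-interaction regression (estimate ~ training time × data type,
ordinary least squares) applies the same gate and expresses every
estimate in the wrap branch nearest the No-Compensation locus, so late
training times cannot alias across ±180°. The centroid is the default
recovery read-out (continuous, unbiased for symmetric distributions); the
peak is reported alongside and gives the same qualitative ordering.

The autocorrelation-only control averages position-ordered,
trial-averaged localizer responses, each lagged by the inter-position
travel time (25 ms at defaults). It contains the spatial autocorrelation
structure of real motion but, being built from isolated flash responses,
no predictive dynamics; its peaks sit on the No-Compensation line.
Trial-averaged (not single-trial) responses are used so its noise level
matches that of the trial-averaged motion analyses.

## Synthetic data generator

The generator produces the statistical structure the analyses assume — no
more. Each of (by default) four processing stages has a Hann-windowed
impulse response starting at its latency (75/150/225/300 ms, 80 ms
duration, amplitude 2) and a position-to-topography map confined to its
own channel subspace: subspaces are random, posterior-weighted and
orthogonalised across stages, and each carries a harmonic-truncated von
Mises position code (circular harmonics weighted by I_h(κ)/I_0(κ),
κ = 8). Orthogonal stage subspaces are what make the temporal
generalization matrix diagonal; a full-rank random mixing cannot be even
approximately orthogonal when channels are few, and measurably biases the
latency-shift recovery through cross-stage decoder leakage. The default
montage has 12 channels with the rearmost 8 flagged posterior — the
smallest layout hosting four orthogonal rank-2 stage codes with posterior
concentration.

Localizer flashes evoke the impulse response times the position
topography; smooth motion evokes the superposition (convolution) of the
impulse response along the stimulus path. The extrapolation shift δ_s
advances stage s's motion response in time — equivalently, the response
to the stimulus occupying position p begins at t(p) + latency − δ_s —
and is the ground truth for parameter recovery. Localizer responses are
never shifted. Noise is i.i.d. Gaussian per channel and sample
(sd 0.25 by default) with optional 1/f^a colouring. The default noise is
set so that a single desk-scale session (5 localizer repetitions per
position, ~24 motion trials) has decoding SNR comparable to the
trial-averaged SNR of a full-scale session with ~20× more trials; scores
then span chance to near-ceiling across the epoch, which is the regime
the analyses are designed for.

What the generator does not emulate: biophysical forward models (dipoles,
leadfields), eye movements, artifacts, oscillatory 5 Hz entrainment, or
continuous recordings (motion epochs are synthesised directly). Passing
tests on this generator therefore demonstrates correctness of the
analysis machinery and recoverability of injected effects under the
stated assumptions — not that real EEG satisfies those assumptions.

## Cluster statistics

The one-sample cluster permutation test thresholds the t-map at the t
quantile of the cluster-forming p (default 0.01, two-tailed), groups
suprathreshold cells under 4-connectivity (optionally wrapping circular
axes, e.g. the position axis), scores clusters by mass (sum of t), and
compares against the sign-flip permutation null of the maximum cluster
mass (default 2^12 permutations, seeded). Cluster p-values are
(1 + #{null ≥ observed}) / (1 + n_perm), honouring the Monte-Carlo
resolution floor. Observed cluster formation and masses are verified
against mne's implementation in the tests; the family-wise error rate is
verified by simulation. Threshold maps run cell-wise one-tailed t-tests
against chance at p < .05 and p < .01; estimator t-tests compute signed
circular differences first and standard t statistics on those.

## Network model

Parameters default to the reference set: 5 layers × 1,000 neurons × 21
velocity subpopulations on [−2, 2] cycles/s; σ_w = σ_p = 1/32 of the
circle; baseline 5 Hz; stimulus intensity 20 (×baseline); Δt = 1 ms for
300 steps; velocity integration over the first 100 steps; τ_m = 10 ms;
t_delay = 11 ms; σ_g shrinking from 2 to 1/8. Two β presets ship — 0.6
(the tabulated value) and 0.3 (the fitted value) — because the source
material is internally inconsistent about which was used; the default is
0.3 and every analysis here sweeps β anyway. The velocity grid likewise
defaults to 21 values (0.2 spacing) with the 0.1-spacing 41-value grid
available by configuration.

The input layer encodes the stimulus as a Gaussian bump directly (no
leaky dynamics), so its representation always peaks at the instantaneous
stimulus position. Higher layers follow the exponential-Euler leaky
update; with constant input I the closed-form fixed point is
(Δt/τ_m)·I/(1 − e^{−Δt/τ_m}) ≈ 1.0508·I at the defaults, which the tests
verify. History before t = 0 is initialised at baseline.

Weight rows are normalised to unit sum, keeping the layer gain at one for
uniform input so the fixed-point analysis holds layer-wise. Because
neurons tile the circle uniformly and all neurons in a subpopulation
share one shift, each weight matrix is circulant; layer input is computed
as a circular FFT cross-correlation rather than a matrix product. The
banded variant truncates the Gaussian kernel at 6σ_w — wide enough that
truncated rates match the dense computation to better than 1e-6 (a 4σ
truncation leaves ~3e-4 tail mass and fails that bound) — and is compared
against an explicit dense circulant matrix in the tests.

The STDP receptive-field shift profile is odd in velocity (zero at v = 0,
mirrored sign for opposite directions) and points opposite to motion. The
base curve's anchor values are configuration inputs originating in prior
work and are not reproduced here; the shipped default rises approximately
linearly to 0.008 circular units per layer transition at 1 cycle/s and
saturates near 0.0125 above ~4 cycles/s, identically across layers
(per-layer scales are configurable). Only the curve's shape matters: the
fitted β multiplier absorbs its overall scale, which is precisely why a
scaling factor is part of the model.

Velocity weights follow a Gaussian over the grid whose mean moves
linearly from 0 to the true velocity and whose width shrinks linearly
over the integration period, delayed by (l−1)·t_delay at layer l, then
remain fixed. The global representation per layer/time is the
velocity-weighted average of subpopulation rates, normalised over
position. Peaks are refined by parabolic interpolation around the argmax
(sub-bin resolution ≈ 10⁻⁴ cycles at 1,000 neurons).

Extrapolation magnitude is measured at the final step: per layer, the
signed circular distance from the β = 0 control peak (the empirical
No-Compensation locus — no closed form exists for the compounding of the
synaptic time constant, so the control run defines it) to the run's peak,
divided by the distance from the control peak to the real-time stimulus
position, averaged over layers 2–5. Layer 1 is excluded: its peak equals
the stimulus position by construction, making the ratio undefined. A
control peak coinciding with the true position at deeper layers is
flagged as degenerate rather than reported. The grid fit sweeps β over
[0.1, 2] in 0.05 steps (magnitude is close to linear in β, so this grid
resolves the target to ~0.01) for one or more transmission delays,
re-simulating the β = 0 control per delay.

## Problem sizes and determinism

The default test/acceptance scale is: 200 localizer trials (5 per
position), 24 motion trials, 12 channels, 250 Hz — about 1.3 s per
synthetic session end-to-end — and the full network at 1,000 neurons
(~0.6 s per simulation). All randomness flows from explicit integer
seeds; the pipeline expands one global seed into per-stage substreams and
stamps every output with the seed and configuration hash. Simulations are
deterministic; identical configurations reproduce outputs byte-for-byte.

## Known limitations

* The generator's stage code is exactly orthogonal across stages; real
  evoked cascades overlap, which would re-introduce some cross-stage
  leakage into training-time analyses.
* The latency-shift recovery assumes a single dominant stimulus velocity
  and constant-speed trajectories between events.
* LDA posteriors are calibrated on localizer amplitudes; motion responses
  with very different gain shift posterior sharpness (not location).
* The network imposes STDP-derived shifts on the connectivity; it does
  not simulate learning, spikes, or recurrent/horizontal connections.
* The cluster permutation test assumes exchangeable subjects under sign
  flips (symmetric null), as usual for this family of tests.
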