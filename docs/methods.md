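# Methods

This note documents the models, parameter choices, and numerical decisions
behind `plantarkit`, and what the synthetic test-bed does and does not show.

## Signal model and the synthetic generator

The package operates on 8-channel plantar-pressure records sampled at a fixed
rate. The sampling rate is fixed at **200 Hz**: the analysis window is defined
as 0.6 s = 120 samples, which pins the rate; it lives in one place
(`config.SAMPLE_RATE_HZ`). One gait cycle is likewise fixed at **120 samples**.

The generator emulates the study conditions rather than a biomechanical gait
model. Each posture has a noise-free cycle template (8 × 120, kPa) built from
half-sine bursts that roll heel → midfoot → metatarsus → toe across the
stance phase:

* **Walking** — burst width 0.35 of the cycle, peak loads ≈ 210–260 kPa on
  the metatarsal (S1, S3, S6) and heel (S7, S8) channels.
* **Running** — compressed contact (width ≈ 0.22–0.24), peaks ≈ 310–380 kPa.
* **Jumping** — a take-off push on the forefoot followed by an airborne gap
  and a landing spike on all channels (peaks ≈ 390–430 kPa).
* **Standing** — constant per-channel load plus noise; no cycle structure.

Midfoot (S4) and toe (S2, S5) channels always peak below the metatarsal and
heel channels, reproducing the regional load concentration seen on a real
sole. **Fatigued** variants of the three movements keep the waveform shape but
are attenuated to 0.8× amplitude and carry 1.5× the phase jitter — a tired
gait is flatter and less regular.

Stochastic components, all drawn from one seeded `numpy` generator:

| parameter | default | meaning |
|---|---|---|
| amplitude jitter | 0.05 | per-cycle multiplicative scale, N(1, 0.05) |
| phase jitter | 0.02 (0.03 fatigued) | per-cycle circular shift, sd as cycle fraction |
| noise | 5 kPa | additive Gaussian per sample, clipped at 0 |

These defaults are the package's standing study conditions; they give a
signal-to-noise ratio a practitioner would call clean lab data (peaks tens of
times the noise floor).

**What the generator does not emulate:** inter-subject variability, sensor
drift and hysteresis, crosstalk, partial/irregular cycles within one posture
bout, footwear effects, or real transition dynamics between postures
(sessions concatenate segments). Consequently, a classifier score on this
test-bed demonstrates that the pipeline — segmentation, labeling, splitting,
training, evaluation — is implemented correctly and that the architecture can
exploit amplitude and shape cues; it does not certify accuracy on human
recordings.

## Sensor model and calibration

The capacitive sensor follows the parallel-plate law C = εA/d, with the
porous dielectric's permittivity the volume-weighted mixture
ε = ε_air·V_air + ε_comp·V_comp (ε_air = 1).

The measured response is summarized by two regional sensitivities of the
relative capacitance change ΔC/C₀ per kPa. The calibration curve is modeled
as **two exact linear segments** joined at the breakpoint:

ΔC/C₀(p) = S_low·p for p ≤ 200 kPa, and 2.52 + S_high·(p − 200) above, with
S_low = 0.0126 kPa⁻¹, S_high = 0.0038 kPa⁻¹, valid over 0–500 kPa. This is
the simplest functional form consistent with two printed slopes; no curvature
between the regimes is modeled. The inverse is the exact piecewise-linear
inverse; readings that map below the **0.4 kPa detection limit are censored
to 0** rather than raising, which keeps streaming conversion robust.
Round-trip identity holds to float precision on [0.4, 500] kPa. Temperature,
hysteresis, and creep are bench properties, not algorithms, and are not
modeled. One curve serves all channels by default; per-channel overrides are
accepted.

## Full-foot surface interpolation

Eight scattered sensors cannot parameterize a tensor-product B-spline
directly. The surface is therefore built in two stages:

1. a thin-plate-spline scattered interpolant through the 8 readings (exact at
   the sensor sites);
2. a cubic B-spline surface (`RectBivariateSpline`, s=0) through an auxiliary
   rectilinear grid of TPS values. The auxiliary grid is a 17-point uniform
   axis per dimension **merged with the sensor coordinates**, so every sensor
   lies on a grid node and the spline reproduces every reading exactly
   (uniform nodes within 10⁻⁶ of a sensor coordinate are dropped to keep the
   knots well separated).

The rendered surface is clamped to [0, 1.25 × max reading]: a physical floor,
plus an explicit ceiling because the thin-plate interpolant can overshoot in
extrapolation zones between the sensor hull and the insole rim. The mask is a
fixed 16-vertex insole silhouette polygon in the normalized frame (x across
the sole, y heel → toe); sensor coordinates approximate the physical layout
and are config-overridable, as nominal positions are not published.

**Pronation.** Standing posture is classified from the load balance of the
metatarsal+heel pairs (S6, S7) vs (S1, S8):
index = (P_L − P_R)/(P_L + P_R), with NORMAL for |index| ≤ 0.15 (the
threshold is a design default, exposed in config). Which pair is medial is
only shown pictorially in insole photographs, so the side convention is a
config flag (`left_is_medial`, default false → an overloaded S6/S7 pair reads
as lateral loading, i.e. underpronation). An unloaded foot returns NORMAL
with index 0 rather than dividing by zero.

## Usage statistics

Zones are left-closed half-open intervals [0,50), [50,200), [200,400),
[400,∞) kPa, so the partition is exhaustive and non-overlapping and zone
times conserve the record duration exactly (in sample counts). The
high-pressure exposure uses the same left-closed comparison (≥ 200 kPa) so it
equals the HIGH + VERY_HIGH zone time identically. Mean regional pressure
excludes the low zone; a channel that never leaves it reports 0 and is
flagged.

Step/jump counting is peak detection (`scipy.signal.find_peaks`) on the
stronger heel channel within annotated movement bouts: local maxima above
100 kPa with a 0.3 s refractory distance. These two constants are invented
counting parameters (the counting algorithm behind the demo numbers is not
published) and are exposed in config. On noise-free synthetic walking the
counter recovers the generated cycle count exactly; with default noise it is
within ±2 %. Calories use a MET model — kcal = MET · mass(kg) · hours · 1.05
with MET 3.5 / 8 / 10 / 1.3 for walk / run / jump / stand — and are an
estimate, not a measurement. Fatigued movements count toward their base
movement (a fatigued step is still a step).

## Segmentation, splitting, and the classifier

Windows of 120 samples slide in steps of 30. With **circular padding**
(default) a window starts at every step multiple and wraps past the end, so
18,000 samples yield exactly 600 windows; the strict mode drops overrunning
windows (597). Circular padding reconciles the printed window count with the
stream length and adds three windows per record that splice the record's end
onto its start — on periodic gait data these are legitimate cycles.

A window spanning a posture change takes the label occupying more than 50 %
of it. An exact tie (or several equally modal classes) goes to the
**later-occurring** class — the more recent evidence — and is logged.

The split is stratified 80/20 (600 → 480/120 per class) with five stratified
folds of the training part (96 per class per fold), deterministic per seed
via scikit-learn splitters.

The classifier is a four-layer 1-D CNN: conv(128, k7) → conv(128, k7) →
pool(2) → conv(256, k7) → conv(256, k7) → pool(2) → flatten → dense(6,
softmax), ReLU activations, same padding, max pooling — 856,838 trainable
parameters for 8 × 120 inputs. Padding, activation, pooling type, optimizer,
schedule, and loss are not dictated by the architecture summary alone; the
choices here (ReLU, same padding, max pool, Adam at 10⁻³ with cosine decay
to 0, categorical cross-entropy, batch 48) make the layer arithmetic
well-defined and the loss/learning-rate trajectories smooth, and they are all
config-exposed. Inputs are standardized by a per-channel z-score whose
statistics come from the **training set only** and are applied as one global
affine map — per-window standardization would erase the amplitude cues that
separate fatigued from normal gait.

The network is implemented directly in NumPy: every convolution pass
(forward, weight gradient, input gradient) is a single BLAS matrix product
over an im2col buffer held channel-major, which keeps a 50-epoch run on the
default dataset (2,880 training windows) around ten minutes on one CPU core.
Training is bit-reproducible for a fixed seed and thread count. The backward
pass is verified against a central finite difference along a random parameter
direction.

Default schedules: 200 epochs is the configured full run; the experiment
helper (`pipeline.run_classification_experiment`) and the acceptance script
use a 50-epoch desk-scale schedule at the full data size (3,600 windows),
which the cosine decay brings to convergence on this test-bed. The end-to-end
suite asserts ≥ 95 % held-out accuracy under those conditions.

Because the estimator follows the scikit-learn contract
(`get_params`/`set_params`, `fit`/`predict`/`score`), hyperparameter search is
the generic grid routine `sklearn.model_selection.GridSearchCV` over the
constructor parameters, and fold-wise cross-validation accuracy can be
computed from `DatasetSplit.folds`; the default experiment reports held-out
test accuracy (one training run) rather than the five-fold figure, which
costs five trainings.

The usage module maps statistics to channels S1–S8 by the anatomical regions
above; finer region names (e.g. navicular) used in some reporting conventions
do not map one-to-one onto the eight channels and are not used.

Correlation analysis (`classifier.correlation_matrix`) computes pairwise
Pearson correlations between per-class mean waveforms and flags pairs above
0.3 as strongly correlated; on the default templates the normal/fatigued
pairs correlate near 1, which is precisely why raw-waveform matching is a
poor classifier here and a learned one is used.

## Alert engine

Rules, with their boundary semantics spelled out:

* **Spike** — any channel **strictly above** 500 kPa; one event per maximal
  run of offending frames.
* **Sustained** — a channel strictly above 200 kPa for **more than** 30 s; a
  run of exactly 30 s is silent.
* **Uneven load** — |P_L − P_R| / max(P_L, P_R) > 0.45 persisting **at
  least** 1 s, with the larger side as denominator (the normalization is not
  dictated by the 45 % figure alone; larger-side is the default and
  configurable). The 1 s persistence floor is a debouncing choice.
* **Overuse** — any channel at or above the 0.4 kPa detection limit for more
  than 30 min without interruption.
* **Fatigue** — at least 3 consecutive windows classified into a fatigued
  class (a debouncing default; exposed in config).

Events are timed in samples and reported in seconds (duration = run length /
rate). The offline scanner is vectorized run-length encoding; the streaming
monitor is an independent per-frame state machine with O(channels) state that
emits an event when its run ends (or at end of stream). Their agreement over
randomized fixtures — and invariance to feeding the stream in chunks of 1, 7,
or 100 frames — is part of the test suite. Degenerate inputs: an all-zero
frame contributes imbalance 0 (no division by zero); raw capacitance input is
rejected until calibrated.

## Problem sizes and limitations

The standing experiment sizes are: 150 cycles × 120 samples per class
(18,000 frames), 600 windows per class, 3,600 windows total, 50 training
epochs — the same data size as the full configuration with a shorter
schedule. Known limitations: synthetic-only validation (no deposited
recordings exist); the six-class test-bed is easier than human data, so its
accuracy is an upper bound on realism; calorie and step figures are estimates
with invented constants; pronation thresholds and sensor coordinates are
plausible defaults, not measured ones; the surface interpolation is a
visualization tool, not a validated pressure reconstruction between sensors.
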