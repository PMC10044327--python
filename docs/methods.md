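# Methods

## Problem setting

The package estimates the ground-reaction wrench — forces Fx, Fy, Fz and
moments Mx, My, Mz at the support surface — from wearable-sensor signals:
ten surface-EMG channels (tibialis anterior, gastrocnemius medialis, peroneus
longus, rectus femoris and semitendinosus of both legs, sensors numbered
1–3, 7, 8 right and 4–6, 9, 10 left) and up to four 6-axis IMUs on the shanks
(1, 4) and thighs (7, 9). Two motion regimes are covered: continuous
posture-control sway (PCM) and discrete stepping episodes (SM). Because EMG
reflects neural drive ~100 ms before force is expressed, EMG-bearing input
patterns carry genuinely predictive information that kinematic sensing alone
lacks.

Coordinates are fixed throughout: x anteroposterior (+forward),
y mediolateral (+left), z vertical (+up), moments right-handed. The two
physical plates of a dual-plate setup are collapsed into a single combined
wrench about a common origin; per-plate decomposition is out of scope.

## Signal conditioning

* EMG (1,111.11 Hz): 4th-order Butterworth band-pass 20–450 Hz, full-wave
  rectification, 4th-order Butterworth low-pass at 3 Hz (the linear
  envelope). Rectification before the low-pass is the standard linear-envelope
  construction; the envelope tracks activation.
* IMU and wrench (148.148 Hz): the same 3 Hz low-pass, per channel.
* Resampling: every-15th EMG sample and every-2nd IMU/wrench sample land on
  a shared 74.074 Hz grid (both ratios are exact integers); the 3 Hz low-pass
  doubles as the anti-alias stage, so plain decimation is exact and the
  output spectrum above 3 Hz sits at the noise floor.
* All offline filtering is zero-phase (forward–backward, SciPy `filtfilt`
  with its default odd-reflection padding). Phase distortion would corrupt
  the EMG-to-force timing that the estimator exploits; a `causal=True` flag
  selects a single forward pass for streaming-style use but is not the tested
  default.

## Estimator

A single LSTM layer with H = 64 hidden units, the four-gate recurrence
written out explicitly (forget f, generation g, input i, output o), followed
by dropout (p = 0.5, training only) and a per-frame affine head H → 6. The
generation gate's nonlinearity is configurable:

* `sigmoid_as_printed` (default): g = σ(·). This is the formulation the
  package reproduces. Since g·i > 0, cell-state increments are always
  positive and c drifts toward positive values; the tanh in h = o ⊙ tanh(c)
  and the signed affine head still let the model regress signed targets.
* `tanh_standard`: the conventional tanh generation gate.

Both modes are implemented, oracle-tested and gradient-checked; neither is
asserted to be "correct".

Training: sequence-to-sequence regression (one wrench frame per input frame),
MSE loss, Adam with batch size 64 and learning rate 0.001, truncated
backpropagation through non-overlapping 128-frame windows (~1.7 s; state
reset at window boundaries, last partial window kept). The session is split
chronologically 50/50; random splitting of overlapping windows would leak
temporal context across the boundary. The last 20 % of the training half is
held out for early stopping (patience 10, max 200 epochs). Weights start
uniform in ±1/√H with the forget-gate bias at +1. Inputs are z-scored with
train-half statistics.

Targets are z-scored internally with train-half statistics and predictions
are mapped back to physical units. This keeps the six channels (forces ~10² N
around a ~700 N Fz offset, moments ~10¹ N·m) equally weighted in the loss and
keeps the printed optimizer settings usable: Adam moves each parameter by
roughly the learning rate per update, so with a handful of updates per epoch
the output bias could never absorb a ~700 N offset in raw units.

Gradients are analytic BPTT, derived by hand for both gate modes and
validated against central finite differences (<1e-4 relative on sampled
parameters). The forward pass is validated against an independent
per-equation recurrence to 1e-10 on 100 random small instances.

## Evaluation

Per-axis error is normalized RMSE in percent. The denominator is the
measured channel's range (max − min) over the evaluation segment — the common
NRMSE convention for signals oscillating about varying baselines — and is
configurable (`range | peak | std`) to match other conventions. Range
normalization makes the score invariant under common scaling and translation
of both series.

Force and moment groups are summarized as mean ± SE with SE = (n−1 sample SD
over the 3 axes)/√3. This convention was chosen because it exactly reproduces
the published summary cells this module's arithmetic mirrors — with two
exceptions in the stepping-motion moment rows (patterns 2 and 6), whose
printed SEs instead match an SD-over-all-six-axes formula; these are
arithmetic slips in the source table, documented by a dedicated test, and the
three-axis convention is used uniformly here. Accuracy is 100 − (GRF group
mean). Display rounding is 3 significant figures; full precision is kept
internally.

## Synthetic data generator

The generator is a first-class, tested component that defines the study
conditions for all benchmarks.

**Kinematics.** An inverted pendulum pivoting at the ankle (CoM height 1 m,
body mass 70 kg) sways with a two-tone quasi-periodic tilt per axis (main
tone 0.25 Hz, secondary tones at 0.62× and 0.41× with 25 % amplitude, seeded
phases; AP amplitude 3°, ML 0.6×). Angles, rates and accelerations are
evaluated analytically on any time grid. SM sessions use a residual 0.4°
quiet-stance sway plus a schedule of round(duration × 0.4 Hz) steps with a
balanced, shuffled left/right/forward sequence and per-step vigour jitter
(±15 %).

**Activations.** Ten series in [0, 1] at 74.074 Hz: baseline 0.08 plus
smooth-rectified antagonist drives phase-locked to the sway evaluated
100 ms *ahead* (plantarflexors on forward lean, TA on backward, evertors on
contralateral lean, weak thigh drives — the ankle strategy dominates). SM
adds direction-specific bursts (fast-rise 0.15 s / slow-decay 0.35 s pulse)
that precede each step's wrench onset by 100 ± 40 ms (uniform per-step
jitter). The ±40 ms jitter keeps the cross-correlation-measured lead inside
[50, 150] ms with margin at the 13.5 ms feature-frame quantization.

**EMG.** Each channel is the activation (interpolated to 1,111.11 Hz)
amplitude-modulating a unit-RMS Gaussian carrier band-limited to 20–450 Hz,
plus baseline white noise (0.05 relative) and a sub-20 Hz drift artifact
(0.1 relative) that the band-pass removes.

**IMU.** Accelerometers see the gravity projection under segment tilt plus
the tangential acceleration at the sensor's lever arm; gyros see segment
angular rate. Shank and thigh segments use distinct tilt gains (0.6 / 1.0)
and lever arms (0.25 / 0.6 m) so shank-only and shank+thigh patterns carry
different information. Steps add a damped 3 Hz oscillation on the stepping
leg. White noise at 0.01 g.

**Wrench.** Fx, Fy = m·L·(angular acceleration) (horizontal CoM inertia);
Fz = m·g minus a small centripetal term plus a 2 %-of-body-weight
plantarflexion modulation (heel unloading); Mx, My from centre-of-pressure
excursion — a kinematic balance term (CoP tracks the CoM projection) plus
ankle-activation differences applied at the 100 ms electromechanical delay;
Mz a small left–right activation asymmetry. SM superposes a signed shear
pulse in the stepped direction (+y left, −y right, +x forward; 15 % of body
weight, with a half-amplitude braking lobe), an unload/reload Fz sequence and
a CoP shift. Plate noise 0.003 of body weight. The activation→wrench map is
deterministic given the config, so a regressor with access to good envelope
estimates can approach zero error — the basis of the parameter-recovery
benchmarks. Noise defaults were set so the trained model's test %RMSE lands
in the 5–20 % regime typical of this estimation problem.

**What the generator does not emulate** (hence what passing benchmarks do and
do not show): no musculoskeletal dynamics (no Hill-type muscles, no
subject-specific anthropometry), no EMG crosstalk or electrode-lift
artifacts, no soft-tissue IMU resonance, linear activation→force coupling
with a single fixed delay, and a stationary noise floor. Results on synthetic
sessions demonstrate that the pipeline is implemented correctly and can
recover a known generative mapping; they do not certify accuracy on human
recordings.

## Problem sizes and numerics

Benchmarks use 120 s sessions (8,889 feature frames; 4,444 train / 4,445
test; ~27 training windows of 128 frames), H = 64, early stopping typically
between 60 and 200 epochs — a few minutes of single-CPU NumPy. Unit tests
use 5–60 s sessions. Degenerate inputs are handled explicitly: zero-variance
channels standardize to zero with a warning (scale 1), constant measured
channels make %RMSE undefined and raise, non-finite training loss aborts
with a diagnostic, truncated decoding windows are skipped with a warning.
Ties in the chronological split floor the training half. Step-onset
detection uses a 5 %-of-body-weight threshold on the median-centred
horizontal shear magnitude, a 500 ms quiet precondition and a 1 s refractory
period; with the generator's pulse shape the threshold crossing lags the true
onset by well under 100 ms.

## Direction decoding

Episodes are cut from the *estimated* wrench (the measured plate signal is
never required), featurized as per-channel means and slopes over the first
200 ms (12 values), z-scored, and classified by a linear one-vs-rest SVM
(C = 1). Held-out scoring splits episodes chronologically within each class
so all three directions appear on both sides. The chance control refits the
decoder on label permutations (default 50) and averages the held-out
accuracy; because accuracies are correlated within each direction cluster,
the control is compared to a binomial band with (classes × permutations)
effective trials.
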