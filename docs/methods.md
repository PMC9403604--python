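# Methods

## Motion representation

The detector never estimates gaze position. Each video is reduced to a
stack of *filtered images*: F_t = |I_t − M_t| with the intermediate
image updated as M_t = (1 − β)·M_{t−1} + β·I_{t−1} and M seeded with
the first frame. The recursion as displayed in the usual shorthand
(seed "M₀ = I₁" with the update referencing I_{t−1} from t = 1) would
read a frame before the clip starts; we resolve it by seeding M with
the first frame and emitting from t = 2, the only reading that yields
T − 1 images from a T-frame clip (599 from 600). The first emitted
image is therefore always |I₂ − I₁| regardless of β.

β controls the memory horizon (effective context ≈ 1/β frames):

* β = 1 degenerates to plain frame differencing,
* β → 0⁺ approaches comparison against the first frame,
* β = 0 is rejected — it is no longer a recursive filter and silently
  turns the representation into a static template match.

Arithmetic is float64 throughout; filtered values lie in [0, 255] by
construction because M is a convex combination of frames. The zero law
(a static clip filters to an all-zero stack) holds to one ulp of the
convex combination, not bitwise, and tests assert it at 1e−12. Stacks
can be exported quantized to 8-bit (PNG sequences) or exact (archives);
the classifier consumes whichever representation the caller passes.

**Sliding windows.** The windowed variant produces one image per window
end-position t = w..T by restarting the recursion on frames
t−w+1..t and keeping only the final F — so each image's receptive
field is exactly the window, a property the tests assert by perturbing
frames outside it. Because the restarted recursion is a fixed linear
combination of the window's first w−1 frames, all windows are computed
as a single tensor contraction; a brute-force restarted loop serves as
the test oracle. Window stride defaults to 1 (overlapping); it is a
parameter, not a hard-coded choice.

## Synthetic video-oculography

The simulator supplies what clinical data cannot: unlimited labeled
clips with exact ground truth. Design choices:

* **Label rule.** A clip is *nystagmus* iff its trace contains ≥ 2
  consecutive beats (slow + fast phase cycles). The generator records
  every beat interval exactly, and rendering derives the label from the
  annotations, so label soundness is a checkable invariant rather than
  a convention.
* **Waveforms.** Jerk slow phases are linear, velocity-decreasing or
  velocity-increasing (exponential envelope, decay constant 8 s⁻¹
  default); slow-phase durations are drawn from the physiological
  150–350 ms range; fast phases complete in 1–2 samples because
  saccadic velocities exceed what 60 Hz sampling resolves — jerk
  waveforms are sampled sawtooths. Pendular waveforms are sinusoids
  whose "beats" are full cycles (they have no fast phase; the
  annotation stores each half-cycle pair so the ≥2-cycle rule applies
  uniformly).
* **Geometry.** Eye rotation maps to pixels at 3 px/degree at the
  reference 240-row resolution, so the default 1–3° beat amplitudes
  span ~3–9 px of motion at 240×320. The gain scales with frame
  height: the same waveform rendered at 15×20 moves sub-pixel
  distances, which is intentional — resolution degradation should
  degrade the signal.
* **Distractors.** Blinks (triangular lid occlusion), sustained lid
  closure, square-wave jerks (step away and back), slow drift, and
  Gaussian position tremor. Distractors alone can never satisfy the
  two-beat rule, so distractor-heavy clips are guaranteed negatives.
* **Dataset composition.** Balanced classes by default; every simulated
  patient contributes both classes (the clinical protocol's bias
  control); 95 % of nystagmus clips are linear jerk and 5 %
  velocity-decreasing, matching the reported clinical waveform mix; a
  configurable fraction of clips (default 44.3 %) is rendered with an
  eccentric gaze offset and tagged accordingly. Negatives are either
  quiescent or carry exactly one beat — the hardest legitimate
  negative.
* **Rendering.** Sclera/iris/pupil as concentric disks, multiplicative
  horizontal illumination gradient, per-pixel Gaussian sensor noise
  (1–4 intensity units by default), quantized to the 8-bit depth a
  real sensor delivers. Everything is seeded; identical inputs give
  bitwise-identical clips.

What the simulator does **not** emulate: iris texture and specular
reflections, torsional movements, head/camera motion, compression
artifacts, and real infrared sensor physics. Passing tests on synthetic
data therefore demonstrate that the representation, training loop and
voting logic work as specified — not clinical-grade accuracy.

## Classifier

Filtered images are area-pooled to 12×16, scaled to [0, 1], and scored
by a backbone from a small registry: the default `tiny_mlp` (one
32-unit hidden layer, Adam, fixed 60-epoch budget, no early stopping)
and `logistic` (linear). Both train in seconds-to-minutes on one CPU;
the registry accepts any factory returning an estimator with
`predict_proba`, so larger architectures can be plugged in without
touching the pipeline. Class imbalance is handled by generating
balanced data rather than loss weighting. Checkpoints are joblib blobs
holding the estimator, its spec and the training log; the log (epoch,
loss) feeds the learning-curve export, whose convergence flag is a
final-window least-squares slope ≥ −ε (ε = 10⁻³/epoch).

## Voting and decision conventions

Soft = mean probability; hard = fraction of per-image votes positive
after binarizing at 0.5; temporal = longest run of consecutive positive
images compared to a required run length (50/100/150/350 frames are the
standard grid), with score = longest-run / stack-length; ensemble =
mean of two video scores. Two tie conventions are fixed and tested:
probabilities exactly at the per-image threshold binarize *positive*,
and video labels use score ≥ threshold. All four rules are monotone in
the per-image probabilities, and increasing the required run length can
only turn positives into negatives — both properties are asserted over
randomized vectors.

## Evaluation

AUROC is computed by threshold sweep + trapezoid and must agree with
the pairwise-concordance definition (ties 0.5) to 1e−12 on randomized
inputs. "Operating point" is ambiguous in screening reports, so
metrics are reported at a default video-score threshold of 0.5 with
the Youden-J-optimal threshold recorded alongside.

The k-fold splitter stratifies by class first (per-fold class counts
within ±1) and spreads each patient's videos round-robin across folds
second, so training portions keep both classes from each patient where
the patient has enough material; infeasible patient constraints are
logged and relaxed, class stratification never is. Note this protocol
deliberately allows the same patient on both sides of a split — it
mirrors the clinical study's balance-within-patient design rather than
leakage-avoiding group k-fold.

Model comparison uses the classical equal-variance unpaired t-test on
per-video probabilities; a two-sided p-value is reported without
multiple-testing correction, and the degenerate zero-variance case is
treated as an exact-equality test. No correction is applied because
single pairwise comparisons against one reference model are reported,
not a family of simultaneous claims.

## Problem sizes

The bundled benchmark is 48 ten-second 60 Hz clips at the native
240×320 resolution from 4 simulated patients (36 train / 12 test):
large enough that the training set covers eccentric-gaze positives —
the hardest class, since a 40 px gaze offset relocates the motion
pattern spatially — while training in minutes on one CPU. The
sampling-rate robustness comparison uses 24 six-second clips at
120×160, evaluated at 60 Hz and decimated to 15 Hz at matched
resolution, averaged over 5 seeds. The training-corpus counting check
renders 300 ten-second clips at 15×20, where rendering is cheap and
the count law (300 × 599) is resolution-independent.

## Known limitations

* The default backbone operates on pooled pixels and is
  location-sensitive: motion patterns at gaze offsets unseen in
  training degrade scores (the synthetic analogue of the clinical
  eccentric-gaze failure mode).
* Decimation-based rate reduction assumes the target rate divides the
  source rate; arbitrary resampling is out of scope.
* Video-container import/export requires an imageio plugin for the
  container; the lossless archive and PNG-directory paths have no
  external dependencies.
* The simulator's noise and illumination levels are plausible rather
  than calibrated against real VOG hardware.
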