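# Methods

## Problem and model

Paroxysmal atrial fibrillation (PAF) manifests in the RR-interval series
as runs of short, erratically varying intervals interrupted by long
compensatory pauses; between episodes the rhythm may be indistinguishable
from normal sinus rhythm. The method treats the HRV signal as a
multi-scale process: a dyadic wavelet decomposition separates the
autonomic frequency bands, and the *shape* of each scale's
coefficient-energy distribution — summarized by a one-parameter entropy —
captures how irregularly energy is spread within that band. Fibrillatory
dynamics raise entropy at characteristic scales; a linear classifier on
those per-scale entropies separates PAF from non-PAF records.

## Pipeline stages and parameters

**Band-pass filter.** 4th-order Butterworth, 5–15 Hz, applied
forward-backward (`filtfilt`). The band concentrates QRS energy and
simultaneously removes baseline wander (< 0.5 Hz), powerline interference
(50 Hz) and most T/P-wave energy, so no separate notch or detrending
stage is used. Zero phase matters: RR intervals are measured between R
peaks of the *original* signal, and a causal filter would bias fiducial
positions by its group delay.

**Pan-Tompkins detection.** Five-point derivative, squaring, 150 ms
moving-window integration, adaptive signal/noise peak levels with
threshold `NPKI + 0.25 (SPKI − NPKI)`, a 200 ms refractory period, and a
search-back pass at half threshold when the gap since the last beat
exceeds 1.66× the running RR average. Detections are corrected for the
known derivative/integrator delay and snapped to the raw-signal maximum
within ±50 ms. Thresholds adapt multiplicatively, so detection is
invariant to amplitude scaling and DC offset. Records shorter than 5 s
(no learning phase) or sampled below 60 Hz are rejected.

**Artifact rejection.** RR intervals outside 0.3–2.0 s (30–200 bpm) or
deviating more than 20% from an 11-beat running median are deleted (not
imputed). The rule is iterated to a fixed point, making cleaning
idempotent; removal of more than 20% of beats sets a data-quality flag.

**Resampling.** The tachogram (RR value vs interval-onset time) is
interpolated with a cubic spline and sampled at `fs_hrv = 2 Hz`. The HRV
signal's physiological content lies below 1 Hz, so 2 Hz sampling makes
the first detail band exactly 0.5–1 Hz and aligns the dyadic ladder with
the standard HRV bands: D2–D3 ≈ HF (0.15–0.4 Hz, vagal), D4–D5 ≈ LF
(0.04–0.15 Hz, sympathovagal balance), D6–D8 ≈ VLF (< 0.04 Hz). A
beat-indexed path (no resampling) is available; it drops the Hz band
interpretation.

**Wavelet decomposition.** db8 (8 vanishing moments), 8 levels, Mallat
cascade with periodization boundary, giving an orthonormal transform:
coefficient energy equals signal energy and reconstruction is exact to
round-off. Exact orthonormality at every level requires the length to be
divisible by 2⁸, so the analysis uses the leading
`floor(n/2⁸)·2⁸` samples — 512 of the ~599 available for a 5-min record
at 2 Hz (a ~4.3-min window). Symmetric padding is available as a config
option; it forfeits exact energy conservation.

**Entropy.** Per level, weights `p_jk = D_jk²/Σ_k D_jk²` (squared
coefficients — detail coefficients are signed, so the raw-coefficient
normalization is not a distribution; an `abs` option uses
`|D_jk|/Σ|D_jk|`). The α-order generalized (Tsallis) entropy
`H = (1 − Σ p^α)/(α − 1)` is used with natural logarithms in its α→1
Shannon limit; values of α within 1e−9 of 1 are routed through the limit
so the sweep grid point α = 1.0 is well defined. H is nonnegative for all
α > 0 and maximal for the uniform distribution. Any α > 0 is permitted:
entropy treatments sometimes restrict α to (0, 1), but the selection
sweep runs to 5.0 and can legitimately settle above 1 (large α weights
the dominant coefficients, small α the rare ones), so the implementation
does not enforce the narrower range.

**Scale selection.** Per scale, a two-sample Welch t-test between
classes (a pooled-variance option exists). Exactly the 3 smallest-p
scales are kept — even when more or fewer clear the 0.05 level — with
ties broken toward the lower scale index; a warning flags any selected
scale with p above the level. Selection runs *inside each training fold*;
a `global_selection` flag reproduces the leaky variant (selection once on
all data) for comparison, and on label-free data it is measurably
optimistic while the per-fold protocol stays at chance.

**Classifier and evaluation.** Features are standardized with statistics
learned on the training fold only, then fit by a linear soft-margin SVM
(C = 1.0; the hard-margin primal describes the separable ideal, but real
folds need not be separable, so a soft margin with moderate C is used).
Evaluation: stratified fivefold cross-validation grouped on record id
(one individual never appears in both train and test), repeated (default
100×) with per-repeat fold seeds spawned from a master seed; test
predictions are pooled into one confusion table per repeat and
correct rate = (TP+TN)/total, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) are reported as mean ± SD over repeats, in
percent.

**α sweep.** Grid 0.1–5.0 in 0.1 steps (50 points). Each record is
decomposed once and its per-level energy distributions are re-summarized
at each α, then scored by the repeated-CV correct rate with the same CV
seed at every grid point; `best_alpha` is the argmax with ties toward
smaller α.

## Synthetic data

The generator emulates the statistical structure the method exploits, at
the nominal study conditions (5-min records; ECG at 128 Hz; benchmark of
25 PAF / 25 distant-from-PAF / 50 normal records):

* **NORMAL**: mean RR 0.8 s, respiratory modulation 0.03 s at 0.25 Hz
  (HF), slower modulation 0.04 s at 0.1 Hz (LF), beat-to-beat Gaussian
  jitter SD 0.015 s — so the HF/LF band machinery is exercised
  meaningfully.
* **DISTANT**: the NORMAL process with doubled jitter (autonomic
  disturbance away from episodes).
* **PAF**: the NORMAL process plus a seeded two-state semi-Markov regime
  switch — AF runs (mean 20 beats, geometric) with mean RR reduced 25%,
  jitter doubled and 8%-per-beat long pauses at +60%, alternating with
  sinus runs (mean 25 beats). This is the minimal mechanism reproducing
  the fast-irregular-runs-plus-pauses signature; it is not an atrial
  electrophysiology model.

ECG synthesis places a sum-of-Gaussians PQRST template at cumulative RR
times plus baseline wander, 50 Hz tone and white noise, and records exact
R-peak samples as ground truth.

What the generator does **not** emulate: real QRS morphology variation,
ectopy, f-waves, non-stationary autonomic drift, sensor artifacts beyond
white noise/wander/powerline, or inter-patient diversity. Passing tests
therefore demonstrate the pipeline's correctness and internal
consistency — detection accuracy, transform fidelity, leak-free
evaluation — not clinical performance on real Holter data, where class
overlap is far larger. On the synthetic benchmark the default effect
sizes make the pairings nearly separable (CV correct rates near 100%),
which is by design: the benchmark is a correctness harness, not a
difficulty benchmark.

## Numerical and design notes

* The generalized entropy is implemented as `(1 − Σp^α)/(α − 1)`; the
  sign is fixed relative to a printed form whose α→1 limit would have
  been −Shannon, contradicting its stated Shannon limit.
* Problem sizes in the test-suite and acceptance script (20 benchmark CV
  repeats; 2–5 repeats per α-sweep grid point; 20 permutation draws × 10
  repeats for the chance control) were chosen to keep estimator noise
  around or below 1–2 percentage points on the reported means.
* Degenerate inputs: an all-zero detail level raises a degenerate-level
  error rather than returning H = 0; flat-line ECG raises a no-peaks
  error; SampEn with zero template matches raises an undefined-entropy
  error rather than returning ±inf.
* The permutation chance control uses the balanced pairing (25 vs 25);
  on an imbalanced pairing a majority-class guess sits at the class
  prior, not 50%, and the control would be uninterpretable.
* Known limitations: the WFDB reader covers formats 16 and 212 with
  single-format records only; the beat template's wave offsets are fixed
  rather than RR-adaptive, so at RR near 0.3 s the T wave of one beat
  overlaps the P of the next (R amplitude still dominates); frequency
  features use a Welch periodogram (128-sample Hann segments, 50%
  overlap) rather than an AR spectrum.
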