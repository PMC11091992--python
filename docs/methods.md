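# Methods

`imckit` analyses concentric knee-extensor isokinetic moment curves
(torque versus knee-flexion angle at a nominal 60°/s over a 90°–10°
range of motion) and links their qualitative morphology to structural
knee injuries.  The pipeline has five stages: synthetic signal
generation, preprocessing, rule-based pattern classification, rater
agreement, and a multinomial association/prediction model.  This note
records the model assumptions, the parameters that matter, and the
design choices made where the underlying taxonomy is qualitative.

## Signal model

A healthy repetition's extension moment curve is modelled as a
parabola in flexion angle with vertex at `peak_angle` (default 50°, the
mid-range) and value `peak_torque` there; with the default mid-range
peak the parabola is symmetric and reaches zero at both ends of the
range of motion.  Angular velocity follows a trapezoid: linear ramps
from 0 to 60°/s over the first and last 8° (`ramp_deg`), so each trace
contains acceleration/deceleration samples below the 50°/s isokinetic
plateau.  Gaussian noise with standard deviation `noise_sd ×
peak_torque` is added per raw sample (raw sampling every 0.4°); torque
is clamped at zero.

The three irregular morphologies are additive kernels on the
normalized curve, each the minimal shape matching its visual
definition:

* **Valley** — a subtractive Gaussian notch (depth `notch_depth`,
  default 0.08 of peak; FWHM `notch_width` = 4°) centred
  `notch_offset` = 8° before the peak in extension order.  A "slight,
  recovering" disturbance: the curve returns to the parabola past the
  notch.
* **Drop** — a subtractive logistic step (depth `drop_depth`, default
  0.30; scale 1°) centred 5° past the peak.  The fall is sharp
  (≈ `drop_depth`/4 per degree at the centre) and never recovers.
* **Shaking** — a sinusoidal flutter of `flutter_cycles` = 5 periods and
  amplitude `flutter_amplitude` = 0.10 spanning the middle 50% of the
  range of motion (30°–70°), which includes the peak.  A Tukey taper
  (α = 0.4) smooths the flutter in and out over the outer 20% of the
  span on each side while leaving four interior troughs at full
  amplitude; a Hann taper was considered and rejected because it leaves
  only two full-amplitude troughs, making the flutter count fragile at
  realistic noise.

The notch/drop/flutter depths quantify the qualitative words "slight"
versus "sharp": they are calibration choices of this package, fixed
once so that the default classifier recovers every canonical artifact
noise-free and ≥95% of trials at 2% torque noise.  Cohort sampling
draws per-trial peak torque (healthy ≈ 190 ± 25 N·m, injured ≈ 160 ±
25 N·m, Shaking trials ≈ 120 ± 20 N·m with an H:Q ratio near 1,
reflecting the reduced output and flexor/extensor imbalance that
accompany that pattern; H:Q is metadata only — flexor traces are not
modelled), jitters the peak angle (σ = 2.5°, clipped to 40–60°), and
emits exactly the requested pattern-by-class counts, which default to
the packaged 114-leg study table.  All randomness derives from a single
root seed through `numpy.random.SeedSequence` spawning.

What the generator deliberately does **not** emulate: eccentric
contractions, fatigue across repetitions, gravity-correction error,
torque-overshoot transients, inter-leg correlation of the bilateral
control legs, or rater-specific visual bias.  Passing the round-trip
tests therefore shows that the classifier implements the taxonomy
faithfully on curves with known ground truth — not that it would match
human raters on clinical dynamometer exports.

## Preprocessing

Each repetition is linearly interpolated onto a 1° flexion grid
(10°–90°, 81 points).  Samples off the isokinetic plateau
(|velocity| < 50°/s, sign ignored) or missing are replaced by linear
interpolation between the flanking valid samples; runs at the grid ends
take the nearest valid value.  Curves are then normalized to the
repetition's own peak moment (per-repetition, not per-trial: the
classifier judges shape within each repetition, and normalization makes
classification invariant to uniform torque rescaling).  Exact peak ties
break toward the angle nearest mid-range, then toward larger flexion.
Only repetitions 2–4 are analysed, avoiding movement-strategy changes
in the first and last efforts; a trial with fewer than four repetitions
is rejected, as is a repetition spanning less than half the range of
motion (mirroring the exclusion of subjects with limited mobility).
Curves are indexed by ascending flexion but read in extension order
(90° → 10°); "before the peak" always means a larger flexion angle.

## Pattern classification

Breakpoints are deviations of the curve from its prevailing parabolic
shape.  Detection proceeds on the smoothed curve (Savitzky–Golay,
quadratic, 5° window — wide enough to suppress sampling noise, narrow
enough to preserve a 4° notch):

1. **Prevailing baseline.**  A quadratic is fitted robustly to the
   interior of the range of motion (≥10° from either end, where
   plateau filling can flatten the trace).  Because every irregular
   morphology is a one-sided shortfall, the fit must settle on the
   prevailing *upper* branch: the iteration starts from the pre-peak
   limb (which post-peak falls leave intact — a naive trimmed fit can
   lock onto a compromise between the two branches of a non-recovering
   drop) and then refits on all interior points within 0.02 below the
   running fit.
2. **Excursions.**  Contiguous regions where the curve falls below the
   baseline by more than half of `min_depth` are breakpoints if their
   worst shortfall reaches `min_depth` (0.03 of peak).  Each carries
   its depth, sharpness (steepest per-degree decrease), recovery flag
   (the curve later re-attains ≥ 90% of its pre-break level), and
   position.  The break *angle* is the fall onset — the first descent
   steeper than the Drop sharpness floor when one exists, otherwise the
   last point on the baseline — because noise relocates the steepest
   point of a long fall by many degrees while the onset is stable.
3. **Positional reference.**  "Before/after the peak" is judged against
   the baseline's vertex rather than the curve argmax: the apex of the
   parabola is flat, so the argmax of a noisy curve wanders several
   degrees.  The vertex is trusted only within 15° of the argmax
   (heavy flutter can tilt the fitted quadratic), and the flutter
   span test below uses the argmax itself.

Decision rules, in precedence order Shaking > Drop > Valley (flutter
subsumes single disturbances, and curves that raters find ambiguous
between Valley and Shaking get a deterministic answer):

* **Shaking** — at least `flutter_min_oscillations` = 3 troughs of
  prominence ≥ `flutter_min_amplitude` = 0.05, measured on the baseline
  residual with `scipy.signal.find_peaks` (detrending is what lets
  troughs on the steep descending limb be scored by their local
  oscillation amplitude), lying within the middle 25–75% of the range
  of motion and spanning the peak.
* **Drop** — a non-recovering breakpoint of depth ≥ 0.20 and sharpness
  ≥ 0.05/°, whose onset lies within `post_peak_window` = 10° after the
  peak (a 2° pre-peak tolerance absorbs onset jitter).
* **Valley** — a recovering breakpoint of depth 0.03–0.15 at or before
  the peak (`near_peak_window` = 15° defines "near").
* **Normal** otherwise.

The flutter amplitude floor of 0.05 is about four standard deviations
of the smoothed noise under the default acquisition noise (2% of peak);
at 0.03 the noise ripple itself occasionally mimics flutter.  All
thresholds live in `ClassifierConfig` and can be overridden from a
YAML/JSON mapping (unknown keys rejected).

A trial is labelled with an irregular pattern only when all three
analysed repetitions receive the *same* irregular label (the
consistency rule); any disagreement yields Normal.

## Rater agreement

Unweighted Cohen's kappa over the four-label space:
κ = (p₀ − pₑ)/(1 − pₑ) with p₀ the fraction of identical labels and pₑ
the product-of-marginals chance agreement.  When both raters are
constant on the same label (pₑ = 1, p₀ = 1) κ is defined as 1.  Verbal
bands use the conventional cut-points with inclusive upper bounds
applied to the raw value: ≤0 no agreement, then none-to-slight (≤0.20),
fair (≤0.40), moderate (≤0.60), substantial (≤0.80), almost perfect
(≤1).  The study's own κ values (0.82 inter-rater, 0.94 intra-rater)
cannot be recomputed because the raw rater labels are unpublished; the
statistic is instead validated on worked examples, symmetry and
permutation properties, an independence-null Monte Carlo, and
scikit-learn's implementation.

## Association model

Injury class (ACL, MS, PFJ, ACL+MS; reference: Healthy) is regressed on
pattern (Valley, Drop, Shaking; reference: Normal) by multinomial
logistic regression on the grouped 4×5 counts.  The reference levels
are forced by the published table layout (odds ratios of each irregular
pattern per injury class against healthy).  With a single categorical
predictor the model is saturated: the MLE coefficients are the log
cross-ratios

    β(pattern, class) = log( n[pattern,class]·n[Normal,Healthy]
                           / (n[Normal,class]·n[pattern,Healthy]) ),

with Wald SE = √(1/a + 1/b + 1/c + 1/d), and the intercept for class k
is log(n[Normal,k]/n[Normal,Healthy]).  `fit_multinomial` computes the
same numbers by Newton–Raphson on the grouped-count log-likelihood
(step-halving safeguard; gradient tolerance scaled by the total count;
covariance from the inverse observed information) and is property-tested
against the closed form on random all-positive tables and against
statsmodels' MNLogit.

Inference is Wald: 95% CIs are exp(β ± z·SE) with z = Φ⁻¹(0.975)
≈ 1.959964 — the exact quantile, not the rounded 1.96, because the
published interval bounds match the exact value (e.g. 197.435 for
ACL/Valley; 1.96 gives 197.444) — and two-sided p-values from the
normal tail of β/SE.  The 40 healthy control legs enter as independent
observations (two per subject); clustering is deliberately ignored to
replicate the published model.  Any zero cell makes the saturated
solution diverge and raises an error; an explicit
`continuity_correction=True` adds 0.5 to every cell (never applied
silently — the packaged table has no zeros, so defaults reproduce the
published values).

One published CI cell is internally inconsistent with its own row
(PFJ/Valley upper bound printed as 74.680 where the estimate and SE
give ≈274.7 — evidently a truncated leading digit); the package reports
the recomputed value.

## Prediction and evaluation

The predictor assigns each pattern the class with maximal fitted
conditional probability — for the saturated model, the modal class of
that pattern's row (Normal→Healthy, Valley→PFJ, Drop→ACL+MS,
Shaking→MS on the packaged table); exact ties break along the fixed
class order (ACL, MS, PFJ, ACL+MS, Healthy), though the packaged table
has none.  Evaluation is in-sample over the same 114 observations, as
in the source analysis (no cross-validation): a 5×5 confusion matrix
(rows actual), per-class recall, precision and F1 with 0/0 scored as 0
(required for the ACL row, which is never predicted), macro-F1 as the
unweighted mean over all five classes including Healthy, and accuracy
as trace/total.

## Numerical choices and degenerate inputs

Interpolation is linear throughout; the velocity filter uses absolute
velocity (plateau membership is sign-independent).  All-zero torque
curves, empty label sequences, length mismatches, non-stochastic rater
confusion rows, unknown config keys, inconsistent cohort counts, and
out-of-range kappa values raise typed errors.  Classification is
deterministic: equal curve and config give equal labels, and identical
specification and seed give bitwise-identical synthetic traces.

## Problem sizes

The association and evaluation stages operate on the fixed 114
observations and run in milliseconds.  Round-trip validation uses the
full 114-trial packaged cohort noise-free plus 200 seeded trials
(50 per pattern) at 2% torque noise — large enough that the 95%
recovery criterion has a comfortable margin (observed ≈ 97–98.5%
across seeds) while the whole suite runs in seconds.

## Known limitations

The classifier's baseline assumes a roughly parabolic prevailing shape;
strongly skewed or plateau-shaped real curves would need a different
baseline family.  The generator's artifact kernels are idealized; real
breakpoints vary in width and asymmetry.  Rater simulation is a simple
per-item confusion model with no item difficulty.  The association
model inherits the source analysis's limitations: in-sample evaluation,
no covariate adjustment, and bilateral control legs treated as
independent.
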