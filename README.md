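# imckit

Qualitative analysis of knee-extensor **isokinetic moment curves**
(IMCs) for injury screening.  On an isokinetic dynamometer the knee is
extended at constant angular velocity (here 60°/s over a 90°–10°
flexion range) while torque is recorded; a healthy extensor curve is a
smooth parabola peaking near mid-range, and characteristic deviations
from it accompany specific structural injuries:

* **Valley** — a slight, recovering notch before or near the peak;
* **Drop** — a sharp fall right after the peak that never recovers;
* **Shaking** — irregular flutter along the middle of the curve.

`imckit` is aimed at biomechanics and sports-medicine researchers who
want this visual taxonomy as a reproducible, testable pipeline: it
generates synthetic torque–angle trials with injectable artifacts,
preprocesses raw repetitions (1° resampling, sub-50°/s plateau
filtering, peak normalization, repetitions 2–4), classifies curves with
a deterministic rule set plus a three-repetition consistency rule,
scores inter-rater agreement with Cohen's κ, and fits the association
between pattern and injury class.

## The model at the core

With pattern *P* ∈ {Normal, Valley, Drop, Shaking} (reference Normal)
and injury class *Y* ∈ {ACL, MS, PFJ, ACL+MS, Healthy} (reference
Healthy), the package fits the multinomial logit

  log [ Pr(Y = k | P) / Pr(Y = Healthy | P) ] = β₀ₖ + βₖᵀ 1{P},

to the grouped 4×5 counts.  The single-predictor design is saturated,
so exp(βₖ,ₚ) equals the contingency cross-ratio
(n_{p,k}·n_{Normal,Healthy})/(n_{Normal,k}·n_{p,Healthy}) with Wald
SE √(Σ 1/n); the Newton solver is verified against this closed form to
1e−6.  The fitted model yields a predictor (modal class per pattern)
evaluated in-sample by confusion matrix, per-class recall/precision/F1,
macro-averaged F1, and accuracy.  The package ships the 114-leg
pattern-by-injury count table this analysis runs on (10 ACL, 17
meniscus, 24 patellofemoral, 23 combined, 40 healthy control legs).

See `docs/methods.md` for the full model description and design
choices.

## Worked example

```python
from imckit import (study_counts, study_labels, fit_multinomial,
                    evaluate, CurveSpec, generate_trial,
                    classify_trial)
from imckit.preprocess import preprocess_trial

# 1. association model on the packaged counts
fit = fit_multinomial(study_counts())
e = fit.entry("ACL", "Valley")
print(f"OR={e.odds_ratio:.3f} SE={e.se:.3f} "
      f"CI=({e.ci_lower:.3f}, {e.ci_upper:.3f}) p={e.p_value:.3f}")

# 2. the pattern -> injury predictor, in sample
confusion, report = evaluate(study_labels(), fit)
print(f"accuracy={100*report.accuracy:.1f}%  macro_F1={report.macro_f1:.3f}")

# 3. signal round trip: a synthetic Drop trial is recovered
trial = generate_trial(CurveSpec(pattern="Drop", noise_sd=0.02, seed=1))
print(classify_trial(preprocess_trial(trial)))
```

prints

```
OR=17.500 SE=1.236 CI=(1.551, 197.435) p=0.021
accuracy=56.1%  macro_F1=0.426
Drop
```

i.e. legs showing a Valley curve have 17.5-fold odds of an ACL rupture
(versus healthy, relative to a Normal curve); the pattern-only
predictor is significantly associated with but only moderately
predictive of the damaged structure (56.1% accuracy, macro-F1 0.426,
and it never predicts isolated ACL rupture); and the classifier
recovers an injected Drop morphology from noisy torque traces.

A command-line interface mirrors the library:

```bash
imckit simulate-cohort --noise-sd 0.02 --seed 1 --out cohort/
imckit classify --cohort cohort/ --out labels.csv
imckit agreement --labels-a labels.csv --labels-b labels.csv --out kappa.json
imckit fit-model --packaged --out odds_ratios.csv
imckit evaluate --packaged --out metrics.json
imckit reproduce-tables --out tables/
```

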