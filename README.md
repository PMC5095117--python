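# hrvscreen

Objective screening for major depressive disorder (MDD) from heart rate
variability (HRV) recorded around a short mental-task paradigm.

Psychiatric screening is usually subjective (interview, self-rating
questionnaires). Depressed patients, however, show a measurable autonomic
signature: a sympathetically shifted baseline (higher heart rate, higher
LF/HF, lower HF) and *blunted reactivity* — during a brief mental stress
task, healthy subjects raise their heart rate and LF/HF and suppress HF,
while patients barely respond. `hrvscreen` implements a screening method
built on that signature: record the electrocardiogram through a
100 s rest → 100 s mental task → 120 s rest protocol, track spectral HRV
indices with a sliding maximum-entropy estimator, summarize each
experimental state by three indices, and feed the nine numbers to a
logistic regression whose logit score is thresholded to make the
screening call.

This package is for physiological-signal and biostatistics researchers who
want to apply, refit, or stress-test such a screen, including a synthetic
cohort simulator with closed-form ground truth.

## Method

For each sliding 30-s window (stepped every 2 s) the R–R tachogram is
cubic-spline resampled to 4 Hz, mean-removed, and fitted with an
autoregressive model by the Burg recursion — the maximum-entropy spectral
method (MEM). Band powers are integrated from the one-sided AR density:
LF (0.04–0.15 Hz), HF (0.15–0.4 Hz), both in ms²; heart rate HR (bpm) is
60000 over the window's mean R–R interval. Each protocol state contributes
the mean of HR, HF and LF/HF over the samples 30–60 s after state onset
(skipping the spectral window's settling), giving the feature vector

x = (HR_before, HR_task, HR_after, HF_before, HF_task, HF_after,
LF/HF_before, LF/HF_task, LF/HF_after).

The screen is a plain logistic regression

log(p/(1−p)) = b₀ + b₁x₁ + … + b₉x₉,

fitted by maximum likelihood (IRLS). The package ships the published
fitted instance (`published_model()`, intercept −5.062, e.g. 0.201 per bpm
of HR_before, +0.312 per unit LF/HF_after) and its published operating
point, logit ≥ 0.28 ⇒ MDD. Evaluation follows standard screening
methodology: Mann–Whitney AUC with a Hanley–McNeil 95% CI, Youden-optimal
cutoff, sensitivity/specificity/PPV/NPV, Cox–Snell and Nagelkerke
pseudo-R², Student's t per feature, and comparison against the Zung
self-rating depression scale (SDS ≥ 50).

## Worked example

```python
from hrvscreen import FeatureVector, published_model, screen

# a reactive (healthy-pattern) subject: HR rises, HF halves during the task
reactive = FeatureVector(hr_before=72.0, hr_task=80.0, hr_after=73.0,
                         hf_before=420.0, hf_task=180.0, hf_after=390.0,
                         lfhf_before=1.1, lfhf_task=3.2, lfhf_after=1.3)
# a blunted subject: faster baseline heart rate, almost no task response
blunted = FeatureVector(hr_before=78.0, hr_task=78.5, hr_after=78.0,
                        hf_before=230.0, hf_task=220.0, hf_after=225.0,
                        lfhf_before=2.2, lfhf_task=2.3, lfhf_after=2.25)

for fv in (reactive, blunted):
    r = screen(published_model(), fv)
    print(round(r.logit, 3), round(r.probability, 3), r.label)
```

prints

```
-3.967 0.019 healthy
0.301 0.575 MDD
```

— the reactive subject scores far below the 0.28 cutoff (probability of
depression 1.9%), while the blunted, sympathetically shifted subject
crosses it.

The same chain is available from the shell: `hrvscreen simulate` writes a
synthetic cohort (per-subject R–R files, schedule, cohort table),
`hrvscreen extract` turns one recording into the nine features,
`hrvscreen fit` / `score` fit and apply a model, and `hrvscreen evaluate`
emits the full diagnostic report (AUC, CI, cutoff, confusion block, SDS
comparison).

## Layout

- `signal_io` — R–R series I/O, R-peak detection from raw ECG, artifact
  cleaning, protocol schedules
- `spectral` — Burg/MEM AR estimation, AR power spectra, band powers,
  sliding HRV indices
- `paradigm` — per-state averaging, nine-feature vectors, feature tables
- `model` — logistic core: published model, scoring, IRLS fitting,
  pseudo-R², serialization
- `evaluation` — ROC/AUC with CI, Youden cutoff, confusion metrics, group
  t-tests, SDS screening and correlation
- `simulate` — synthetic R–R cohorts with group-dependent autonomic
  reactivity and SDS scores

See `docs/methods.md` for modelling assumptions, parameter defaults and
limitations.
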