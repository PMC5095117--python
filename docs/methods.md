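# Methods

This note documents the models, conventions and defaults behind
`hrvscreen`, the choices that were genuinely open, and what the synthetic
tests do and do not establish.

## Signal model and preprocessing

The raw input is either an R–R interval series (ms) or a single-lead ECG
from which R peaks are detected by a derivative-energy detector
(Pan–Tompkins style): 5–30 Hz band-pass, differentiation, squaring, 80-ms
moving integration, adaptive threshold at 20% of the peak energy, beat
time refined to the raw-signal local maximum, refractory period 300 ms by
default. This is the simplest detector adequate for clean recordings; it
is not an arrhythmia-grade QRS detector.

Artifact cleaning flags intervals outside 300–2000 ms or deviating more
than 20% from the median of their 5-interval neighbourhood, replaces them
by the local median of unflagged neighbours, and refuses series with more
than 50% flags. These are conventional HRV-preprocessing limits, exposed
as arguments; cleaning is idempotent by construction (a replaced value
equals its neighbourhood median, so a second pass flags nothing).

## Maximum-entropy spectra

The tachogram RR(t) attaches each interval to the beat that *starts* it
(this matches the generative definition used by the simulator; either
attachment convention is common) and is cubic-spline resampled at 4 Hz
over each analysis window, then mean-removed. An AR model is fitted by
the Burg recursion — the maximum-entropy spectral estimator — which is
stable by construction (all reflection coefficients satisfy |k| < 1).

The power spectral density is **one-sided**,

S(f) = 2 σ² Δt / |1 + Σₖ aₖ e^(−2πi f k Δt)|²,  0 ≤ f ≤ 2 Hz,

so that the integral over [0, Nyquist] equals the process variance and a
sinusoidal R–R modulation of amplitude A ms contributes A²/2 ms² to its
band. Band powers (LF 0.04–0.15 Hz, HF 0.15–0.4 Hz) are trapezoidal
integrals on a 0.001 Hz grid **refined around the AR pole frequencies**:
when a pole sits very close to the unit circle (nearly noiseless
sinusoids) the spectral line is narrower than any fixed grid, and without
refinement band integrals become erratic; tangent-spaced points across
each pole's half-width integrate such lines accurately.

**AR order.** On the standard window (30 s × 4 Hz = 121 samples) the
default order is min(⌊N/10⌋, 12). Higher orders (e.g. ⌊N/3⌋ capped at 24,
a common rule for longer stationary segments) split spectral lines and
produced band-power swings of several hundred percent across windows of a
stationary signal; order 12 gives two clean poles per physiological
oscillation plus noise-floor capacity (measured on a stationary subject:
HF 452 ± 26 ms² against a ground truth of 450). The order is a config
knob (`SpectralConfig.ar_order`) for users with longer windows.

HF is reported in absolute ms², not normalized units — consistent with
the small HF coefficient scale (±0.01–0.02 per ms²) of the published
model. LF/HF is undefined (window flagged invalid) when HF < 10⁻¹² ms².

## Paradigm mapping

Sliding indices are computed every 2 s over the preceding 30 s; window
timestamps are right edges, so the first index falls at t = 30 s. Each
state of the rest(100 s)/task(100 s)/rest(120 s) schedule is summarized by
the mean of valid samples in the **closed** interval
[onset + 30 s, onset + 60 s] (16 samples): the 30-s lead-in discards
windows straddling the state transition, so averaged values reflect the
new state only. Endpoint inclusion is a convention; it moves state means
by at most one sample in sixteen. Feature extraction requires the
recording to cover the schedule and is invariant to a uniform time shift
of recording plus schedule.

## Logistic screen

Features enter raw (unstandardized) — the published coefficient scale
(0.201 per bpm) only makes sense on raw units. Fitting is plain maximum
likelihood via IRLS with step-halving, convergence at |ΔLL| < 10⁻⁸, at
most 100 iterations. Complete or quasi-complete separation (coefficients
past 10³, or fitted probabilities pinned at the labels) raises an
explicit error rather than returning meaningless estimates; an optional
ridge penalty (excluding the intercept) is available for degenerate
fixtures where regularized scores are still wanted. A tie at the cutoff
classifies as MDD (`logit ≥ cutoff`) — conservative for a screen.
Pseudo-R²: Cox–Snell 1 − exp((2/n)(LL₀ − LL₁)), Nagelkerke rescaled by
its maximum.

The published model instance is exposed as `published_model()`. Its
scores on new data are unit-consistent (bpm, ms², ratio) but not
calibrated to any new population; refitting is expected for serious use.

## Evaluation conventions

AUC is computed by the rank (Mann–Whitney) estimator with ties counted
half, which equals the trapezoid under the threshold-sweep curve exactly.
The 95% CI uses Hanley–McNeil; the optimal cutoff maximizes Youden's
J = sensitivity + specificity − 1 over observed scores (positive when
score ≥ cutoff), ties resolved toward the lower cutoff (higher
sensitivity). Percentages are reported to one decimal; raw fractions are
retained on the object. Group contrasts use Student's pooled t (Welch via
a flag); the SDS association is a Pearson correlation.

Of note, the published confusion counts (35/9/37/10) imply
sensitivity/specificity/PPV of 79.5/78.7/77.8%, while the report prints
80.0/79.0/78.0; only NPV (80.4%) is exactly consistent. The package
reports what the counts imply and the test suite documents the
rounding-level discrepancy.

## Synthetic cohorts

The simulator generates beats recursively (next beat one current R–R
interval later) with

RR(t) = mean_rr(state) + lf_amp(state)·sin(2π·0.1·t + φ₁)
      + hf_amp(state)·sin(2π·f_resp·t + φ₂) + ε,  ε ~ N(0, σ²),

phases uniform per subject, f_resp uniform on [0.2, 0.35] Hz, state
changes instantaneous (the paradigm's 30-s settling exclusion absorbs
them). A subject's `blunting` ∈ [0, 1] shrinks every state deviation from
the pre-task baseline; 0 is the full healthy response, 1 no response.

Default group distributions (all config): healthy baseline R–R
900 ± 90 ms, HF amplitude 33 ± 10 ms, LF amplitude 22 ± 6 ms, task
response ×0.88 on R–R, ×0.5 on HF, ×1.5 on LF with per-subject jitter
(sd 0.06–0.09 on the factors), blunting U(0, 0.7); depressed baseline
shifted sympathetically (R–R 865 ms, HF 29 ms, LF 23 ms) with blunting
U(0.3, 1.0). Noise σ = 8 ms, white. SDS = 35 + 25·blunting + N(0, 6)
for patients, 40 + N(0, 6) for controls, clipped to 20–80. Group sizes
default to 44 patients / 47 controls, matching the study design this
simulator emulates. These dispersions were chosen so that a default
cohort is *hard*: fitted-model AUC lands around 0.85–0.94 across seeds
with overlapping groups (a demonstration regime, not an estimate of any
real cohort — the original recordings are not redistributable, so no
distributional parameters could be estimated from them). Substantially
tighter groups become completely separable at n = 91, where plain
maximum-likelihood logistic fitting is undefined.

What the simulator deliberately omits: 1/f broadband variability,
respiratory frequency drift, baroreflex coupling, ectopy, and any direct
link between SDS and spectral indices other than through blunting.
Passing tests therefore establish the *pipeline's* correctness
(closed-form band-power recovery, coefficient recovery, oracle agreement)
and the qualitative group contrast, not clinical performance on real
patients.

## Problem sizes and numerical details

Tests and the acceptance script use the native protocol length (320 s,
~400 beats/subject), paper-sized cohorts (44/47) for end-to-end checks,
n = 4096 for spectral oracle comparisons and n = 5000 for
coefficient-recovery checks. PSD grid step 0.001 Hz plus pole
refinement; spline windows half-open (t − 30, t]; all simulations are
seeded and deterministic given the seed.
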