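# Methods

This note documents the models, conventions and design choices behind
`ramdi`: what the measurement pipeline computes, what the simulator does and
does not emulate, and the statistical conventions of the validation battery.

## The measurement

A measurement session records the magnetically sensed radial-artery pulse on
both wrists at 200 Hz: 5–6 min of baseline, 5 min of supra-systolic cuff
occlusion on one arm, and 5 min after cuff release.  Reactive hyperaemia —
the flow surge and endothelium-mediated dilation that follow release —
transiently increases the pulse amplitude on the occluded arm.  The radial
artery maximum distensibility index (RA-MDI) quantifies the largest relative
amplitude increase over the release window, normalized against the
simultaneous control arm.

Phases are stored as half-open, 0-based sample-index intervals; files carry
time in seconds and indices are reconstructed as `round(t * fs)`.  Signal
amplitude is unitless flux: the sensing physics gives no calibrated unit,
and every downstream quantity is a ratio, so the scale cancels.

## Filtering chain

1. **Mains notch.**  A constrained second-order IIR notch
   `H(z) = b0 (1 + (b1/b0) z^-1 + z^-2) / (1 + a0 z^-1 + a1 z^-2)` with
   zeros on the unit circle at the notch angle and poles at the same angle
   inside it.  The closed form is `b0 = 1/(1 + beta)`,
   `beta = sqrt((1-G^2)/G^2) tan(pi delta_f / fs)`, `a1 = 2 b0 - 1`,
   `b1 = a0 = -2 b0 cos(2 pi f0 / fs)`, where `G^2` is the
   magnitude-squared response at the band edges `f0 ± delta_f/2`.  `A_b`
   (default −3 dB) follows the engineering convention that −3 dB is exactly
   the half-power point (`G^2 = 2^(A_b/3)`), matching the design's stated
   rationale of removing 50% of band-edge noise power; in strict decibels
   the edge level is `1.0034 × A_b` (−3.0103 dB at the default).

   The widely circulated reference coefficient set for this filter
   (`a0 = b1 = 0.0302984`, `a1 = 0.9229900`, `b0 = 0.9614950` at 200 Hz) is
   reproduced by this closed form only with `delta_f ≈ 2.548 Hz` — not the
   nominally quoted 5 Hz stopband — and implies a spectral null at
   50.50 Hz rather than 50 Hz.  The intended design grid is unknown, so the
   package defaults to `f0 = 50 Hz` (null on the mains line) with
   `delta_f = 2.5481 Hz` (the reference pole radius) and exposes both
   parameters; the reference coefficients themselves are available as
   `TABLE_COEFFICIENTS`.

2. **Low-pass.**  Linear-phase windowed-sinc FIR (Hamming window, 101 taps
   at 200 Hz, cutoff 30 Hz, unity DC gain).  The paper-level contract —
   passband ripple ≤ 1% below 24 Hz, stopband ≥ 40 dB above 45 Hz — is
   asserted by tests on the designed response.  Application reflect-pads by
   half the filter length and centre-crops, so output is time-aligned with
   input and has the same length.

3. **DC / baseline removal.**  Subtraction of a centred 10 s moving
   average.  10 s is much longer than any plausible beat period (≥ 0.33 s)
   and much shorter than the phase durations, so beats pass while cuff
   artifacts and slow drift are removed.  The first second of every
   filtered record is flagged as IIR start-up transient and excluded from
   downstream statistics.

## Artifact gating

Sliding-window RMS (2 s windows, 1 s hop) is compared against the median
RMS of the baseline phase; windows outside `[0.2, 5.0] ×` that reference
are marked invalid (`rms_out_of_range`), with a 1 s guard margin on each
side because artifact onsets and tails ramp through the bound.  The window
length matters: over 5 s, a 3 s motion burst averages below the upper
bound.  The numeric range is an engineering default — no published range
exists — and is configurable (`gate.rms_lo` / `gate.rms_hi`).

## Beats, heart rate, envelope

* **Peaks** are local maxima with prominence ≥ 0.3 × a robust amplitude
  scale (median 2 s peak-to-trough range of the baseline phase) and
  spacing ≥ 0.33 s (180 bpm refractory).  The relative threshold makes
  detection invariant to rescaling the input.  Peaks inside invalid
  segments are discarded.
* **Heart rate** is the peak count per 60 s window scaled to beats/min
  (30 s hop); windows with fewer than 3 peaks are flagged invalid.
* **Envelope** (the distension surrogate): per-beat amplitude = peak value
  minus the preceding trough (signal minimum between consecutive peaks),
  averaged in 30 s windows with 15 s hop.  A beat is dropped if any sample
  of its trough-to-peak span is masked invalid — otherwise artifact tails
  leak into the trough.  Windows with fewer than 3 surviving beats are
  omitted, and windows straddling a phase boundary belong to no phase.

## Occlusion verification

Complete occlusion leaves no detectable beats, so the check is spectral
rather than beat-driven: the residual ratio is the pulse-band (0.4–3 Hz)
RMS of the occlusion phase over that of the baseline phase on the filtered
occluded-arm signal, estimated by Welch's method with 30 s segments and
*median* averaging (a single motion burst must not be able to mask a
complete occlusion).  Occlusion is complete iff the ratio is strictly
below 0.1.  At low noise the ratio tracks the true residual pulsation to
within a few percent; at high noise the band noise floor adds in
quadrature.

## The index

No published formula exists for the RA-MDI; the definition here is this
package's own, a direct reading of "maximum dilatation during the 5-minute
release window, adjusted for the control arm":

    raw = max over release windows t of [ E_occ(t)/B_occ − E_ctl(t)/B_ctl ],
    floored at 0,

with `E` the windowed envelope per arm and `B` the median baseline-phase
envelope of the same arm.  Subtracting the control-arm ratio (rather than
dividing by it) cancels additive common-mode drift exactly and common
multiplicative gain drift to first order; a session with no response
scores ≈ 0.  If the control arm is unusable its ratio term is 1 and a
`control_unusable` flag is set.  An alternative index using windowed
per-beat area-under-the-curve ratios instead of envelopes is selectable
(`index.mode = "auc"`); beat AUC (trapezoidal area of |x| between
consecutive beat onsets) is always reported per phase.

**Covariate adjustment.**  The clinical algorithm adjusts for sex, mean
arterial pressure (MAP = DBP + pulse pressure/3), age and the
resting-vs-release heart rates, but publishes no functional form or
coefficients.  The package ships the machinery as a multiplicative factor

    g_sex × (MAP_ref/MAP)^γ1 × (age_ref/age)^γ2 × (HR_rest/HR_release)^γ3

with reference profile male / MAP 93 mmHg / age 40 y, and all exponents
defaulting to **zero**: adjustment is an explicit configuration act, never
a silent default.  Missing covariates yield the raw index with an
`unadjusted` flag.

## Simulator

The session generator is a ground-truth machine, not a hemodynamic model.
Beats are a stylized two-component pulse (raised-cosine systolic peak plus
a dicrotic shoulder riding the downslope; the shoulder's standalone
prominence is < 5% of the beat amplitude so it cannot be mistaken for a
beat).  Both arms share one beat train (one heart, 2% beat-period jitter)
and the common-mode mains and drift noise; white noise and motion bursts
are independent per arm.  During occlusion the occluded arm's amplitude
drops to a 2% residual (not quantified clinically; engineering choice).
After release the envelope gain is

    1 + dilation × exp(−ln²(τ/t_peak) / (2σ²)) + surge × exp(−τ/15 s),

a log-normal dilation bump (unit height at t_peak = 75 s, σ set so the
right side falls to e^(−1/2) 40 s later — dilation is negligible in the
first half-minute, consistent with dilation beginning ~1 min after
release) plus an immediate flow surge (default 0.25, τ = 15 s).  Default
noise: mains 0.5 and drift 0.3 of the pulse amplitude, white σ = 0.02,
motion bursts 0.2/min at 10× amplitude for 3 s.  Annotations carry every
beat time, the true envelope, burst intervals and all parameters.

What it does **not** emulate: beat-morphology changes with vascular tone,
respiratory modulation, arrhythmia, sensor placement drift, day-to-day
physiological variation of the response (replicate pairs share identical
ground truth by contract).  Passing tests therefore demonstrate recovery
of construction-time truth under the modelled disturbances — not clinical
validity on real recordings.

**Cohort generator.**  Per-group covariate and risk-score marginals are
truncated log-normals matched to median/IQR/range summaries (`s =
asinh(IQR/2·median)/z₀.₇₅` on the log scale) or truncated normals for
mean/SD entries, for a 50-control / 46-diabetes cohort.  The index column
is linked to a latent risk driver through a Gaussian copula: with latent
correlation `r = 2 sin(π ρ / 6)`, two standard-normal scores pushed
through strictly monotone continuous marginal transforms have pooled
population Spearman correlation exactly ρ (default target 0.70).  The
latent driver is the pooled normal score of the primary risk score
(10-year Framingham, lipids), drawn from its exact per-group marginal;
other pooled scores are monotone transforms of the same driver (hence
attain the same ρ with the index), diabetes-only engines use the exact
diabetes marginal, and covariates are linked within group at fixed rank
correlations (age 0.5, BMI 0.4, HbA1c 0.7, CIMT 0.6, SBP 0.4, DBP 0.3).
Consequences, verified by tests: link 0 ⇒ pooled correlation 0 despite
group structure; the per-group separation of the index is *induced* by the
link (medians ≈ 0.3 vs 0.7) rather than imposed; the mean sample Spearman
over 500 cohorts sits within ±0.03 of the target.

## Statistical conventions

* **Bland-Altman:** limits are mean ± 2 × sample SD (n−1 denominator) —
  the clinical convention used for this index — not 1.96 SD; the
  multiplier is a parameter.
* **Mann-Whitney:** `U = #{a_i < b_j} + ½ #ties` (second-sample
  referenced; the complement is `n1·n2 − U`).  Exact two-sided p by label
  arrangement enumeration when `C(n1+n2, n1) ≤ 50,000` (handles ties
  exactly), by the classical count recursion (Gaussian-binomial
  coefficients) for tie-free data with `n1·n2 ≤ 400`, else a tie-corrected
  normal approximation without continuity correction.
* **Spearman:** Pearson correlation of mid-ranks; exact permutation p
  (all n! pairings, two-sided by |ρ|) for n ≤ 10, else the t
  approximation.
* **Regression:** ordinary least squares with 95% t-based intervals;
  categorical predictors dummy-coded against a stated reference level.
* **ROC:** empirical curve over all thresholds, positive prediction at
  score ≥ cutoff; AUC by trapezoid (equals `U/(n1·n2)` under the shared
  tie convention — asserted to 1e−12); 95% CI by seeded stratified
  bootstrap (2,000 replicates; the clinical CI method is unstated);
  operating cutoff maximizes Youden's J with ties resolved to the smallest
  cutoff.
* No multiple-testing adjustment; reports carry the fixed note "P value
  < 0.01 is considered significant."

## Numerical choices and degenerate inputs

Zero initial IIR state with the first ~1 s flagged transient; FIR edges by
reflect-pad + centre-crop; envelope/HR/RMS windows on a fixed grid from
t = 0 (hop = window/2), referenced by centre time; occlusion completeness
and high-risk labels use strict/≥ comparisons as documented; flat signals
yield empty peak series (not errors); constant inputs to Spearman are
flagged undefined; rank-deficient regression designs raise an error naming
the collinear columns; all simulator randomness flows from one
`numpy` `Generator` seed, and every stochastic CLI command takes `--seed`.

## Problem sizes in the test suite

The suite simulates full-length 15.5-min sessions (186,000 samples/arm):
single sessions for the chain, recall and occlusion checks, 2 × 20
sessions for the dilation monotonicity sweep, 24 replicate pairs (48
sessions) for the repeatability analysis, 500 replicate cohorts for the
correlation calibration and 1,000 null replicates for the rank-test
type-I calibration — sizes chosen so the whole suite completes in a few
minutes on one CPU while keeping every statistical assertion at a
meaningful sample size.

## Known limitations

* The index definition and the adjustment exponents are this package's
  own; no numerical equivalence with the clinical device's proprietary
  values is claimed.
* The repeatability emulation measures the sensor-noise floor only; real
  between-day variation is physiological and an order of magnitude larger.
  With Gaussian-dominated measurement error, the event "all 24 studentized
  differences within ±2 SD" holds in only ~1/3 of samples for *any* noise
  level — the corresponding test documents this and is expected to show
  one marginal point outside the limits.
* Whether the clinical "area under the curve" is per-beat or whole-phase
  is unstated; the per-beat reading is implemented, with the AUC-ratio
  index as an option.
* A 60 Hz mains region is supported only by setting `notch.f0_hz`; there
  is no adaptive mains tracking.
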