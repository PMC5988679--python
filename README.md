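# ramdi — radial artery maximum distensibility index

`ramdi` measures vascular function from dual-arm reactive-hyperaemia pulse
recordings.  A cuff occludes one radial artery for five minutes; after
release, the flow surge and endothelium-mediated dilation transiently raise
the pulse amplitude sensed at the wrist.  The package implements the full
measurement chain for such recordings — mains-notch, low-pass and baseline
filtering, RMS artifact gating, beat detection, heart-rate and
pulse-amplitude-envelope trends, occlusion verification — and computes the
**radial artery maximum distensibility index (RA-MDI)**:

```
RA-MDI = max over release windows t of [ E_occ(t)/B_occ − E_ctl(t)/B_ctl ]   (floored at 0)
```

where `E` is the 30 s pulse-amplitude envelope on each arm and `B` the
median baseline-phase envelope of the same arm: the largest
control-normalized relative envelope increase during the 5-minute release
window.  A multiplicative covariate adjustment (sex, mean arterial
pressure, age, resting-vs-release heart rate) is available but disabled by
default, since no reference coefficients exist.

The first filtering stage is the constrained second-order notch

```
H(z) = b0 (1 + (b1/b0) z⁻¹ + z⁻²) / (1 + a0 z⁻¹ + a1 z⁻²),
b0 = 1/(1 + tan(π Δf / fs)),  a1 = 2 b0 − 1,  b1 = a0 = −2 b0 cos(2π f0/fs)
```

at the mains frequency (f0 = 50 Hz, fs = 200 Hz, half-power bandwidth
Δf ≈ 2.55 Hz), followed by a 101-tap Hamming-window FIR low-pass at 30 Hz
and subtraction of a 10 s moving-average baseline.

The package is written for researchers in vascular-function biomarkers: a
Python API first (`import ramdi`), a ground-truth simulator for sessions
and for two-group clinical cohorts, the statistical battery used to
validate such an index (Bland-Altman, Spearman, Mann-Whitney U, OLS, ROC),
and a thin `mdi` command line on top.

## Worked example

`examples/process_session.py` simulates one 15.5-minute session with a
known dilation response of 0.5 and measures it:

```
recording: 186000 samples/arm at 200 Hz (15.5 min), 1085 true beats
occlusion complete: True (pulse-band residual 0.023, truth 0.02)
raw index:        0.477   (planted dilation 0.5)
ra_mdi:           0.477   (adjustment factor 1)
qc flags:         (none)
  occluded resting    hr   69.9 bpm   envelope  1.040   valid 100%
  occluded occlusion  hr    nan bpm   envelope    nan   valid 2%
  occluded relaxation hr   68.4 bpm   envelope  1.152   valid 98%
```

The pipeline confirms the cuff actually suppressed the pulse (residual 2%
of baseline, hence no heart rate or envelope during occlusion), recovers
the resting heart rate, and reads an index of 0.477 — slightly below the
planted peak dilation of 0.5 because 30 s envelope windows average over
the rise and fall of the response.

The other examples cover the remaining capabilities, each printing what it
computes and what the numbers mean:

* `examples/filter_design.py` — the notch design, its coefficients next to
  the published reference set, band-edge attenuation (−3.01 dB) and the
  50% power removal of a band-edge tone.
* `examples/cohort_validation.py` — a synthetic 96-subject two-group
  cohort with the index linked to risk scores at Spearman ρ = 0.70, and
  the full validation report (group comparison p ≈ 2e−10, score
  correlations ≈ 0.7, ROC AUC ≈ 0.88–0.92).
* `examples/repeatability.py` — replicate-session agreement, Bland-Altman
  limits within ±0.01 on the sensor-noise floor.

The same operations are scriptable from a shell:

```bash
mdi simulate session --out-prefix sess --seed 4
mdi process sess.csv sess.meta.json --out result.json
mdi simulate cohort --out cohort.csv --seed 3
mdi stats cohort --in cohort.csv --out report.json
```

## Layout

```
src/ramdi/            the library
  signal_model.py       recordings, subjects, phases, cohort tables, I/O
  filters.py            notch design + three-stage filtering chain
  pulse_analysis.py     gating, peaks, heart rate, envelope, occlusion check
  mdi_index.py          phase summaries, the index, covariate adjustment
  simulator.py          ground-truth sessions, replicate pairs, cohorts
  validation_stats.py   Bland-Altman, Spearman, Mann-Whitney, OLS, ROC
  cli.py                the `mdi` entry point
examples/             one narrative script per capability
docs/methods.md       models, conventions and design decisions
tests/                pytest suite with independent brute-force oracles
```
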