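# enigo

Electrical neuroimaging of Go/NoGo inhibition experiments, end to end:

- **synth** — synthetic two-group (SI vs II), two-session (BEG vs END)
  Go/NoGo studies: randomized task schedules with an alternating NoGo
  criterion, ex-Gaussian trial-level behavior with the adaptive
  response-time threshold (block 1 at 380 ms, then 90% of the previous
  block's mean Go RT), and multichannel EEG epochs with plantable
  group/stimulus/session source effects.
- **behavior** — RT outlier rejection (2 SD, per subject), session
  summaries, signal-detection scores (d′ = z(Hit) − z(FA),
  C = (z(Hit) + z(FA))/2 with boundary-rate correction), pooled and
  Welch/Satterthwaite t tests, 2×2 mixed ANOVAs with partial eta squared,
  Levene's test, Lilliefors-corrected normality testing, and
  speed–accuracy-tradeoff correlations with Holm step-down correction.
- **preprocess** — zero-phase second-order Butterworth filtering
  (0.1 Hz HP, 40 Hz LP, 50 Hz notch), epoching (−100…+500 ms, half-open
  window), HIT/CR relabeling, per-block trial-count matching, ±80 µV
  artifact rejection, averaging, and spherical-spline bad-channel
  interpolation.
- **masstats** — electrode × time mixed-ANOVA interaction maps with
  sustained-period detection (≥10% of electrodes, ≥11 contiguous frames,
  p < 0.05) and a permutation-calibrated duration criterion.
- **headmodel** — spherical stand-in head model: ~3005-node 6-mm source
  grid in a spherical shell, a 64-channel 10-10 montage fixture, and an
  analytic three-shell (brain/skull/scalp, 1 : 1/80 : 1) dipole lead field.
- **inverse** — minimum-norm distributed inverse with local
  autoregressive-average (LAURA-style) neighbor weighting and depth
  compensation; period-averaged topographies in, scalar current densities
  out.
- **srcstats** — node-wise 2×2 ANOVAs, cluster formation under the
  8.5-mm connection radius with a spatial-extent criterion (k_E ≥ 15),
  and AlphaSim-style Monte-Carlo calibration of that criterion (6-mm FWHM
  smoothing).
- **pipeline** — orchestrates all stages; detected sensor-space periods
  automatically become the source-analysis periods of interest; emits a
  JSON + Markdown report.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked behavioral
examples, Monte-Carlo cluster calibration, localization accuracy, task
generator exactness, and property-based substitutes for data-dependent
results). The statistical routines are all verified against independent
brute-force oracles.

## CLI

```bash
enigo simulate --seed 7 --out sim/              # behavioral study TSV
enigo behavior --log sim/study_log.tsv --out report.json
enigo headmodel --out lf.h5                     # grid + lead field
enigo clusterthresh --fwhm 6 --n-iter 10000 --seed 1
enigo run --seed 7 --out results/               # full pipeline + report
```

`enigo run` accepts a YAML config (`--config cfg.yaml`) mirroring
`enigo.pipeline.RunConfig`; all defaults equal the analysis parameters
described above.

## Design notes

- Epoch windows are half-open `[t0, t1)`: 614 samples at 1024 Hz for
  −100…+500 ms.
- Artifact rejection uses a strict `> 80 µV` rule; a sample at exactly
  80 µV is kept.
- The spherical shell replaces anatomical gray-matter geometry, so node
  coordinates are geometric, not anatomical.
- Baseline correction is off by default and available as a flag.
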