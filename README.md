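# medstate

Subject-specific decoding of medication state (OFF vs ON) from motor-cortical
band power, together with the clinical factor scoring and statistics needed to
relate decoding accuracy to symptom change. A synthetic-data generator stands
in for real recordings, so the entire pipeline is runnable and testable
offline.

## What it does

- **`medstate.synthetic`** — generates two-condition, two-hemisphere
  source-space time series (band-limited oscillations over a 1/f background,
  white noise, optional high-frequency muscle-artifact bursts) and 33-item
  motor-exam ratings whose improvement is coupled to the spectral effect
  magnitude. Fully deterministic given a seed.
- **`medstate.clinical`** — 7-factor motor scoring of the 33 exam items
  (raw sums and weighted averages on the 0-4 item scale) and the OFF-ON
  change per factor. Per-item weights can be overridden from a CSV.
- **`medstate.spectral`** — high-frequency epoch rejection (mean 50-330 Hz
  power > 1.5 sd above the mean), order-18 Butterworth lowpass at 48 Hz,
  5 s snippets with 50 % overlap, per-snippet z-normalization, Welch spectra
  on a 0.5 Hz grid, and mean power in the 7-13, 13-20, 20-30 and 35-45 Hz
  bands.
- **`medstate.decoder`** — per-subject linear soft-margin SVM with class
  balancing, standardization, contiguous unshuffled stratified 10-fold
  cross-validation, per-fold weight profiles and a fold-averaged ROC.
- **`medstate.bayesopt`** — 1-D Bayesian optimization (GP surrogate,
  expected improvement) of the SVM box constraint over [1e-6, 1e+6] in at
  most 30 objective evaluations.
- **`medstate.stats`** — paired signed-rank tests (exact by enumeration for
  small n), Bonferroni, tie-corrected Friedman, Benjamini-Hochberg step-up,
  Spearman correlation matrix, and OLS regression of factor change on
  decoding accuracy with 95 % confidence bands.
- **`medstate.pipeline` / `medstate.cli`** — YAML-configured end-to-end
  orchestration with per-stage seed derivation and bit-reproducible reruns.

## CLI

```sh
# full synthetic run: simulate -> features -> decode -> clinical -> stats
medstate all --out runs/demo --n-subjects 20 --seed 0

# or stage by stage
medstate simulate --out runs/sim --n-subjects 4 --seed 0
medstate features --recordings runs/sim/recordings.h5 --out runs/feat
medstate decode   --features runs/feat/features.csv --out runs/dec
medstate stats    --ratings runs/sim/ratings.csv \
                  --decoding runs/dec/decoding.csv --out runs/stats
medstate report   --results runs/demo
```

Each run persists its configuration (`config.yaml`), per-stage CSV/JSON
artifacts and a Markdown report; rerunning with the same configuration
reproduces every artifact byte-identically.

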