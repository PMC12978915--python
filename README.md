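# emgmap

Multimuscle, multimetric surface-EMG (sEMG) analysis of protocol-structured
mammography compression sessions: from raw 14-channel recordings (or a fully
synthetic cohort) to a 10-metric feature table, Bonferroni-corrected paired
contrasts, a muscle × metric sensitivity matrix, and a per-view percent-change
activation map.

## What it does

A *session* is one participant's set of labeled segments following the
two-paddle protocol: controls `C1`, `C2`, `C3` (nominally 2 min) and eight
15-second compressions (`F_RCC`, `F_LCC`, `F_LMLO`, `F_RMLO` with the flat
paddle, `C_*` with the curved paddle), recorded on 7 muscle pairs
(sternocleidomastoid, upper trapezius, deltoid, infraspinatus, teres major,
serratus anterior, external oblique; left and right).

The pipeline stages:

1. **session_io** — session data model, validation, and plain-CSV interchange
   (long and wide dialects, bit-exact round trip, `# fs_hz=` header).
2. **preprocess** — 1.5 s edge trimming, zero-phase 4th-order Butterworth
   bandpass (20–500 Hz), RMS envelopes (250 ms windows, 50% overlap), and
   control-referenced normalization: each channel is divided by the standard
   deviation of its reference control's RMS envelope (C2 for the flat family
   and C1/C2, C3 for the curved family), which pins the control stdRMS at
   exactly 1.
3. **features** — 5 time-domain metrics (meanRMS, stdRMS, SSC/s, ZC/s, WFL)
   and 5 frequency-domain metrics (meanFreq, medianFreq, spectral entropy,
   drop-in-power, spectral deformation Ω₂/Ω₁) from a Welch PSD (128-sample
   Blackman window, 50% overlap, 20–500 Hz band).
4. **stats** — paired t-tests over four contrast families
   (compression-vs-control m=8, paddle-vs-paddle m=4, angle-vs-angle m=4,
   control-vs-control m=2) with Bonferroni correction, advisory Lilliefors
   normality p-values, and the sensitivity matrix (fraction of the 8
   compressions significant per muscle × metric).
5. **synthetic_data** — reproducible synthetic cohorts: spectrally shaped
   Gaussian baseline noise, ipsilateral amplitude gains (deltoid-dominant by
   default), a narrowband low-frequency admixture that shifts activated
   spectra downward, and lognormal between-participant variability.
6. **report** — group tables (mean (SD) with significance marks), the
   percent-change map (flat+curved pooled per view), and the `run_pipeline`
   driver writing all artifacts as CSV/JSON.

## CLI

```sh
emgmap simulate --seed 7 --n 25 --out cohort/          # synthetic cohort CSVs
emgmap extract  --input cohort/ --out features.csv     # preprocess + features
emgmap compare  --features features.csv --family compression_vs_control --out comparisons.csv
emgmap report   --features features.csv --out artifacts/
emgmap run      --config config.yaml                   # full pipeline
```

`config.yaml` example:

```yaml
simulate: {seed: 7, n_participants: 25}
preprocess: {trim_s: 1.5, band_low_hz: 20, band_high_hz: 500}
psd: {nperseg: 128, window: blackman}
stats: {alpha: 0.05, families: [compression_vs_control]}
out: artifacts
```

Artifacts: `features.csv`, `comparisons.csv`, `sensitivity_matrix.csv`,
`group_table.csv`, `percent_change.csv`, `percent_change_max.csv`,
`manifest.json`. Identical seeds give byte-identical outputs.

## Notes on conventions

- The normalization scale and the stdRMS feature use the sample standard
  deviation (ddof=1) of the same envelope, so reference controls sit at
  stdRMS = 1 up to float rounding.
- In assembled feature tables WFL is reported per second; the raw
  `time_domain_features` operation returns plain total variation.  Controls
  and compressions have very different durations, and a duration-scaled
  metric would register as a spurious effect in every paired contrast.
- ZC/SSC thresholds default to 0 (pure sign logic) and are configurable.
- Frequency metrics are invariant under amplitude scaling; amplitude metrics
  scale as 1/s under normalization.
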