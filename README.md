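# biprkit

Analysis toolkit for the **blink-induced pupillary response (BIPR)** and its
twin-study heritability:

- **Preprocessing** (`biprkit.eyetrack`): EyeLink-ASC-dialect sample parsing,
  up-sampling to 1 kHz, blink detection (40–400 ms pupil loss) versus eye
  closures, cubic interpolation of blink gaps, zero-phase 0.02–4 Hz FIR
  band-pass, decimation to 100 Hz.
- **Vigilance staging** (`biprkit.vigilance`): per-run Vigilant / Drowsy /
  VeryDrowsy / Discarded labels from the pupil-loss fraction
  (<10% / 10–40% / 40–75% / >75%), with Drowsy+VeryDrowsy merged to AllDrowsy.
- **BIPR features** (`biprkit.bipr`): blink-locked −2…+3 s epochs baselined to
  the −200…0 ms mean, per-run average profiles, D/C peak times and amplitudes,
  the D−C time difference and magnitude drop, blink rate per eyes-open minute,
  mean blink duration, mean pupil size, and the 2×IQR outlier screen.
- **Reliability statistics** (`biprkit.stats`): ICC(2,k) via REML on the
  two-way crossed random-effects model (unbalanced run counts supported;
  equals the Shrout–Fleiss mean-square formula on balanced tables),
  within-subject correlations of z-scored measure vectors, and the paired
  vigilant-vs-drowsy one-way ANOVA with the 0.05/9 Bonferroni threshold.
- **Twin genetics** (`biprkit.twin`): intra-pair correlations, ACE/ADE family
  choice from the correlation pattern, maximum-likelihood variance-component
  fits with age/sex/vigilance covariates, nested χ² path-dropping, AIC
  selection (both −2LL+2k and the χ²−2df flavour), and profile-likelihood
  95% CIs.
- **Synthetic data** (`biprkit.synthetic`): seeded generators for pupil runs
  (known blink/closure lists plus a Gaussian-bump response kernel), twin
  cohorts under specified A/C/D/E fractions, and reliability tables — every
  downstream stage has a parameter-recovery test surface.
- **Pipeline** (`biprkit.pipeline`): end-to-end orchestration from raw or
  synthetic runs to the reliability, state-comparison and heritability
  reports, deterministic under a single seed.

## CLI

```sh
biprkit simulate --n-runs 3 --duration-s 300 --seed 1 --out-dir runs/
biprkit preprocess runs/run1.asc --out-dir out/
biprkit measures runs/run1.asc
biprkit reliability table.tsv
biprkit heritability pairs.csv --out ledger.json
biprkit run-all --config study.yaml --seed 7 --out-dir reports/
```

`run-all` without `--config` executes the default synthetic study
(44 MZ + 36 DZ twin pairs, 4 runs per subject) and writes
`measures.tsv`, `classification.tsv`, `reliability_icc.tsv`,
`state_anova.tsv`, `heritability.json` and `manifest.json`. Every analysis
tunable (vigilance thresholds, peak windows, filter cutoffs/orders, minimum
epochs, outlier multiplier, α family size) is exposed in the YAML config.

## Notes

- A run must be longer than the 0.02 Hz high-pass filter (150001 taps at
  1 kHz with the default order factor 3, i.e. ≥ ~150 s); shorter runs raise
  `TraceTooShortError` with the minimum stated. The order factors are
  configurable.
- Mean pupil size is computed on the interpolated, unfiltered trace: the
  0.02 Hz high-pass removes the mean, so the filtered stage cannot carry it.
- Closure intervals are bridged only transiently for filtering and are never
  interpolated as data; only blink gaps are filled.
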