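# eemfac

An end-to-end pipeline for PARAFAC analysis of fluorescence
excitation–emission matrices (EEMs) of dissolved organic matter, with a
synthetic data generator so every stage is testable against known ground
truth:

- **`eemfac.synth`** — synthetic multi-source EEM datasets: Gaussian-band
  fluorophore components (a seven-component humic/protein-like reference
  library is built in), log-normal concentration designs, inter-source peak
  shifts, Rayleigh/Raman scatter ridges, inner-filter attenuation, noise,
  and cocktail (contaminated) datasets.
- **`eemfac.preprocess`** — the standard correction chain, in order:
  absorbance-based inner-filter correction (`10^((A_ex+A_em)/2)`),
  Raman-area normalization (Ex 350 nm, Em 381–426 nm band of a blank),
  scatter excision to a missing-value mask, per-sample total-signal
  (Frobenius-norm) normalization with exact reversal on the scores, and
  leverage/residual outlier flagging.
- **`eemfac.parafac`** — non-negative trilinear decomposition by
  alternating least squares (multistart, seeded, EM-style imputation of
  masked pixels), core-consistency diagnostic, split-half validation, model
  selection over a component range, F_max, leverage.
- **`eemfac.compare`** — Tucker congruence coefficients, similarity
  classification (≥ 0.95 "equal", 0.85–0.95 "fair"), optimal
  (Hungarian) component matching across models, cross-model F_max
  regression.
- **`eemfac.peaks`** — peak-picking sensitivity analysis: per-pixel R²/slope
  maps of intensity against component F_max, peak-monitoring reports, and a
  clean-vs-contaminated experiment driver.
- **`eemfac.io` / `eemfac.cli`** — plain-CSV dataset and model formats,
  YAML-configured pipeline driver, and the `eemfac` command.

## CLI

```sh
eemfac simulate  --out data/ --components G2,G6,G7 --n-samples 30 --seed 1
eemfac preprocess --in data/ --blank blank.csv --out corrected/
eemfac fit       --in corrected/ --ncomp 3:7 --starts 10 --seed 1 --out model/
eemfac validate  --in corrected/ --ncomp 3
eemfac compare   --model-a modelA/ --model-b modelB/ --out matches.csv
eemfac peakmap   --model model/ --data corrected/ --out maps/
eemfac cocktail  --config cocktail.yaml --out cocktail_out/
eemfac run       --config run.yaml --out run_out/
```

`run` takes a YAML config, e.g.:

```yaml
seed: 1
simulate:            # or: input_dir: path/to/dataset
  components: [G2, G6, G7]
  n_samples: 30
  noise_sigma: 0.01
preprocess:
  do_ife: true
  do_normalize: true
fit:
  f_min: 3
  f_max: 7
  n_starts: 10
```

Dataset directories hold one CSV per sample (first row = excitation
wavelengths, first column = emission wavelengths, blank cell = missing
pixel), a `manifest.csv`, optional per-sample absorbance CSVs and a
`truth.json` with the generator's ground truth. Model directories hold
`model.json`, `scores.csv`, `em_loadings.csv`, `ex_loadings.csv`.

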