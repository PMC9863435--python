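# dermivivc

Analysis pipeline for establishing a Level C in vitro–in vivo correlation
(IVIVC) between in vitro release testing (IVRT) of topical semisolid products
and in vivo tape-stripping (dermatopharmacokinetic) data, with derived
bioequivalence (BE) acceptance windows. Ships with a synthetic study
generator so the whole pipeline is testable end to end without external data.

## Stages

- **`dermivivc.ivrt`** — withdrawal-corrected cumulative release per unit
  area from vertical-diffusion-cell receptor concentrations, Higuchi (√time)
  fits per cell yielding apparent release constants (ARC, µg/cm²/min^½), and
  a 90% CI on the test/reference ARC ratio (log-Welch by default, Fieller
  optional).
- **`dermivivc.dpk`** — strip masses from pre/post tape weights, stratum
  corneum thickness from blank-site TEWL by 1/TEWL linear extrapolation,
  drug-amount vs relative-SC-depth profiles, and trapezoidal AUCs
  (µg·% skin depth) per participant and study.
- **`dermivivc.ivivc`** — OLS Level C fit of AUC on ARC, AUC prediction from
  ARC, and the two-value CV agreement measure.
- **`dermivivc.be`** — BE windows on ARC (pooled reference ARC × 0.7999 and
  × 1.2501 by default) mapped through the model onto predicted AUC, and
  product classification.
- **`dermivivc.synthetic`** — simulators for both study types: Higuchi
  release with exact withdrawal-dilution bookkeeping, transient Fickian
  drug-depth profiles after a timed application, geometrically decaying strip
  masses, and TEWL series consistent with each participant's SC thickness.
  Zero-noise output is inverted exactly by the analysis stages.
- **`dermivivc.pipeline` / `dermivivc.cli`** — YAML-configured end-to-end
  runs with CSV intermediates, plain-text report tables and a JSON run log.

## CLI

```sh
# full pipeline from a YAML config (see below)
dermivivc all config.yaml

# fit / classify directly from a points CSV; "bundled" uses the packaged
# five-point metronidazole cream summary dataset
dermivivc ivivc --points bundled
dermivivc be --points bundled

# generate synthetic CSV datasets, then run the standalone stages
dermivivc simulate --config sim.yaml --out data/ --seed 7
dermivivc ivrt --data data/ivrt_data.csv --meta data/ivrt_meta.csv
dermivivc ts --data data/tapestrip_data.csv --tewl data/tewl_data.csv
```

A minimal full-pipeline config:

```yaml
seed: 7
output_dir: out
ivrt:
  simulate:
    runs:
      - {run_id: run1, products: {reference: 38.0, T1: 33.0}}
      - {run_id: run2, products: {reference: 38.5, T2: 27.0, T3: 51.0}}
ts:
  simulate:
    product_scale: {reference: 1.0, T1: 0.95, T2: 0.75, T3: 1.25}
```

Summary mode (bypassing the raw stages) replaces the two blocks with
`ivivc_points: bundled` or a path to a points CSV
(`product_id,run_label,arc,auc`).

## Notes on conventions

- The Higuchi intercept is estimated, never forced through the origin.
- Reported tables round half-to-even at 2 decimals; all arithmetic is full
  precision internally.
- Reference ARCs from multiple runs are pooled by arithmetic mean before the
  BE window is built; the BE verdict is driven by the ARC window (the AUC
  window is reported alongside and, the map being affine increasing, always
  agrees).
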