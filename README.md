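# mrmediate

Two-sample Mendelian randomization with two-step mediation analysis for
GWAS summary statistics.

The package covers the full desk-scale workflow:

- **`sumstats`** — summary-statistics data model, canonical TSV I/O and
  allele harmonization (strand flips, palindromic-SNP policies).
- **`instruments`** — instrument selection: p-value filter, greedy LD
  clumping (r² < 0.001 within 10,000 kb by default) and the per-SNP
  F-statistic filter (F ≥ 10).
- **`mr_core`** — Wald ratio, IVW (fixed and multiplicative random
  effects), Egger regression, weighted median, and simple/weighted
  kernel-mode estimators.
- **`sensitivity`** — Cochran's Q (IVW and Egger), the Egger intercept
  test, a simulation-based residual outlier procedure (global, per-SNP
  and distortion tests with outlier-corrected estimates), and
  leave-one-out analysis.
- **`mediation`** — product-of-coefficients mediation (mediated effect,
  mediated proportion, delta-method uncertainty), the three-leg two-step
  pipeline, and a reverse-MR screen.
- **`synthetic_data`** — a seeded generator for three-trait GWAS summary
  statistics with a known exposure → mediator → outcome structure
  (optional pleiotropy, outliers, LD blocks) plus a truth ledger, so the
  whole pipeline is testable without any data download. It also ships the
  transcribed worked-example tables used by the acceptance suite.
- **`pipeline` / `cli`** — YAML-configured runs, TSV/JSON report outputs
  and a `mrmediate` command-line entry point.

## CLI

```sh
# simulate a three-trait system from a YAML config ({seed: 1, n_snps: 50, ...})
mrmediate simulate --config sim.yaml --out-dir data/

# instrument selection and harmonization as standalone steps
mrmediate select-instruments --sumstats data/exposure.tsv --ld data/ld.tsv --out selected.tsv
mrmediate harmonize --exposure selected.tsv --outcome data/outcome.tsv --out harmonized.tsv

# full MR run / two-step mediation run from a YAML run config
mrmediate mr --config run.yaml
mrmediate mediate --config run.yaml

# diagnostics on a harmonized TSV
mrmediate sensitivity --harmonized harmonized.tsv --out sensitivity.tsv

# recompute the published worked-example mediation table
mrmediate replay-fixture
```

A run config names the input TSVs (paths relative to the config file),
an output directory, and optional thresholds:

```yaml
exposure: data/exposure.tsv
mediator: data/mediator.tsv   # omit for a plain MR run
outcome: data/outcome.tsv
ld: data/ld.tsv
out_dir: results/
seed: 1
selection: {pval_threshold: 1.0e-5, clump_r2: 0.001, clump_window_kb: 10000, min_f: 10}
ivw_model: multiplicative_random
```

Summary-statistics files are tab-separated with header
`variant_id chrom pos effect_allele other_allele eaf beta se pval n`
(missing token `NA`); foreign headers can be mapped via `column_map` in
the Python API.

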