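# vigimr

Pharmacoepidemiology toolkit for spontaneous-report signal mining and
genetic causal inference, with a ground-truth simulator so the whole
pipeline is testable offline:

- **simulate** — synthetic spontaneous-report tables (duplicate case
  versions, suspect roles, missing demographics, onset dates) with
  drug–event associations injected at an exact target reporting odds ratio,
  and two-trait GWAS summary statistics with a known causal effect,
  guaranteed-significant instruments, optional directional pleiotropy and
  deliberately messy allele coding.
- **ingest** — report-table reading, case deduplication (latest version
  wins), primary-suspect filtering, trade/generic drug-name normalization.
- **meddra** — flat preferred-term → {psychiatric, other} dictionary (a
  stub ships with the package; user dictionaries are accepted) and
  report-level psychiatric-event proportions.
- **signal** — reporting odds ratio with Wald confidence intervals,
  Haldane–Anscombe zero-cell correction, CI/minimum-count positivity rule,
  per-drug-per-stratum Bonferroni correction, and sex/age stratification
  (two age-bin schemes).
- **tto** — time-to-onset extraction, two-parameter Weibull maximum
  likelihood with Wald intervals on the log scale, and hazard typing
  (early / random / wear-out failure).
- **mr** — two-sample Mendelian randomization: p-value + distance/LD
  instrument clumping, allele harmonization (palindrome handling, sign
  flips), IVW, MR-Egger with intercept test, weighted median, weighted
  mode, a simplified residual-sum-of-squares outlier test, and
  Benjamini–Hochberg FDR over a family of trait pairs.
- **report** — descriptive summary tables, publication-shaped TSV outputs,
  and a printed-ratio arithmetic checker.

## CLI

```sh
vigimr simulate-reports -c sim.yaml -o reports.tsv        # YAML config, seed required
vigimr simulate-gwas -c gwas.yaml --out-exposure e.tsv --out-outcome o.tsv
vigimr signal -r reports.tsv -o signals.tsv --stratum overall --stratum sex --stratum age
vigimr tto -r reports.tsv -d Omeprazole -o tto.tsv
vigimr mr --exposure e.tsv --outcome o.tsv -o mr.tsv --seed 1
vigimr report -r reports.tsv --outdir out/ --paper-check
```

All files are plain tab-separated text; the report and summary-statistic
dialects are documented in `vigimr.io`. `vigimr report --paper-check`
re-verifies the bundled fixture of published proportion rows.

Example simulation config (`sim.yaml`):

```yaml
n_reports: 50000
drugs: {Omeprazole: 0.2, Esomeprazole: 0.2}
psychiatric_pts: [Depression, Anxiety, Insomnia]
other_pts: [Nausea, Headache, Rash, Fatigue]
injected_signals:
  - {drug: Omeprazole, pt: Depression, target_ror: 5.0,
     tto_scale_alpha: 100.0, tto_shape_beta: 0.5}
duplicate_rate: 0.1
missing_demo_rate: 0.1
seed: 1
```

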