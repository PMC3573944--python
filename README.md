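# grsrisk

Genetic risk score construction and risk-model evaluation for candidate-SNP
case-control studies. The package implements, as a tested reusable pipeline:

- **Synthetic cohorts** (`grsrisk.synth`) — case-control simulation under a
  log-additive logistic disease model with HWE genotypes and an ordinal
  smoking exposure, ascertained by rejection sampling from a
  prevalence-anchored population; plus expansion of printed category/count
  tables into individual-level records.
- **Risk scores** (`grsrisk.grs`) — the count score (cGRS, sum of risk-allele
  dosages) and the weighted score (wGRS, product of genotype relative risks
  normalized by the population-average relative risk
  `u = (1-p)^2 + 2p(1-p)OR + p^2OR^2`), with decile binning against a
  control-group reference. Missing genotypes contribute a factor of 1 to the
  wGRS.
- **Per-SNP association** (`grsrisk.assoc`) — Hardy-Weinberg chi-square (and
  exact) tests, allelic odds ratios with Woolf CIs, EM-based pairwise D',
  and liability-threshold variance explained `2p(1-p)(ln OR)^2`.
- **Risk model** (`grsrisk.model`) — logistic regression of status on wGRS
  decile rank and ordinal smoking, a relative-risk calculator, and
  per-category OR tables with trend tests.
- **Evaluation** (`grsrisk.evaluate`) — rank-based AUC with bootstrap CIs,
  paired AUC comparison (bootstrap or DeLong), Hosmer-Lemeshow calibration,
  Harrell bootstrap optimism correction, 75/25 split validation, and Youden
  cutoff confusion metrics.
- **CLI and formats** (`grsrisk.io`, `grsrisk.cli`) — TSV cohort files, YAML
  configuration, and deterministic end-to-end orchestration.

## CLI

Cohorts are TSV with header `subject_id  status  smoking  <snp_id>...`
(`status` 0/1, `smoking` 0/1/2, dosages 0/1/2 or `NA`). The configuration is
YAML with `snps` (list of `{snp_id, risk_allele, p, oratio}`), `seed`, and
optional keys for the GRS mode, decile reference policy, bootstrap replicate
count, split fraction, and the simulation block (`n_cases`, `n_controls`,
`prevalence`, `smoking_dist`, `smoking_or`, `missing_rate`).

```sh
grsrisk simulate --config config.yaml --seed 1 --out cohort.tsv
grsrisk assoc    --config config.yaml --cohort cohort.tsv --out assoc.tsv
grsrisk score    --config config.yaml --cohort cohort.tsv --out scores.tsv
grsrisk fit      --config config.yaml --cohort cohort.tsv --out model.tsv
grsrisk evaluate --config config.yaml --cohort cohort.tsv --out eval.tsv
grsrisk validate --config config.yaml --cohort cohort.tsv --out valid.tsv
grsrisk run      --config config.yaml --seed 1 --out outdir   # end-to-end
```

`run` writes six artifacts (association table, SNP weights, scores,
category-OR tables, model coefficients, evaluation report), each stamped
with the configuration hash and seed; reruns with identical inputs are
byte-identical.

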