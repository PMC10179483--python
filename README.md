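# cc-organotrait

Simulation and phenotype-analysis pipeline for diet-challenge studies on
Collaborative Cross (CC) mouse lines. The package generates synthetic
cohorts with a known genetic structure (additive line, sex, diet and
line-x-diet effects), derives the standard obesity/glucose phenotypes,
estimates broad-sense heritability and genetic coefficients of variation
per line stratum, computes trait correlation matrices and diet contrasts,
and scores per-line classification/regression models of adjusted organ
weight.

## What it computes

- **Synthetic cohort** — 8 CC lines x 2 sexes x 2 diets (standard chow,
  CHD, vs high-fat, HFD) at the default design's exact per-cell group
  sizes (207 animals); bi-weekly body weights over a 12-week challenge;
  intraperitoneal glucose tolerance tests (IPGTT) at weeks 6 and 12 read
  at 0/15/30/60/120/180 min; terminal liver, spleen and heart weights.
- **Derived traits** — trapezoid-rule glucose AUC over 0–180 min,
  body-weight change (BW12 − BW0), actual and percent organ weight
  (organ / final BW x 100), and per-(line, sex) diet contrasts of group
  means (delta organ weight / delta body weight).
- **Quantitative genetics** — one-way ANOVA per line with the unbalanced
  effective sample size n0 = (N − Σnᵢ²/N)/(a−1); method-of-moments
  variance components Ve = MSW, Vg = max(0, (MSB − MSW)/n0); broad-sense
  heritability H² = Vg/(Vg+Ve); genetic CV = SD of line means / overall
  mean — per trait and sex x diet stratum.
- **Descriptive statistics** — pairwise-complete Pearson correlation
  matrices with heatmaps per stratum; Welch t-tests of HFD vs CHD with
  `*`/`**`/`***` annotations at p < 0.05/0.01/0.001.
- **Predictive models** — per line: binary classification of percent organ
  weight above its 70th percentile (decision tree, Gaussian naive Bayes,
  KNN, random forest; stratified 4-fold CV; mean ROC-AUC) and regression
  of percent organ weight (linear, KNN; 100 repeated 70–30 train-test
  splits; mean held-out R², floored at zero for the grid score).

## CLI

Every stage is a subcommand of `cc-organotrait`:

```bash
cc-organotrait simulate --seed 42 --out cohort.csv
cc-organotrait traits --in cohort.csv --out traits.csv
cc-organotrait heritability --in traits.csv --out h2_table.csv
cc-organotrait correlate --in traits.csv --by sex,diet --out heatmaps/ --table correlations.csv
cc-organotrait contrast --in traits.csv --out contrasts.csv
cc-organotrait classify --in traits.csv --organ liver --k 4 --seed 1 --out grid.json
cc-organotrait regress --in traits.csv --organ liver --iters 100 --seed 1 --out grid.json
cc-organotrait run --config study.yaml            # full end-to-end replica
```

`cc-organotrait run` writes cohort.csv, traits.csv, h2_table.csv,
correlations.csv + heatmaps/, contrasts.csv, per-organ classification and
regression grids (JSON), and a `manifest.json` echoing the config, its
hash, all protocol constants and per-stage row counts. Reruns with the
same config are byte-identical. A YAML config can override any
simulation parameter or protocol, e.g.:

```yaml
seed: 42
simulation:
  body_weight: {mu: 20.0, diet_effect: 2.0, sigma_line: 2.0, sigma_e: 1.5}
classification: {k: 4}
regression: {iterations: 100, train_fraction: 0.7}
feature_set: paper-text   # or table-caption
```

## Cohort CSV schema

Tidy, one row per mouse x measurement:
`mouse_id,line,sex,diet,measure,week,t_min,value` with `measure` one of
`bw_g, glucose_mg_dl, liver_g, spleen_g, heart_g`; `t_min` is set only on
glucose rows. `read_cohort`/`write_cohort` round-trip records exactly.

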