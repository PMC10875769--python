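# phenosearch

Phenotype discovery and treatment-efficacy screening for randomized trial
cohorts. The pipeline, designed for trials with a composite 90-day kidney
endpoint (death, >25% eGFR drop vs the pre-illness reference, or renal
replacement therapy), runs in four stages:

1. **Variable screening** — baseline variables are cut into quartiles; within
   each quartile the risk ratio of composite-event incidence (active vs
   placebo arm) is computed. Variables whose risk ratios move strictly
   monotonically across ≥3 consecutive quartiles pass; passing variables are
   ranked by the steepness of an OLS slope of risk ratio on quartile index
   (two slopes for a full four-quartile run) and the top-15 are kept.
2. **Preprocessing (per candidate model)** — drop patients with >50% missing
   model variables, impute the rest by chained random forests, apply a
   (shifted) log transform with centering/scaling, and remove outliers with a
   Bonferroni outlier test on externally studentized residuals.
3. **Consensus clustering** — in-package k-means (Lloyd, random restarts) and
   PAM (BUILD + SWAP with restarts), wrapped in subsampled consensus
   clustering; final labels via average-linkage hierarchical clustering of
   the consensus matrix; per-cluster consensus scores and CDF-area summaries
   (with a null-corrected k-selection rule).
4. **Model search & reporting** — every variable subset × algorithm is
   evaluated; models need cluster-consensus > 0.90 for both phenotypes and a
   significant (two-sided log-rank p < 0.05) benefit in at least one
   phenotype; the smallest benefiting p wins. The final model is
   characterized with median [IQR] / count (%) tables, Mann–Whitney and
   chi-square tests, standardized mean differences, and Kaplan–Meier
   cumulative-incidence curves.

Because the motivating trial's data are proprietary, a synthetic-cohort
generator (`phenosearch.synthetic_cohort`) plants a two-phenotype structure
with a phenotype-specific treatment effect so the whole pipeline is testable
end to end, including recovery of the planted labels.

## CLI

```bash
# simulate a cohort with planted phenotypes
phenosearch simulate --out out/ --seed 1

# rank baseline variables by quartile risk-ratio slope steepness
phenosearch select-variables --cohort out/cohort.csv --out out/ranked.csv

# evaluate all candidate clustering models over a variable pool
phenosearch search-models --cohort out/cohort.csv \
    --variables apache_ii,bicarbonate,lactate,egfr \
    --sizes 2,4 --reps 100 --seed 1 --out out/models.csv

# characterize phenotypes given labels
phenosearch report --cohort out/cohort.csv --labels out/phenotypes.csv --out out/report/

# everything at once (simulation -> exclusions -> screening -> search -> report)
phenosearch run-all --out out/run --seed 1 --reps 100
```

All commands are deterministic for a fixed `--seed`.

## Layout

```
src/phenosearch/
  synthetic_cohort.py     cohort generator with planted ground truth
  cohort_io.py            CSV read/write, validation, exclusions, dictionary
  outcomes_stats.py       composite outcome, KM/log-rank/MWU/chi2/RR/SMD
  variable_selection.py   quartile risk ratios, monotone screen, slope rank
  preprocessing.py        missingness filter, forest imputation, transform,
                          Bonferroni outlier removal
  consensus_clustering.py k-means, PAM, consensus matrices, k selection
  model_search.py         enumeration, gates, selection
  reporting.py            characterization tables, curves, pipeline driver
  cli.py                  click command group
```
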