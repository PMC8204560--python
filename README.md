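# omsurv

Headless multi-omics survival analysis for cancer cohorts: combinable
survival-based feature selection, Cox proportional-hazards risk scoring with
nomogram / time-dependent ROC / calibration output, KMeans subtype discovery
with automatic model-order selection, and per-subtype survival comparison —
all driven by a single seeded YAML configuration and emitted as a structured
run report.

It is aimed at biostatisticians and cancer-genomics researchers who have a
CSV with one row per patient — survival time, event indicator, optional
clinical covariates, and blocks of omics features (gene expression,
methylation, miRNA) — and want a reproducible, scriptable pipeline from raw
table to subtype-level survival curves without writing glue code.

## The model

Patient survival is modelled with the Cox proportional-hazards model

    h(t | x) = h0(t) · exp(β·x)

fitted by maximizing the Efron partial likelihood (Newton–Raphson, with an
optional L1 penalty solved by proximal-Newton coordinate descent for
Lasso-Cox). The per-patient risk score ("radscore") is the linear predictor
Σⱼ βⱼ xᵢⱼ; survival at a horizon t is predicted through the Breslow baseline
cumulative hazard, S(t | x) = exp(−H₀(t))^exp(β·(x−x̄)). Discrimination is
measured by Harrell's concordance index and the cumulative/dynamic
time-dependent ROC (censoring handled by inverse-probability-of-censoring
weights); calibration by equal-frequency binning against within-bin
Kaplan–Meier estimates.

Feature selection chains any of five screens sequentially, each applied to
the survivors of the previous one: a pairwise-correlation redundancy filter,
univariate Cox (Wald p < α), median-split log-rank, joint multivariate Cox,
and cross-validated Lasso-Cox. Subtypes are found by KMeans on the selected
features, with the cluster count k chosen over k = 3..9 by silhouette
(unlabeled cohorts) or adjusted mutual information against a stage label;
subtype survival differences are assessed by the k-group log-rank test and
pairwise hazard ratios with 95% confidence intervals.

## Worked example

No external data needed — the built-in generator plants prognostic features
and subtype structure in a proportional-hazards cohort:

```python
from omsurv.report import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="scratch/run1", seed=1,
    simulate={"n_samples": 200, "n_gene": 60, "n_methyl": 20, "n_mirna": 20,
              "n_prognostic": 5, "missing_fraction": 0.01},
    selection=[{"method": "uni_cox", "alpha": 0.05}, {"method": "lasso"}],
)
report = run_pipeline(cfg)
for s in report.stages:
    print(s.stage, s.summary)
```

prints (seed 1):

```
load {'n_samples': 200, 'n_features': 100, 'n_events': 115, 'n_train': 140, 'n_test': 60}
preprocess {'n_outliers_flagged': 0, 'n_imputed': 142}
feature_selection {'chain': ['uni_cox', 'lasso'], 'sizes': [15, 13], 'n_selected': 13, 'status': 'complete'}
risk_assessment {'train_cindex': 0.810, 'test_cindex': 0.769, 'test_auc_6': 0.786,
                 'test_auc_12': 0.825, 'cv_cindex': 0.779, 'cv_auc': 0.832, 'n_model_features': 13}
clustering {'k': 3, 'criterion': 'silhouette'}
survival_analysis {'logrank_p': 3.24e-06, 'logrank_chi2': 25.28, 'n_groups': 3}
```

Reading: the univariate Cox screen kept 15 of 100 features and Lasso-Cox
trimmed them to 13 (4 of the 5 planted prognostic features among them); the
risk model discriminates well out of sample (test c-index 0.77, 6-unit-horizon
AUC 0.79); silhouette chose 3 subtypes whose survival differs strongly
(log-rank p ≈ 3e-6). Every stage's tables, plots and parameters land in
`scratch/run1/` together with `report.json` / `report.md`.

The same run from the shell:

```bash
omsurv run --config run.yaml --seed 1 --out-dir scratch/run1
omsurv simulate --config sim.yaml --out cohort.csv   # just the synthetic CSV
omsurv cluster --config run.yaml                     # resume at one stage
```

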