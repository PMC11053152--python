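# pptc-protrisk

Proteome-based recurrence-risk modelling for pediatric papillary thyroid
carcinoma (PPTC).

Pediatric thyroid carcinomas are rare, highly heterogeneous, and lack
accepted recurrence-risk stratification criteria; with ~85% of patients
recurrence-free over a median ~6-year follow-up, the statistical problem is
building an individualized prognostic model from a TMT-quantified protein
abundance matrix (thousands of proteins, a few hundred FFPE samples in
multi-plex batches) and a small, heavily censored clinical cohort. This
package implements that analysis end-to-end for bioinformaticians and
biostatisticians working with survival-annotated proteomes:

- **Preprocessing** of the proteins × samples matrix: CV-based quality
  control over pooled reference channels and technical replicates,
  missingness filtering (NA rate > 85% removed), robust sequential-regression
  imputation, empirical-Bayes (ComBat) batch correction, half-minimum
  replacement of non-positive values, replicate merging.
- **Differential expression**: two-sided Welch's *t* on log2 abundances with
  Benjamini–Hochberg adjustment; a protein is a DEP when FC > 1.2 (model
  feature pool) or FC > 1.5 (reporting) with adjusted *p* < 0.05.
- **Clinical survival analysis**: univariate/multivariate Cox
  proportional-hazards models over eleven clinical features, Kaplan–Meier
  median splits with log-rank tests, and continuous-vs-categorical age
  coding compared by global *p*, AIC and Harrell's C-index.
- **Prognostic models**: CliCox, CliRsf, ProtCox, ProtRsf and CliProtRsf —
  Cox and random-survival-forest learners over clinical and/or protein
  features, grid-search tuned with 3-fold cross-validation; LASSO-Cox
  selection for ProtCox; for the forests, 100-repeat permutation-importance
  **stability selection** (each repeat keeps its top 50 features by the drop
  in out-of-bag Harrell's C under column permutation; the panel keeps
  features selected ≥ 50 times).
- **Risk stratification**: each patient's predicted survival curve S(t) is
  reduced to a continuous risk ranking Crank = τ − ∫₀^τ S(t) dt (τ the
  training horizon); the high/low threshold is the midpoint of the mean
  Cranks of recurrent and non-recurrent training patients, and the
  classification is evaluated by confusion counts, accuracy and KM log-rank
  separation.
- **Synthetic cohort generator** reproducing the study's data structure —
  batches with pooled references, technical replicates, abundance-dependent
  missingness, planted differential proteins, co-regulated prognostic
  proteins driving an exponential proportional-hazards recurrence process at
  ~14% event rate — so every stage is testable against known ground truth
  without any data download. See `docs/methods.md` for the model and its
  deliberate design choices.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (2,000 proteins; 85 PM + 83 PB + 66 AM patients; 16 batches):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_qc.py
python analysis/03_differential_expression.py
python analysis/04_clinical_cox.py
python analysis/05_prognostic_models.py
python analysis/06_risk_stratification.py
```

Output of a complete run (abridged):

```
cohort: 2000 proteins x 240 tissue channels (+16 pooled), 13.2% missing entries
PM patients: 85, recurrences: 12 (14.1%)
median pooled CV: 0.0267
mean batch R^2: 0.305 before ComBat, 0.0073 after
PM_vs_PB_fc1.2: 105 up, 108 down
planted differential proteins recovered at FC>1.2: 200/200; false calls: 3
univariately significant factors (p<0.05): ['TLNN', 'LLNN']
split: 51 train / 34 test
protein feature pool (train-set DEPs at FC>1.2): 215
CliCox:      11 features, C train/cv/test = 0.872/ nan /0.570
CliRsf:      11 features, C train/cv/test = 0.894/0.560/0.656
ProtCox:     14 features, C train/cv/test = 1.000/ nan /0.887
ProtRsf:     29 features, C train/cv/test = 0.991/0.820/0.854
CliProtRsf:  27 features, C train/cv/test = 0.991/0.850/0.834
threshold (midpoint of group mean Cranks, train only): 25.62
confusion vs observed recurrence: TP=9 FP=2 TN=71 FN=3; accuracy 94.12%
log-rank high vs low (train): p = 5.83e-19
log-rank high vs low (test): p = 0.0174
```

Reading this: batch correction removes essentially all batch-explained
variance (R² 0.31 → 0.007); every planted differential protein is recalled
at FC > 1.2 with 3 false calls; the protein-based models clearly beat the
clinical ones out of sample (C-index 0.85–0.89 vs 0.57–0.66), matching the
qualitative finding that protein features carry the prognostic signal; and
the Crank threshold separates held-out high- from low-risk patients
(log-rank p = 0.017) with 94% overall accuracy against observed recurrence.
(A cross-validated C-index is reported only for grid-tuned forest models,
hence `nan` for the Cox learners.)

The same pipeline is scriptable in one call:

```sh
pptc-protrisk run --out runs/demo --seed 7
```

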