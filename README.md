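# chromoscore

Chromothripsis — the catastrophic shattering and re-joining of one or a
few chromosomes — leaves a characteristic footprint in somatic
copy-number (CN) profiles: breakpoints clustered in a confined region
whose copy number oscillates among a small set of integer states.
Tumors carrying this footprint tend to show reduced cytotoxic immune
infiltration and worse outcomes under immune-checkpoint blockade (ICB).

`chromoscore` is a toolkit for studying that chain of associations end
to end, for computational oncologists working from segmented CN
profiles (SEG), somatic mutation tables (MAF-like), bulk expression
matrices and clinical outcome tables. It provides:

- a **criteria-based chromothripsis caller** on CN segments: a
  Monte-Carlo scan statistic for breakpoint clustering (criterion A)
  gated on CN-state oscillation (criterion B);
- the **chromothripsis score (CPS)**: six CN feature distributions
  (segment size, absolute CN, CN change, breakpoints per arm,
  oscillating chain lengths, breakpoints per 10 Mb) are categorized by
  BIC-selected Gaussian mixtures, decomposed into CN signatures by
  restarted KL-NMF, and fed to a logistic GLM whose predicted
  probability of chromothripsis is the CPS, reported with a stratified
  10-fold cross-validated AUC;
- **genomic covariates**: variant confidence filters, tumor mutational
  burden (TMB), per-gene mutation frequencies with Fisher tests, CNA
  burden (genes hit by gains/losses), length-weighted median tumor
  ploidy, and the weighted genome instability index (wGII);
- **immune microenvironment scoring**: ssGSEA, geometric-mean signature
  scores, CD8/Treg–TAM–MDSC and cytokine ratios, and Welch-t pathway
  differentials with BH adjustment;
- **survival analysis**: median-threshold biomarker grouping,
  Kaplan–Meier + log-rank, univariate Cox (Efron ties), IPCW
  time-dependent AUC(t), and RECIST responder/objective-responder rate
  comparisons;
- a fully seeded **synthetic cohort generator** that plants
  chromothripsis events, expression signature shifts and
  CPS-driven survival, so every stage has a recoverable ground truth.

## The score at the core

For sample $i$ with category count vector $m_i$, signatures $S$
(categories × K, simplex columns) and NNLS exposures
$e_i = \arg\min_{e \ge 0} \lVert S e - m_i \rVert_2$, the CPS is the
GLM probability

$$\mathrm{CPS}_i = \operatorname{logit}^{-1}\!\big(\beta_0 + \beta^\top e_i\big) \in [0,1].$$

Patients are split at the cohort median of each biomarker (strictly
greater → high group), and the high/low indicator enters univariate Cox
models $h(t \mid x) = h_0(t)\,e^{\beta x}$ so hazard ratios are
comparable across biomarkers.

## Worked example

```bash
chromoscore run --config configs/demo.yaml --outdir demo_out
```

simulates 200 samples (50% with a planted chromothripsis event), calls
chromothripsis, trains the CPS model, computes covariates and immune
scores, simulates CPS-driven outcomes and analyses them. It prints:

```json
{
 "detector": {"sensitivity": 1.0, "specificity": 1.0},
 "cps": {"cv_auc": 1.0, "n_signatures": 3},
 "survival": {
  "cps_logrank_p": 1.1040388964198802e-16,
  "median_high": 10.4872,
  "median_low": 45.3838,
  "responder_fisher_p": 8.88591287479495e-09,
  "objective_fisher_p": 1.3399686549485228e-12
 }
}
```

The caller recovers every planted event without false positives at
these generator settings; the CPS separates planted from background
profiles perfectly in 10-fold CV; and the high-CPS half of the cohort
has a median overall survival of 10.5 months against 45.4 months for
the low-CPS half, with correspondingly lower response rates. The
per-biomarker table (`biomarker_survival.tsv`) shows CPS with the
largest hazard ratio (HR 4.26, 95% CI 2.96–6.14) while TMB, wGII and
PD-L1 expression are null — as expected, since the simulated hazard is
driven by CPS alone.

Library use follows a statsmodels-like pattern:

```python
from chromoscore import ChromothripsisScoreModel, read_seg, filter_profile

profiles = [filter_profile(p) for p in read_seg("profiles.seg")]
results = ChromothripsisScoreModel(profiles, labels, n_signatures=3,
                                   folds=10, seed=0).fit()
print(results.summary())          # coefficients, CV AUC
scores = results.predict(profiles)  # per-sample CPS in [0, 1]
results.save("cps_model.json")
```

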