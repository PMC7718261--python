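# pgskit

Discovery and application of **progression gene signatures (PGSs)**:
prognostic biomarker panels built from genes that are simultaneously highly
expressed in tumors, essential for cancer-cell survival in RNAi depletion
screens, and associated with tumor progression in patient cohorts.

The package is aimed at computational biologists working with bulk
expression cohorts (RNA-seq or microarray), matched clinical outcome tables,
and gene-level shRNA screen data, who want a reproducible, testable
implementation of the full discovery-to-risk-score pipeline — including a
synthetic cohort generator so every stage can be exercised without any
external download.

## The method

1. **Candidate selection.** Genes are ranked by a ubiquity statistic (the
   5th percentile of log₂ expression across samples — high only when the
   gene is high in essentially every tumor) and the top percentile (default
   99th) forms the candidate pool; the pool size can be refined by BIC
   optimisation of the downstream signature model.
2. **Survival-gene filtering.** For each candidate, shRNA log₂ fold changes
   of depletion are averaged per cell line and then across cell lines; genes
   with mean FC < 0 are called survival genes. Significance is confirmed by
   one-tailed one-sample *t*-tests per shRNA (H₁: mean FC < 0), Fisher's
   combined probability test per gene (−2Σln *p* ~ χ²(2k)), and
   Benjamini–Hochberg FDR across the pool.
3. **Signature assembly.** Survival genes enter a backward stepwise logistic
   regression of the binary progression indicator on per-gene z-scored
   expression; the gene with the largest Wald *p* is removed (refitting each
   time) until all remaining *p* < 0.25. The lenient threshold deliberately
   retains weakly interacting variables.
4. **Risk scoring.** Z-scored signature expression is linearised by a
   full-rank PCA; components are screened by a 1000-tree random forest
   (percent contribution > 0.05), re-decomposed, and iterated until the
   forest retains all components. The final components feed a boosted
   ensemble of 3-tanh-node networks (100 stages, learning rate 0.1) with
   tenfold stratified cross-validation. Predicted progression probability
   *p* is transposed to a risk score *s* = 100·(*p* − 0.5) ∈ [−50, 50];
   *s* > 0 defines the high-risk group.
5. **Evaluation.** ROC/AUC (Mann–Whitney, out-of-fold on the training
   cohort), DeLong paired ROC comparison against baseline biomarkers,
   confusion matrices with Fisher's exact test, Kaplan–Meier curves with
   log-rank tests, Cox proportional-hazards models (Efron ties), and Welch
   *t*-tests for treatment-benefit and hypoxia contrasts.

Validation cohorts are z-scored within their own cohort before scoring;
qPCR panels are scored after the ΔCt transform
(ΔCt = Ct(reference) − Ct(gene), per-gene z-scored across the panel).

## Worked example

```python
import pgskit as pk

cfg = pk.SimulationConfig(n_samples=400, n_genes=2000, n_planted=20, seed=1)
cohort = pk.simulate_cohort(cfg)
result = pk.run_pipeline(cohort.expression, cohort.clinical, cohort.screen, seed=1)

print("signature:", result.signature.genes)
print(f"out-of-fold AUC: {result.report['auc_oof']:.3f}")
km = result.report["km_by_group"]
print(f"median DFS high-risk: {km['high']['median_label']} months")
print(f"median DFS low-risk:  {km['low']['median_label']} months")
print(f"log-rank p: {result.report['logrank']['p']:.3g}")
```

prints

```
signature: ['G0000', 'G0003', 'G0005', 'G0008', 'G0011', 'G0013', 'G0014', 'G0018', 'G0019']
out-of-fold AUC: 0.784
median DFS high-risk: 17.9372 months
median DFS low-risk:  56.6925 months
log-rank p: 3.31e-08
```

Every gene in the recovered signature is one of the 20 planted
progression-driving genes; the out-of-fold AUC of 0.78 sits close to the
theoretical ceiling of ≈0.81 for this cohort (the AUC of the *true* latent
risk factor under a logistic progression model with effect 1.5), and the
risk groups separate disease-free survival by a factor of ~3 in median time.
The same pipeline is available stage by stage from the shell via the `pgs`
command (`pgs simulate`, `pgs select-candidates`, `pgs screen-essential`,
`pgs assemble-pgs`, `pgs train-risk`, `pgs score`, `pgs evaluate`,
`pgs split`, `pgs qpcr-score`, `pgs run`).

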