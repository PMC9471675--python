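# evmir

Analysis pipeline for paired qPCR miRNA panels from circulating
extracellular vesicles (EVs) and adipose tissue, as used in
placebo-controlled treatment studies: Ct normalization, covariate-adjusted
mixed-model differential abundance, partial-correlation follow-up, and a
miRNA-overtargeting network test whose significance comes from simulated
"equivalent random networks".

It is aimed at analysts working with TaqMan-array-style Ct tables from
small paired cohorts (two arms × two visits), where treatment effects must
be separated from technical yield, reference-gene drift, and systemic
confounders such as weight gain and hemodilution.

## What it computes

**Normalization.** Raw Ct values are first adjusted by the recovery of an
exogenous spike-in (e.g. cel-miR-39): each sample's Cts shift by the
deviation of its spike Ct from the cohort mean. Reference features are then
chosen by a NormFinder-type model-based stability value ρ that combines a
feature's shrunken intergroup difference with its intragroup variance
(lower ρ = more stable), searching all pairs exhaustively. Normalized
abundance is −ΔCt = −(Ct − mean Ct of the references), i.e. log2 relative
abundance (geometric-mean reference on the concentration scale). Relative
expression between conditions follows the −ΔΔCt rule, 2^(−ΔΔCt), and
features whose between-arm effect is below 1.5-fold are filtered before
modeling.

**Differential abundance.** Per feature, a repeated-measures mixed model

    y_ij = β0 + β1·arm + β2·visit + β3·arm×visit + Σ γ·covariates + b_i + ε_ij

with subject random intercepts b_i (REML). The treatment effect is the
arm×visit interaction β3, tested with a t reference using between-within
denominator degrees of freedom; Benjamini–Hochberg FDR across the panel;
post-hoc within-arm and between-arm contrasts; a directional (one-sided)
conversion for tests with an a-priori expected sign. Partial correlations
of per-subject change scores are computed by two-stage residual regression
with the same covariates.

**Overtargeting.** Given a validated miRNA→target database (miRTarBase
SE_WR dialect, strong evidence = reporter assay / Western blot) and a query
set of differentially expressed miRNAs, T_j counts the query miRNAs
targeting gene j. Global cooperative targeting S = Σ_j max(T_j − 1, 0) and
per-gene significance are assessed empirically against B simulated
equivalent random networks (degree-matched query resampling by default;
uniform resampling and degree-preserving edge rewiring as alternatives),
with the add-one rule p = (1 + #{null ≥ observed}) / (B + 1). Overtargeted
gene sets can be tested for hypergeometric enrichment against GMT gene
sets, and networks export to GraphML/SIF for Cytoscape.

**Clinical indices.** K_FFA (−100 × OLS slope of ln FFA over 19–40 min) and
Adipo-IR (fasting FFA × fasting insulin).

A synthetic-data module generates paired cohorts, target databases and
clinical series with planted ground truth, so every stage is testable
without patient data.

## Worked example

```python
from evmir.simulate import CohortConfig, TargetDbConfig, generate_cohort, generate_target_db
from evmir.qpcr import spike_adjust, normalize, normfinder_stability, change_scores, fold_filter
from evmir.de import ModelSpec, fit_mixed_de
from evmir.network import overtarget_test

ct, sheet, truth = generate_cohort(CohortConfig(seed=7))   # 12/arm, 42 miRNAs
adj = spike_adjust(ct, "cel-miR-39")
wide = adj.data.pivot(index="feature_id", columns="sample_id", values="ct")
groups = sheet.resolve(list(wide.columns)).set_index("sample_id")["arm"]
rank = normfinder_stability(wide.loc[adj.features_of_class("target")], groups)
mat = normalize(adj, list(rank.best_pair), spike_adjusted=True)
mat.values = mat.values.drop(index=list(rank.best_pair))
filt, _ = fold_filter(change_scores(mat, sheet), 1.5)
de = fit_mixed_de(mat, sheet, ModelSpec(),
                  features=sorted(filt.data.feature_id.unique()))
print(de.table[["feature_id", "estimate", "signed_fc", "p", "q"]].round(4))

db, db_truth = generate_target_db(TargetDbConfig(seed=7))
res = overtarget_test(db, db_truth.config["query"], B=10_000, seed=7)
print(res.s_observed, res.p_simulation, len(res.overtargeted_genes))
```

prints

```
     feature_id  estimate  signed_fc      p      q
 hsa-miR-195-5p   -0.7372    -1.6670 0.0262 0.0314
 hsa-miR-20a-5p   -0.7471    -1.6785 0.0039 0.0077
hsa-miR-374b-5p   -1.8314    -3.5587 0.0000 0.0000
   hsa-miR-7-5p   -0.7275    -1.6558 0.0161 0.0242
 hsa-miR-92a-3p   -1.1669    -2.2453 0.0010 0.0031
    hsa-miR-s02   -0.6395    -1.5578 0.0510 0.0510
35 9.999000099990002e-05 15
```

The five planted miRNAs (true signed fold change −2.0, i.e. −1 log2) pass
the 1.5-fold pre-filter and are flagged at low FDR; estimates sit around
the planted effect. In the target database, all 10 genes planted to be
cooperatively targeted by 4 of the 5 query miRNAs are recovered, and the
global excess-targeting statistic S = 35 is never reached by any of the
10,000 degree-matched random networks (p = 1/(B+1) ≈ 1e−4).

A `evmir` console script exposes the same stages
(`simulate`, `normalize`, `overtarget`, `enrich`, `indices`, `all` with a
YAML config); see `evmir --help`.

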