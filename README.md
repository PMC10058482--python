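# hbmnet — exposure-mixture networks from human biomonitoring data

`hbmnet` estimates **correlation networks of chemical exposure biomarkers**
from human biomonitoring (HBM) cohorts: urine and blood concentrations of
metals, phthalate metabolites, PFAS and similar substances, measured in the
same subjects.  Communities of the resulting network — groups of biomarkers
more densely connected among themselves than to the rest — are candidate
*real-life chemical mixtures*, relevant to anyone studying combined
exposures: exposome researchers, regulatory toxicologists, epidemiologists.

HBM data come with particular statistical obstacles that the package handles
end to end:

* **Left-censoring** — values below the limit of detection/quantification
  (LOD/LOQ) are only known to lie below the limit; biomarkers with more than
  40% of measured values censored are excluded, and the remaining censored
  cells are imputed by censored-likelihood EM (single conditional
  imputation given the subject's observed biomarkers, truncated at the log
  limit).
* **Urine dilution** — urinary concentrations are standardised for
  creatinine (µg/L ÷ g/L → µg/g creatinine), lipophilic blood biomarkers
  for blood lipids; alternative adjustment modes support sensitivity
  analysis.
* **Confounding determinants** — log concentrations are residualised on
  age, BMI, smoking (configurable) before network estimation.

## The model

For standardised residual log-concentrations `x ~ N(0, Σ)`, two biomarkers
are conditionally independent given all others iff the corresponding entry
of the precision matrix `Θ = Σ⁻¹` is zero.  The network therefore has an
edge `i–j` wherever `Θ_ij ≠ 0`, with weight the partial correlation
`ρ_ij = −Θ_ij / √(Θ_ii Θ_jj)`.  `Θ` is estimated by the **graphical lasso**:

```
max_Θ  log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|
```

fitted along 10 equally spaced penalties from λ_max (empty graph) down to
0.1·λ_max.  The penalty is selected by

* **StARS** (unweighted networks): subsample the data (20 subsamples of
  size ⌊10√n⌋), refit the path, and pick the densest graph whose average
  per-edge instability `2θ̂(1−θ̂)` stays ≤ 0.1; or
* **EBIC** (weighted networks, γ = 0.5), followed by a **parametric
  bootstrap** (1000 iterations) whose per-edge median partial correlations
  form the reported network.

Communities are found by **walktrap** (4-step random walks, dendrogram cut
at maximum modularity); intra-community edges are drawn black (green when
positive-weighted), inter-community edges red.  Stratified analyses
(e.g. by median age, BMI ≤ 25 vs > 25, education level) run the pipeline
per stratum and compare partitions by adjusted Rand index.

Because real HBM cohorts are access-restricted, the package ships a
synthetic cohort generator with planted precision structure, covariate
effects, urine dilution, LOD censoring and missingness — with the ground
truth returned for recovery testing.

## Worked example

```python
import hbmnet as hn

cfg = hn.CohortConfig(seed=1, censor_quantile=[0.3]*5 + [0.0]*10)
bm, cov, truth = hn.generate_cohort(cfg)      # 400 subjects, 15 biomarkers
pm, report = hn.preprocess(bm, cov)           # censoring filter .. scaling
res = hn.ExposureNetwork(pm).fit(method="stars", seed=2)
print(res.summary())
```

```
                  Exposure-biomarker network
==============================================================
No. subjects:                      400
No. biomarkers:                     15
Selection method:                stars
Network type:               unweighted
Selected lambda:                0.1631
Edges:                              18
Density:                         0.171
Communities:                         3
Modularity:                      0.660
--------------------------------------------------------------
community 1: bm01, bm02, bm03, bm04, bm05
community 2: bm06, bm07, bm08, bm09, bm10
community 3: bm11, bm12, bm13, bm14, bm15
==============================================================
```

The three recovered communities are exactly the three planted biomarker
blocks (adjusted Rand index 1.0 against `truth.community_labels`); 18 edges
at density 0.17 include the 15 planted ring edges.  `res.edge_list()`,
`res.partial_corr`, `res.plot()` and GraphML export give access to the
fitted network; `hn.run_stratified` and `hn.creatinine_sensitivity` cover
the stratified and sensitivity analyses.

The same pipeline is scriptable from the shell:

```bash
hbmnet simulate --n-subjects 400 --seed 1 --outdir cohort/
hbmnet run --cohort cohort/ --seed 1 --outdir results/
hbmnet stratify --cohort cohort/ --variable age --rule median --outdir strat/
```

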