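# Methods

## Scope and model

`hbmnet` treats a panel of p exposure biomarkers measured in n subjects as a
Gaussian graphical model on the natural-log concentration scale: after
preprocessing, the data vector of a subject is modelled as multivariate
normal, and the object of inference is the sparse precision (inverse
covariance) matrix Θ.  A zero off-diagonal entry of Θ means conditional
independence of the two biomarkers given all others; nonzero entries carry
the partial correlation ρ_ij = −Θ_ij/√(Θ_ii Θ_jj).  Communities of the
resulting network are read as candidate co-occurring exposure mixtures.

The normality assumption is taken seriously only after the log transform
and covariate residualisation; HBM concentrations themselves are
right-skewed and approximately log-normal.

## Preprocessing chain

Fixed order, recorded step by step in the provenance record:

1. **Single biomarker per substance** — speciated measurements (e.g. total
   vs organic arsenic) and the same substance in several matrices inflate
   correlations without adding exposure information; a user-supplied
   mapping keeps one biomarker per substance.  Which one best reflects
   long-term exposure is subject-matter judgement, so there is no automatic
   choice.
2. **Censoring filter** — a biomarker is excluded iff strictly more than
   40% of its measured (non-missing) values are below LOD/LOQ.  Ties at
   exactly 40% are retained.
3. **Dilution standardisation** — `divide` (default): urinary
   concentrations ÷ creatinine (g/L), lipophilic blood biomarkers ÷ blood
   lipids; the censoring thresholds are divided alongside and become
   subject-specific.  `covariate`: concentrations unchanged, log-creatinine
   added to the correction covariates (skipped, with a note, if creatinine
   is constant).  `none`: identity.  The three modes exist to support the
   sensitivity analysis.
4. **Natural-log transform** of values and thresholds.
5. **Censored imputation** (below).
6. **Chained single imputation** of sporadically missing data (below).
7. **Residualisation** — each biomarker column is replaced by its OLS
   residuals on the correction determinants (default age, BMI, smoking)
   plus intercept.  "Corrected for" is implemented as residualisation
   because it is the standard preparation for partial-correlation
   estimation.
8. **Scaling** — columns centred and scaled to unit SD (denominator n−1).

### Censored-likelihood EM

Censored cells are left-censored observations of the latent log
concentration.  The multivariate-normal mean and covariance are estimated
by EM: the E-step conditions each unobserved cell on the subject's observed
cells; censored coordinates contribute the mean and variance of the
univariate conditional distribution truncated above at the cell's (log)
threshold, missing coordinates the untruncated conditional moments.
Cross-moments between two unobserved coordinates in the same row use the
untruncated conditional covariance — exact multivariate truncated moments
are intractable for arbitrary censoring patterns, and this univariate
approximation is exact for the common case of one censored coordinate per
row (and exact in the mean regardless).  Convergence: maximum absolute
parameter change < 1e−6, at most 500 iterations (error on failure); a
non-positive-definite covariance update is ridge-repaired with a warning.

Each censored cell is then imputed once by the conditional expectation of
the latent value given the subject's *observed* biomarkers, truncated above
at the threshold — so every imputed value is strictly below its limit.  A
conditional mean (not a random draw) is used: the imputation is therefore
deterministic, slightly understates within-cell variance, and is the
natural single-imputation analogue.

### Chained single imputation

Determinants are completed first, in one pass ordered by ascending
missingness: linear regression for continuous variables, logistic
regression for binary ones, each fitted on the observed rows against the
other determinants.  The completed determinants plus the currently complete
biomarker columns then form the prediction matrix for missing biomarker
cells (linear regression).  Imputed values are the regression predictions,
making the whole step deterministic; a variable with no observed values, or
missingness above 50% (configurable), is an error.  Missingness is assumed
completely at random, the mechanism the synthetic generator implements.

## Network estimation

* **Graphical lasso** — block coordinate descent maximising
  log det Θ − tr(SΘ) − λΣ_{i≠j}|Θ_ij|; the inner lasso subproblems are
  solved by coordinate descent (numba-compiled kernel, pure-Python
  fallback).  Only off-diagonals are penalised, so W_ii = S_ii and
  λ ≥ max_{i≠j}|S_ij| returns the empty graph in closed form.  Convergence:
  mean absolute off-diagonal change of W below 1e−5, at most 200 sweeps;
  non-convergence is flagged, not raised.  The KKT conditions
  (W_ii = S_ii; W_ij − S_ij = λ·sign(Θ_ij) at nonzeros; |W_ij − S_ij| ≤ λ at
  zeros) are the primary correctness oracle in the test suite, alongside
  brute-force maximisation on 2×2 problems and an independent library
  implementation.  Entries below 1e−8 in absolute value count as structural
  zeros.  Warm starts propagate along the path.
* **Penalty path** — 10 equally spaced values from λ_max = max off-diagonal
  |S| down to 0.1·λ_max.
* **StARS** — 20 subsamples without replacement of size ⌊10√n⌋ (capped at
  n−1), the path refitted on each; per-edge instability 2θ̂(1−θ̂) averaged
  over all p(p−1)/2 pairs, monotonised by a running maximum from the
  sparse end; the smallest penalty (densest graph) with monotonised
  instability ≤ 0.1 is selected, and the final network is the full-data fit
  at that penalty.  If no penalty qualifies, the sparsest is returned with
  a warning flag.  Subsample count and size follow the original stability
  selection recipe.
* **EBIC** — −2·(n/2)(log det Θ − tr(SΘ)) + E log n + 4γE log p with
  E the edge count and γ = 0.5; ties broken toward the sparser fit.
* **Parametric bootstrap** — datasets of the original size are simulated
  from N(0, Θ̂⁻¹) with Θ̂ the EBIC-selected precision, columns re-scaled,
  EBIC selection re-run, and per-edge medians of the partial correlations
  reported (absent edges contribute 0).  Failed iterations are skipped and
  counted; more than 10% failures is an error.  Note the procedure is
  intrinsically conservative: it resamples from the L1-shrunk model, so
  moderate edges can fall below the EBIC acceptance threshold in the
  replicates and drop out of the median structure.  Default 1000
  iterations.

## Communities

Walktrap (4-step random walks, agglomerative, dendrogram cut at maximum
modularity) via igraph, behind the package's own partition type.  Weighted
networks enter the walk through |weight| — negative partial correlations
in these panels are rare and small, and a random walk needs non-negative
transition probabilities — while the sign is kept for display.  Isolated
nodes become singleton communities.  Modularity is Newman–Girvan on
absolute weights, Q = Σ_c (e_c/m − (d_c/2m)²), implemented and documented
independently of igraph.  Partitions across strata are compared by
adjusted Rand index, normalised mutual information and per-community best
Jaccard overlap, restricted to the shared nodes.

## Synthetic cohorts

The generator emulates the data features the pipeline must survive:
log-normal marginals (latent Gaussian, unit geometric-mean baseline),
block-structured partial correlations, determinant effects, multiplicative
urine dilution, LOD censoring, sporadic missingness.  Defaults define the
reference recovery scenario: 400 subjects, 15 biomarkers in 3 communities,
within-community partial correlation 0.3, LOD at the 20% quantile, 2%
missingness, dilution SD 0.5 on the log scale (the approximate spread of
spot-urine creatinine), two-thirds urinary biomarkers.

**Block topology.**  Within-community edges form a ring (cycle) by
default: a ring realises the planted partial correlation exactly, is
positive definite for any strength < 0.5 at any block size, and keeps
marginal correlations moderate and heterogeneous, as in real panels.  For
communities of three or fewer members the ring is the complete graph.  A
`dense` topology (every within-block pair connected) is available; dense
equicorrelated blocks are not positive definite for every size/strength
combination, in which case the diagonal is inflated to an eigenvalue floor
of 0.1 and the inflation recorded — note this shrinks the realised partial
correlations and concentrates all within-block *marginal* correlations
near λ_max, where a coarse 10-point path resolves them poorly.

The LOD is placed at a per-biomarker empirical quantile of the generated
concentrations, giving exact control of censoring rates for tests of the
40% filter.  The dilution factor is exp(log-creatinine deviation), so
creatinine division removes it exactly.  Determinant effect sizes are
deliberately modest defaults (e.g. +0.01 log-units per year of age on
interleaved biomarker subsets) and fully configurable — no reference
values exist for them.  Missingness is completely at random.

What the generator does *not* emulate: household or sampling-design
clustering, mother–child pairing across matrices, non-Gaussian dependence,
informative missingness, measurement error in creatinine.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to survey-design
artefacts.

## Pipeline, seeds, problem sizes

All randomness flows from the single run seed; stages derive their seeds by
fixed offsets (preprocess +0, StARS +1, bootstrap +2, simulation +3).
Stratified runs repeat filtering and imputation per stratum and drop the
stratification variable from the correction covariates.  The urine
validity pre-filter (creatinine within 0.3–3 g/L) is available but off by
default.

The test-bed works at the reference scenario's sizes (n = 400, p = 15;
recovery averaged over 10 seeds; bootstrap at 100 iterations inside the
recovery experiment, 200 in its dedicated unit checks) — large enough for
the asymptotic selection criteria to behave, small enough to iterate on.

## Known limitations

* The EM cross-moment approximation (above) can bias covariance estimates
  when many biomarkers of the same subject are censored simultaneously and
  strongly dependent; rates near the 40% filter boundary deserve a
  sensitivity check.
* Single imputation understates uncertainty relative to multiple
  imputation with pooling (out of scope by design).
* EBIC with γ = 0.5 at these sample sizes is conservative; combined with
  resampling from the shrunk model it makes the bootstrap median network a
  deliberately sparse, high-confidence structure rather than an unbiased
  edge-weight estimate.
* Walktrap on |weight| discards sign information when grouping; partitions
  of networks with substantial negative dependence should be interpreted
  with care.
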