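"""Data selection and preparation chain for HBM concentration matrices.

The fixed pipeline order is::

    select -> filter -> dilution -> log -> censored-impute
           -> missing-impute -> residualise -> scale

i.e. (1) keep a single biomarker per substance, (2) drop biomarkers with more
than 40% of measured values below LOD/LOQ, (3) standardise urinary
concentrations for creatinine and lipophilic blood biomarkers for blood
lipids, (4) natural-log transform, (5) impute left-censored cells by
censored-likelihood EM, (6) impute sporadically missing determinants and
biomarker cells by chained single regression imputation, (7) residualise on
the correction determinants, (8) centre and scale to unit variance.

Every step appends to the provenance record carried by the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import norm

from .datatypes import BiomarkerMatrix, DataError, ProcessedMatrix, validate_covariates

DEFAULT_CENSOR_THRESHOLD = 0.40  # exclude biomarkers with >40% below LOD/LOQ
DEFAULT_CORRECTION = ("age", "bmi", "smoking")


class ConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# censoring summary and filter
# ---------------------------------------------------------------------------

def censoring_summary(bm: BiomarkerMatrix) -> pd.DataFrame:
    """Per-biomarker fraction of non-missing cells below LOD and below LOQ.

    Biomarkers with no non-missing cell get NaN fractions and are flagged in
    the ``all_missing`` column.
    """
    nonmiss = (~bm.missing).sum(axis=0)
    ncens = bm.censored.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = ncens / nonmiss.replace(0, np.nan)
    out = pd.DataFrame(
        {
            "n_nonmissing": nonmiss,
            "n_censored": ncens,
            # below-LOD/LOQ is a single censored category (LOQ defaults to LOD)
            "frac_below_lod": frac,
            "frac_below_loq": frac,
            "all_missing": nonmiss == 0,
        }
    )
    out.index.name = "biomarker"
    return out


def filter_by_censoring(bm: BiomarkerMatrix, threshold: float = DEFAULT_CENSOR_THRESHOLD):
    """Exclude biomarkers whose censored fraction strictly exceeds ``threshold``.

    The cut is strict ("more than 40%"): a biomarker censored in exactly 40%
    of its measured values is retained.  Column order of the retained
    biomarkers is preserved.  Returns ``(retained BiomarkerMatrix, excluded
    biomarker list)``.
    """
    if not 0 <= threshold <= 1:
        raise DataError(f"censoring threshold must be in [0, 1], got {threshold}")
    summary = censoring_summary(bm)
    frac = summary["frac_below_loq"].fillna(np.inf)  # all-missing -> excluded
    excluded = [b for b in bm.biomarkers if frac[b] > threshold]
    retained = [b for b in bm.biomarkers if b not in excluded]
    return bm.subset(columns=retained), excluded


# ---------------------------------------------------------------------------
# scale transforms
# ---------------------------------------------------------------------------

def log_transform(bm: BiomarkerMatrix) -> BiomarkerMatrix:
    """Natural-log transform observed values and censoring thresholds."""
    if bm.log_scale:
        raise DataError("matrix is already on the log scale")
    observed = ~(bm.censored | bm.missing)
    vals = bm.values.to_numpy()
    bad = observed.to_numpy() & ~(vals > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"non-positive value at subject {bm.values.index[i]!r}, "
            f"biomarker {bm.values.columns[j]!r}: cannot log transform"
        )
    out = bm.copy()
    with np.errstate(divide="ignore"):
        out.values = np.log(out.values)
        out.thresholds = np.log(out.thresholds)
        out.meta = out.meta.copy()
    out.log_scale = True
    return out


def standardize_dilution(
    bm: BiomarkerMatrix, covariates: pd.DataFrame, mode: str = "divide"
) -> BiomarkerMatrix:
    """Correct for urine dilution and blood lipid content.

    ``divide``: urinary concentrations are divided by creatinine
    (ug/L / g/L -> ug/g creatinine) and lipophilic blood biomarkers by blood
    lipids; censoring thresholds are divided alongside, which makes them
    subject-specific.  ``covariate``: values unchanged — the caller appends
    creatinine to the correction covariates instead.  ``none``: identity.
    Biomarkers that are neither urinary nor lipophilic-blood are never
    altered.
    """
    if mode not in ("divide", "covariate", "none"):
        raise DataError(f"unknown dilution mode {mode!r}")
    out = bm.copy()
    if mode in ("covariate", "none"):
        return out
    if bm.log_scale:
        raise DataError("dilution standardisation must precede the log transform")
    covariates = validate_covariates(covariates, bm.subjects)

    urinary = [b for b in bm.biomarkers if bm.is_urinary()[b]]
    lipophilic = [b for b in bm.biomarkers if bm.is_lipid_soluble_blood()[b]]
    if urinary:
        if "creatinine" not in covariates:
            raise DataError("creatinine required to standardise urinary biomarkers")
        creat = covariates["creatinine"].to_numpy(dtype=float)
        bad = ~(creat > 0)
        if bad.any():
            raise DataError(
                f"non-positive or missing creatinine for subjects "
                f"{list(bm.subjects[bad])}"
            )
        out.values[urinary] = out.values[urinary].div(creat, axis=0)
        out.thresholds[urinary] = out.thresholds[urinary].div(creat, axis=0)
    if lipophilic:
        if "blood_lipids" not in covariates:
            raise DataError("blood_lipids required to standardise lipophilic biomarkers")
        lip = covariates["blood_lipids"].to_numpy(dtype=float)
        if (~(lip > 0)).any():
            raise DataError("non-positive or missing blood lipids")
        out.values[lipophilic] = out.values[lipophilic].div(lip, axis=0)
        out.thresholds[lipophilic] = out.thresholds[lipophilic].div(lip, axis=0)
    return out


# ---------------------------------------------------------------------------
# censored-likelihood EM imputation
# ---------------------------------------------------------------------------

def _truncated_moments(mu, sd, upper):
    """Mean and variance of N(mu, sd^2) truncated to (-inf, upper]."""
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    alpha = (np.asarray(upper, dtype=float) - mu) / sd
    # hazard lambda = phi(alpha) / Phi(alpha), computed in log space
    lam = np.exp(norm.logpdf(alpha) - log_ndtr(alpha))
    m1 = mu - sd * lam
    # E[Z^2 | Z <= a] = 1 - a*lam for standard Z, hence this variance
    var = sd**2 * np.clip(1.0 - alpha * lam - lam**2, 1e-12, None)
    return m1, var


def _conditional_update(sigma, mu, obs_idx, unobs_idx):
    """Conditional mean map and covariance of unobserved given observed."""
    if len(obs_idx) == 0:
        K = np.zeros((len(unobs_idx), 0))
        cov = sigma[np.ix_(unobs_idx, unobs_idx)]
        return K, cov
    Soo = sigma[np.ix_(obs_idx, obs_idx)]
    Suo = sigma[np.ix_(unobs_idx, obs_idx)]
    K = np.linalg.solve(Soo, Suo.T).T  # Suo @ Soo^-1
    cov = sigma[np.ix_(unobs_idx, unobs_idx)] - K @ Suo.T
    return K, cov


def impute_censored_ml(
    bm: BiomarkerMatrix,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-8,
):
    """Maximum-likelihood single conditional imputation of left-censored cells.

    Fits a multivariate normal to the log-concentration matrix by EM,
    treating each censored cell as left-censored at its (log) threshold and
    each missing cell as unobserved.  Each censored cell is then replaced by
    the expectation of its latent value conditional on the subject's observed
    biomarkers, truncated above at the cell's threshold — so every imputed
    value lies strictly below its limit.  Missing cells are left for the
    chained imputation stage.

    Returns ``(imputed BiomarkerMatrix, diagnostics dict)``.  Deterministic
    given the data (the procedure involves no random draws; ``seed`` is
    accepted for interface uniformity).
    """
    if not bm.log_scale:
        raise DataError("censored imputation expects log-scale data")
    X = bm.values.to_numpy(dtype=float).copy()
    cens = bm.censored.to_numpy()
    miss = bm.missing.to_numpy()
    D = bm.thresholds.to_numpy(dtype=float)
    n, p = X.shape

    none_observed = (~(cens | miss)).sum(axis=0) == 0
    if none_observed.any():
        raise DataError(
            f"biomarkers with no observed values: "
            f"{list(bm.values.columns[none_observed])}"
        )

    # initialise: censored cells slightly below threshold, missing at col mean
    fill = X.copy()
    fill[cens] = D[cens] - 0.1
    col_mean = np.nanmean(fill, axis=0)
    rows_miss, cols_miss = np.where(np.isnan(fill))
    fill[rows_miss, cols_miss] = col_mean[cols_miss]
    mu = fill.mean(axis=0)
    sigma = np.cov(fill, rowvar=False, ddof=0) + 1e-6 * np.eye(p)

    unobs = cens | miss
    # group rows by unobserved pattern so each conditional solve is done once
    patterns: dict = {}
    for i in range(n):
        patterns.setdefault(unobs[i].tobytes(), []).append(i)

    ridge_applied = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        for key, rows in patterns.items():
            rows = np.asarray(rows)
            u_mask = np.frombuffer(key, dtype=bool)
            u_idx = np.where(u_mask)[0]
            o_idx = np.where(~u_mask)[0]
            E = X[rows].copy()
            if u_idx.size == 0:
                S1 += E.sum(axis=0)
                S2 += E.T @ E
                continue
            K, cov_u = _conditional_update(sigma, mu, o_idx, u_idx)
            mu_star = mu[u_idx] + (X[np.ix_(rows, o_idx)] - mu[o_idx]) @ K.T
            sd_u = np.sqrt(np.clip(np.diag(cov_u), 1e-12, None))
            var_star = np.tile(np.diag(cov_u), (rows.size, 1))
            m1 = mu_star.copy()
            # truncated moments only for censored coordinates
            for k_local, j in enumerate(u_idx):
                is_c = cens[rows, j]
                if is_c.any():
                    tm, tv = _truncated_moments(
                        mu_star[is_c, k_local], sd_u[k_local], D[rows[is_c], j]
                    )
                    m1[is_c, k_local] = tm
                    var_star[is_c, k_local] = tv
            E[:, u_idx] = m1
            S1 += E.sum(axis=0)
            S2 += E.T @ E
            # second-moment correction: conditional covariance with truncated
            # variances on the diagonal (cross terms kept untruncated)
            C = rows.size * cov_u
            C[np.diag_indices_from(C)] = var_star.sum(axis=0)
            S2[np.ix_(u_idx, u_idx)] += C
        mu_new = S1 / n
        sigma_new = S2 / n - np.outer(mu_new, mu_new)
        eigmin = np.linalg.eigvalsh(sigma_new).min()
        if eigmin < ridge:
            warnings.warn("EM covariance not positive definite; ridge applied")
            sigma_new += (ridge - eigmin) * np.eye(p)
            ridge_applied = True
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"censored-imputation EM did not converge in {max_iter} iterations "
            f"(last parameter change {delta:.3g})"
        )

    # final single conditional imputation of censored cells
    out = bm.copy()
    vals = out.values.to_numpy()
    for key, rows in patterns.items():
        rows = np.asarray(rows)
        u_mask = np.frombuffer(key, dtype=bool)
        u_idx = np.where(u_mask)[0]
        o_idx = np.where(~u_mask)[0]
        if u_idx.size == 0:
            continue
        K, cov_u = _conditional_update(sigma, mu, o_idx, u_idx)
        mu_star = mu[u_idx] + (X[np.ix_(rows, o_idx)] - mu[o_idx]) @ K.T
        sd_u = np.sqrt(np.clip(np.diag(cov_u), 1e-12, None))
        for k_local, j in enumerate(u_idx):
            is_c = cens[rows, j]
            if is_c.any():
                tm, _ = _truncated_moments(
                    mu_star[is_c, k_local], sd_u[k_local], D[rows[is_c], j]
                )
                # strictly below the limit, also numerically
                upper = D[rows[is_c], j]
                vals[rows[is_c], j] = np.minimum(tm, upper - 1e-12)
    out.values = pd.DataFrame(vals, index=bm.values.index, columns=bm.values.columns)
    diagnostics = {
        "iterations": it,
        "converged": converged,
        "ridge_applied": ridge_applied,
        "mu": mu,
        "sigma": sigma,
        "n_imputed": int(cens.sum()),
    }
    return out, diagnostics


# ---------------------------------------------------------------------------
# chained single imputation of missing data
# ---------------------------------------------------------------------------

def _is_binary(series: pd.Series) -> bool:
    return series.dropna().nunique() <= 2


def _fit_predict_linear(Xobs, yobs, Xmis):
    beta, *_ = np.linalg.lstsq(Xobs, yobs, rcond=None)
    return Xmis @ beta


def impute_missing_chained(
    bm: BiomarkerMatrix,
    covariates: pd.DataFrame,
    seed: int = 0,
    max_missing: float = 0.5,
):
    """Chained single-regression imputation of sporadically missing data.

    Determinants are completed first (linear regression for continuous,
    logistic regression for binary variables), in one pass ordered by
    ascending missingness; the completed determinants plus the observed
    biomarkers then serve as the prediction matrix for the missing biomarker
    cells (linear regression).  Imputed values are the regression
    predictions, making the procedure deterministic.

    Returns ``(completed BiomarkerMatrix, completed covariates, counts)``.
    """
    from sklearn.linear_model import LogisticRegression

    covariates = validate_covariates(covariates, bm.subjects).copy()
    rates = covariates.isna().mean()
    if (rates >= 1.0).any():
        raise DataError(
            f"covariates with zero observed values: {list(rates.index[rates >= 1.0])}"
        )
    if (rates > max_missing).any():
        raise DataError(
            f"covariates exceeding {max_missing:.0%} missingness: "
            f"{list(rates.index[rates > max_missing])}"
        )

    obs_mask = covariates.notna()
    # provisional fills so every predictor column is complete
    filled = covariates.copy()
    for c in filled.columns:
        if filled[c].isna().any():
            col = filled[c]
            fill = col.mode().iloc[0] if _is_binary(col) else col.mean()
            filled[c] = col.fillna(fill)

    order = rates[rates > 0].sort_values().index
    for c in order:
        mis = ~obs_mask[c]
        others = [x for x in filled.columns if x != c]
        X = np.column_stack([np.ones(len(filled)), filled[others].to_numpy(float)])
        y = covariates[c]
        if _is_binary(y):
            yobs = y[obs_mask[c]]
            classes = yobs.dropna().unique()
            if len(classes) == 1:
                filled.loc[mis, c] = classes[0]
            else:
                clf = LogisticRegression(penalty=None, max_iter=1000)
                clf.fit(X[obs_mask[c].to_numpy()], yobs.to_numpy())
                filled.loc[mis, c] = clf.predict(X[mis.to_numpy()])
        else:
            pred = _fit_predict_linear(
                X[obs_mask[c].to_numpy()],
                y[obs_mask[c]].to_numpy(float),
                X[mis.to_numpy()],
            )
            filled.loc[mis, c] = pred
    covariates_done = filled

    out = bm.copy()
    vals = out.values.copy()
    bio_rates = vals.isna().mean()
    if (bio_rates >= 1.0).any():
        raise DataError(
            f"biomarkers with zero observed values: "
            f"{list(bio_rates.index[bio_rates >= 1.0])}"
        )
    if (bio_rates > max_missing).any():
        raise DataError(
            f"biomarkers exceeding {max_missing:.0%} missingness: "
            f"{list(bio_rates.index[bio_rates > max_missing])}"
        )
    n_imputed = int(vals.isna().sum().sum())
    order = bio_rates[bio_rates > 0].sort_values().index
    for b in order:
        mis = vals[b].isna()
        complete_bio = [c for c in vals.columns if c != b and not vals[c].isna().any()]
        X = np.column_stack(
            [
                np.ones(len(vals)),
                covariates_done.to_numpy(float),
                vals[complete_bio].to_numpy(float),
            ]
        )
        obs = ~mis
        pred = _fit_predict_linear(
            X[obs.to_numpy()], vals.loc[obs, b].to_numpy(float), X[mis.to_numpy()]
        )
        vals.loc[mis, b] = pred
    out.values = vals
    counts = {
        "covariate_cells_imputed": int((~obs_mask).to_numpy().sum()),
        "biomarker_cells_imputed": n_imputed,
    }
    return out, covariates_done, counts


# ---------------------------------------------------------------------------
# covariate correction and scaling
# ---------------------------------------------------------------------------

def residualize_covariates(
    values: pd.DataFrame, covariates: pd.DataFrame, covariate_list: Sequence[str]
) -> pd.DataFrame:
    """Replace each biomarker column by its OLS residuals on the determinants.

    An intercept is always included, so with an empty covariate list the
    columns are simply mean-centred.  Residual columns are orthogonal to
    every listed determinant.
    """
    covariate_list = list(covariate_list)
    missing = [c for c in covariate_list if c not in covariates.columns]
    if missing:
        raise DataError(f"unknown correction covariates: {missing}")
    n = len(values)
    X = np.ones((n, 1))
    if covariate_list:
        C = covariates[covariate_list].to_numpy(dtype=float)
        if np.isnan(C).any():
            raise DataError("correction covariates contain missing values")
        X = np.column_stack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = []
        rank = 1
        for k, name in enumerate(covariate_list):
            r = np.linalg.matrix_rank(X[:, : k + 2])
            if r == rank:
                collinear.append(name)
            rank = r
        raise DataError(f"collinear correction covariates: {collinear}")
    Y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


def zscore_scale(values: pd.DataFrame, provenance: Optional[list] = None) -> ProcessedMatrix:
    """Centre each column at 0 and scale to unit standard deviation (ddof=1)."""
    if values.isna().any().any():
        raise DataError("cannot scale a matrix with missing cells")
    sd = values.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise DataError(f"zero-variance biomarkers: {list(zero.index)}")
    scaled = (values - values.mean()) / sd
    pm = ProcessedMatrix(scaled, provenance=list(provenance or []))
    pm.record("zscore_scale", ddof=1)
    return pm


def select_single_biomarker(bm: BiomarkerMatrix, mapping: dict):
    """Keep one biomarker per substance according to a user-supplied mapping.

    ``mapping`` associates a substance name (matched against the ``substance``
    metadata column, which defaults to the biomarker name) with the biomarker
    chosen to represent it; all other biomarkers of that substance are
    dropped.  Which biomarker best reflects long-term exposure is a
    subject-matter judgement, so the mapping is always explicit input.

    Returns ``(reduced BiomarkerMatrix, dropped biomarker list)``.
    """
    if not mapping:
        return bm.copy(), []
    substance = (
        bm.meta["substance"]
        if "substance" in bm.meta
        else pd.Series(bm.meta.index, index=bm.meta.index)
    )
    dropped = []
    keep = list(bm.biomarkers)
    for subst, chosen in mapping.items():
        if chosen not in bm.biomarkers:
            raise DataError(f"mapping names unknown biomarker {chosen!r}")
        group = [b for b in bm.biomarkers if substance.get(b) == subst]
        if chosen not in group:
            raise DataError(
                f"chosen biomarker {chosen!r} is not a {subst!r} biomarker"
            )
        for b in group:
            if b != chosen and b in keep:
                keep.remove(b)
                dropped.append(b)
    return bm.subset(columns=keep), dropped


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessReport:
    excluded_biomarkers: list
    dropped_duplicates: list
    em_diagnostics: dict
    imputation_counts: dict
    correction_covariates: list
    provenance: list


def preprocess(
    bm: BiomarkerMatrix,
    covariates: pd.DataFrame,
    *,
    single_biomarker_map: Optional[dict] = None,
    censor_threshold: float = DEFAULT_CENSOR_THRESHOLD,
    dilution_mode: str = "divide",
    correction_covariates: Sequence[str] = DEFAULT_CORRECTION,
    seed: int = 0,
    em_tol: float = 1e-6,
    em_max_iter: int = 500,
):
    """Run the full preparation chain; returns (ProcessedMatrix, PreprocessReport)."""
    provenance: list = []
    covariates = validate_covariates(covariates, bm.subjects)

    bm, dropped = select_single_biomarker(bm, single_biomarker_map or {})
    provenance.append({"step": "select_single_biomarker", "dropped": dropped})

    bm, excluded = filter_by_censoring(bm, censor_threshold)
    provenance.append(
        {"step": "filter_by_censoring", "threshold": censor_threshold,
         "excluded": excluded}
    )

    bm = standardize_dilution(bm, covariates, mode=dilution_mode)
    correction = [c for c in correction_covariates]
    if dilution_mode == "covariate":
        covariates = covariates.copy()
        covariates["log_creatinine"] = np.log(covariates["creatinine"])
        # a constant creatinine column carries no dilution information and
        # would make the correction design rank-deficient
        if (
            covariates["log_creatinine"].std() > 0
            and "log_creatinine" not in correction
        ):
            correction.append("log_creatinine")
    provenance.append({"step": "standardize_dilution", "mode": dilution_mode})

    bm = log_transform(bm)
    provenance.append({"step": "log_transform", "base": "e"})

    if bm.censored.to_numpy().any():
        bm, em_diag = impute_censored_ml(bm, seed=seed, tol=em_tol, max_iter=em_max_iter)
    else:
        em_diag = {"iterations": 0, "converged": True, "n_imputed": 0}
    provenance.append(
        {"step": "impute_censored_ml",
         "iterations": em_diag["iterations"], "n_imputed": em_diag["n_imputed"]}
    )

    bm, covariates, counts = impute_missing_chained(bm, covariates, seed=seed)
    provenance.append({"step": "impute_missing_chained", **counts})

    resid = residualize_covariates(bm.values, covariates, correction)
    provenance.append({"step": "residualize_covariates", "covariates": correction})

    processed = zscore_scale(resid, provenance=provenance)
    report = PreprocessReport(
        excluded_biomarkers=excluded,
        dropped_duplicates=dropped,
        em_diagnostics={k: v for k, v in em_diag.items() if k not in ("mu", "sigma")},
        imputation_counts=counts,
        correction_covariates=correction,
        provenance=processed.provenance,
    )
    return processed, report
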