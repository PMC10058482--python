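"""Penalty selection for the graphical lasso: StARS, EBIC and the
parametric-bootstrap median network.

Two selection routes mirror the two network flavours:

* unweighted networks — StARS (stability approach to regularisation
  selection): fit the penalty path on random subsamples and pick the densest
  graph whose average edge instability stays below a threshold (default 0.1);
* weighted networks — EBIC (extended Bayesian information criterion,
  gamma = 0.5) along the path, followed by a parametric bootstrap (default
  1000 iterations) whose per-edge median partial correlations form the
  reported network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import DataError
from .glasso import (
    PrecisionEstimate,
    empirical_covariance,
    fit_path,
    glasso,
    lambda_path,
)

STARS_THRESHOLD = 0.1
STARS_SUBSAMPLES = 20
EBIC_GAMMA = 0.5
BOOTSTRAP_ITERATIONS = 1000


def _as_array(X) -> np.ndarray:
    if hasattr(X, "to_numpy"):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("expected a subjects x biomarkers matrix")
    return X


# ---------------------------------------------------------------------------
# StARS
# ---------------------------------------------------------------------------

def edge_instability(frequencies: np.ndarray) -> np.ndarray:
    """Per-edge instability 2*theta*(1-theta) from edge appearance frequencies.

    The statistic is the probability that two independently drawn subsample
    graphs disagree on the edge; it ranges over [0, 0.5] and attains 0.5 when
    the edge appears in exactly half of the subsamples.
    """
    f = np.asarray(frequencies, dtype=float)
    return 2.0 * f * (1.0 - f)


def instability_from_adjacencies(adjacencies: np.ndarray) -> float:
    """Average instability over all node pairs, given stacked adjacencies.

    ``adjacencies`` has shape (n_subsamples, p, p); the average runs over all
    p(p-1)/2 unordered pairs.
    """
    A = np.asarray(adjacencies, dtype=float)
    freq = A.mean(axis=0)
    p = freq.shape[0]
    iu = np.triu_indices(p, 1)
    return float(edge_instability(freq[iu]).mean())


@dataclass
class StarsResult:
    lambdas: np.ndarray
    instability: np.ndarray          # raw, per lambda (sparse -> dense order)
    monotonized: np.ndarray          # running max from the sparse end
    selected_lambda: float
    selected_index: int
    n_subsamples: int
    subsample_size: int
    threshold: float
    no_lambda_selected: bool         # no penalty met the threshold; sparsest used
    estimate: Optional[PrecisionEstimate] = None

    def __post_init__(self) -> None:
        if np.any(self.instability < -1e-12) or np.any(self.instability > 0.5 + 1e-12):
            raise DataError("StARS instabilities must lie in [0, 0.5]")


def default_subsample_size(n: int) -> int:
    """floor(10*sqrt(n)), capped below the sample size."""
    return min(n - 1, int(np.floor(10.0 * np.sqrt(n))))


def stars_select(
    X,
    path: Optional[np.ndarray] = None,
    threshold: float = STARS_THRESHOLD,
    n_subsamples: int = STARS_SUBSAMPLES,
    subsample_size: Optional[int] = None,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> StarsResult:
    """Select the penalty by edge stability across subsamples.

    For each penalty on the path the glasso is fitted to ``n_subsamples``
    subsamples drawn without replacement; the per-edge instability
    2*theta*(1-theta) is averaged over all node pairs, monotonised by a
    running maximum from the sparse end, and the smallest penalty (densest
    graph) whose monotonised instability stays <= ``threshold`` is selected.
    The returned estimate is the glasso fit on the full data at the selected
    penalty.  Deterministic for a fixed seed.
    """
    X = _as_array(X)
    n, p = X.shape
    S_full = empirical_covariance(X)
    if path is None:
        path = lambda_path(S_full)
    path = np.asarray(path, dtype=float)
    b = default_subsample_size(n) if subsample_size is None else int(subsample_size)
    if not 0 < b < n:
        raise DataError(f"subsample size {b} must lie in (0, n={n})")

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(path), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        S_b = empirical_covariance(X[idx])
        warm = None
        for li, lam in enumerate(path):
            est = glasso(S_b, float(lam), tol=tol, max_iter=max_iter, warm=warm)
            counts[li] += est.adjacency
            warm = est

    freq = counts / n_subsamples
    iu = np.triu_indices(p, 1)
    instability = np.array([edge_instability(freq[li][iu]).mean() for li in range(len(path))])
    monotonized = np.maximum.accumulate(instability)

    ok = np.where(monotonized <= threshold)[0]
    if ok.size:
        sel = int(ok.max())  # densest graph still below the threshold
        no_sel = False
    else:
        sel = 0
        no_sel = True
        warnings.warn(
            "no penalty on the path meets the StARS instability threshold; "
            "returning the sparsest"
        )
    estimate = glasso(S_full, float(path[sel]), tol=tol, max_iter=max_iter)
    return StarsResult(
        lambdas=path,
        instability=instability,
        monotonized=monotonized,
        selected_lambda=float(path[sel]),
        selected_index=sel,
        n_subsamples=n_subsamples,
        subsample_size=b,
        threshold=threshold,
        no_lambda_selected=no_sel,
        estimate=estimate,
    )


# ---------------------------------------------------------------------------
# EBIC
# ---------------------------------------------------------------------------

def ebic_score(est: PrecisionEstimate, S: np.ndarray, n: int, gamma: float = EBIC_GAMMA) -> float:
    """Extended BIC of a fitted precision matrix.

    score = -2 * (n/2) * (log det Theta - tr(S Theta)) + E log n + 4 gamma E log p

    where E is the number of nonzero off-diagonal pairs (edges).  gamma = 0
    recovers the ordinary BIC for the Gaussian log-likelihood.
    """
    theta = est.theta if isinstance(est, PrecisionEstimate) else np.asarray(est)
    p = theta.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise DataError("precision estimate is not positive definite")
    ll = 0.5 * n * (logdet - float(np.trace(S @ theta)))
    E = (
        est.n_edges
        if isinstance(est, PrecisionEstimate)
        else int((np.abs(theta - np.diag(np.diag(theta))) > 1e-8).sum() // 2)
    )
    return float(-2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p))


@dataclass
class EbicResult:
    lambdas: np.ndarray
    scores: np.ndarray
    selected_lambda: float
    selected_index: int
    gamma: float
    estimate: PrecisionEstimate
    fits: list = field(default_factory=list, repr=False)


def ebic_select(
    X,
    path: Optional[np.ndarray] = None,
    gamma: float = EBIC_GAMMA,
    tol: float = 1e-5,
    max_iter: int = 200,
    S: Optional[np.ndarray] = None,
) -> EbicResult:
    """Fit the penalty path and return the EBIC-minimising estimate.

    Ties are broken toward the sparser (larger-penalty) fit.
    """
    X = _as_array(X)
    n = X.shape[0]
    if S is None:
        S = empirical_covariance(X)
    if path is None:
        path = lambda_path(S)
    path = np.asarray(path, dtype=float)
    fits = fit_path(S, path, tol=tol, max_iter=max_iter)
    scores = np.array([ebic_score(est, S, n, gamma) for est in fits])
    best = 0
    for i in range(1, len(path)):
        if scores[i] < scores[best] - 1e-12:  # strict improvement: sparser wins ties
            best = i
    return EbicResult(
        lambdas=path,
        scores=scores,
        selected_lambda=float(path[best]),
        selected_index=best,
        gamma=gamma,
        estimate=fits[best],
        fits=fits,
    )


# ---------------------------------------------------------------------------
# parametric bootstrap median network
# ---------------------------------------------------------------------------

@dataclass
class BootstrapNetwork:
    median_weights: np.ndarray    # p x p symmetric, diagonal 0
    n_iterations: int
    n_failed: int
    seed: int
    base_estimate: PrecisionEstimate
    labels: Optional[list] = None


def bootstrap_median_network(
    X,
    n_iterations: int = BOOTSTRAP_ITERATIONS,
    gamma: float = EBIC_GAMMA,
    seed: int = 0,
    base_estimate: Optional[PrecisionEstimate] = None,
    tol: float = 1e-5,
    max_iter: int = 200,
    max_failure_rate: float = 0.1,
) -> BootstrapNetwork:
    """Median network structure under a parametric bootstrap.

    Datasets of the original size are simulated from a multivariate normal
    with covariance equal to the inverse of the EBIC-selected precision; the
    EBIC selection is re-run on each, and the median of every edge's partial
    correlation across iterations (absent edges contributing 0) forms the
    reported weights.  Iterations that fail numerically are skipped and
    counted; more than ``max_failure_rate`` failures is an error.
    """
    X = _as_array(X)
    n, p = X.shape
    if base_estimate is None:
        base_estimate = ebic_select(X, gamma=gamma, tol=tol, max_iter=max_iter).estimate
    sigma = np.linalg.inv(base_estimate.theta)
    L = np.linalg.cholesky(0.5 * (sigma + sigma.T))
    rng = np.random.default_rng(seed)

    weights = np.zeros((n_iterations, p, p))
    failed = 0
    for it in range(n_iterations):
        Z = rng.standard_normal((n, p)) @ L.T
        try:
            Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
            res = ebic_select(Z, gamma=gamma, tol=tol, max_iter=max_iter)
            weights[it] = res.estimate.partial_corr * res.estimate.adjacency
        except Exception:
            failed += 1
            weights[it] = np.nan
    if n_iterations and failed > max_failure_rate * n_iterations:
        raise RuntimeError(
            f"{failed}/{n_iterations} bootstrap iterations failed"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(weights, axis=0) if n_iterations else np.zeros((p, p))
    median = np.nan_to_num(median)
    median = 0.5 * (median + median.T)
    np.fill_diagonal(median, 0.0)
    return BootstrapNetwork(
        median_weights=median,
        n_iterations=n_iterations,
        n_failed=failed,
        seed=seed,
        base_estimate=base_estimate,
        labels=base_estimate.labels,
    )
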