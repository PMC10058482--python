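"""Sparse inverse-covariance estimation by the graphical lasso.

Maximises the L1-penalised Gaussian log-likelihood

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|

by block coordinate descent: the algorithm cycles through the variables,
solving a lasso regression of each variable on the rest (in terms of the
working covariance estimate W), exactly the classic formulation.  Only
off-diagonal entries are penalised, so the diagonal of W equals the diagonal
of S and ``lambda >= max_{i!=j} |S_ij|`` yields the empty graph.

The optimality (KKT) conditions of the objective are

    W_ii = S_ii,
    W_ij - S_ij = lambda * sign(Theta_ij)   where Theta_ij != 0,
    |W_ij - S_ij| <= lambda                 where Theta_ij  = 0,

with W = Theta^{-1}; :func:`kkt_violation` measures the worst-case breach
and serves as the primary correctness oracle.

The inner double loop is compiled with numba when available (pure-Python
fallback otherwise, same code path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import DataError

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

#: absolute threshold below which a precision entry counts as structural zero
EDGE_TOL = 1e-8


@njit(cache=True)
def _glasso_kernel(S, lam, tol, max_iter, inner_max, W, B):  # pragma: no cover
    """Block coordinate descent sweeps; W and B are updated in place."""
    p = S.shape[0]
    m = p - 1
    n_off = p * (p - 1)
    V = np.empty((m, m))
    s = np.empty(m)
    beta = np.empty(m)
    converged = False
    iters = 0
    for _sweep in range(max_iter):
        iters += 1
        total_change = 0.0
        for j in range(p):
            ii = 0
            for a in range(p):
                if a == j:
                    continue
                s[ii] = S[a, j]
                beta[ii] = B[a, j]
                jj = 0
                for b in range(p):
                    if b == j:
                        continue
                    V[ii, jj] = W[a, b]
                    jj += 1
                ii += 1
            c = V @ beta
            # lasso sub-problem: min 1/2 b'Vb - s'b + lam*|b|_1
            for _inner in range(inner_max):
                mx = 0.0
                for k in range(m):
                    vkk = V[k, k]
                    r = s[k] - (c[k] - vkk * beta[k])
                    if r > lam:
                        bnew = (r - lam) / vkk
                    elif r < -lam:
                        bnew = (r + lam) / vkk
                    else:
                        bnew = 0.0
                    d = bnew - beta[k]
                    if d != 0.0:
                        beta[k] = bnew
                        for q in range(m):
                            c[q] += V[q, k] * d
                        if abs(d) > mx:
                            mx = abs(d)
                if mx < 0.1 * tol:
                    break
            ii = 0
            for a in range(p):
                if a == j:
                    continue
                total_change += abs(W[a, j] - c[ii])
                W[a, j] = c[ii]
                W[j, a] = c[ii]
                B[a, j] = beta[ii]
                ii += 1
        if total_change / n_off < tol:
            converged = True
            break
    return converged, iters


@dataclass
class PrecisionEstimate:
    """Penalised precision-matrix estimate and derived quantities."""

    theta: np.ndarray          # p x p symmetric positive definite
    lam: float                 # penalty used
    covariance: np.ndarray     # W = Theta^{-1} from the optimisation
    converged: bool
    iterations: int
    labels: Optional[list] = None
    _B: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def partial_corr(self) -> np.ndarray:
        """rho_ij = -theta_ij / sqrt(theta_ii * theta_jj); diagonal set to 0."""
        d = np.sqrt(np.diag(self.theta))
        rho = -self.theta / np.outer(d, d)
        np.fill_diagonal(rho, 0.0)
        return rho

    @property
    def adjacency(self) -> np.ndarray:
        A = np.abs(self.theta) > EDGE_TOL
        np.fill_diagonal(A, False)
        return A

    @property
    def edges(self) -> set:
        A = self.adjacency
        return {(i, j) for i, j in zip(*np.where(np.triu(A, 1)))}

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def _validate_cov(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DataError("covariance must be square")
    if S.shape[0] < 2:
        raise DataError("need at least 2 biomarkers to estimate a network")
    if not np.allclose(S, S.T, atol=1e-10):
        raise DataError("covariance must be symmetric")
    if np.any(np.diag(S) <= 0):
        raise DataError("covariance diagonal must be positive")
    return 0.5 * (S + S.T)


def glasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 200,
    inner_max: int = 200,
    warm: Optional[PrecisionEstimate] = None,
    labels: Optional[list] = None,
) -> PrecisionEstimate:
    """Graphical lasso at a single penalty value.

    ``warm`` supplies a previous estimate (typically the fit at the adjacent,
    larger penalty on the regularisation path) whose working covariance and
    regression coefficients initialise the sweeps.  Convergence is declared
    when the mean absolute change of the off-diagonal working covariance in
    one full sweep drops below ``tol``; non-convergence is flagged on the
    result and warned about, not raised.
    """
    S = _validate_cov(S)
    if lam < 0:
        raise DataError("penalty must be non-negative")
    p = S.shape[0]

    eigmin = np.linalg.eigvalsh(S).min()
    if eigmin < -1e-8:
        warnings.warn(
            f"covariance not positive semidefinite (min eig {eigmin:.2e}); "
            "ridge regularisation applied"
        )
        S = S + (abs(eigmin) + 1e-8) * np.eye(p)

    off = S - np.diag(np.diag(S))
    lam_empty = np.abs(off).max()
    if lam >= lam_empty and lam > 0:
        # penalty large enough that the optimum is exactly diagonal
        theta = np.diag(1.0 / np.diag(S))
        return PrecisionEstimate(
            theta=theta,
            lam=float(lam),
            covariance=np.diag(np.diag(S)).astype(float),
            converged=True,
            iterations=0,
            labels=list(labels) if labels is not None else None,
            _B=np.zeros((p, p)),
        )

    if warm is not None and warm.covariance.shape == S.shape and warm._B is not None:
        W = warm.covariance.copy()
        np.fill_diagonal(W, np.diag(S))
        B = warm._B.copy()
    else:
        W = S.copy()
        B = np.zeros((p, p))

    converged, iters = _glasso_kernel(
        S, float(lam), float(tol), int(max_iter), int(inner_max), W, B
    )
    if not converged:
        warnings.warn(f"glasso did not converge in {max_iter} sweeps (lambda={lam:g})")

    # recover Theta from the final regressions: theta_jj = 1/(w_jj - w12'beta)
    theta = np.zeros((p, p))
    for j in range(p):
        idx = np.arange(p) != j
        beta = B[idx, j]
        denom = W[j, j] - W[idx, j] @ beta
        tjj = 1.0 / denom
        theta[j, j] = tjj
        theta[idx, j] = -beta * tjj
    theta = 0.5 * (theta + theta.T)
    theta[np.abs(theta) < EDGE_TOL] = 0.0
    np.fill_diagonal(theta, np.maximum(np.diag(theta), 1e-12))

    return PrecisionEstimate(
        theta=theta,
        lam=float(lam),
        covariance=W,
        converged=bool(converged),
        iterations=int(iters),
        labels=list(labels) if labels is not None else None,
        _B=B,
    )


def empirical_covariance(X: np.ndarray) -> np.ndarray:
    """Sample covariance (denominator n-1) of the processed matrix.

    On standardised columns this is the correlation matrix up to floating
    tolerance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise DataError("need at least 3 subjects for a covariance estimate")
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / (n - 1)


def lambda_path(S: np.ndarray, n_lambdas: int = 10, min_ratio: float = 0.1) -> np.ndarray:
    """Equally spaced penalty path from lambda_max down to min_ratio*lambda_max.

    ``lambda_max`` is the largest off-diagonal |S_ij| — the smallest penalty
    at which the graphical lasso returns an empty graph.
    """
    S = _validate_cov(S)
    off = S - np.diag(np.diag(S))
    lam_max = float(np.abs(off).max())
    if lam_max <= 0:
        raise DataError("all off-diagonal covariances are zero: degenerate path")
    return np.linspace(lam_max, min_ratio * lam_max, n_lambdas)


def fit_path(
    S: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> list:
    """Fit the glasso along a decreasing penalty path with warm starts."""
    fits = []
    warm = None
    for lam in lambdas:
        est = glasso(S, float(lam), tol=tol, max_iter=max_iter, warm=warm)
        fits.append(est)
        warm = est
    return fits


def kkt_violation(est: PrecisionEstimate, S: np.ndarray, lam: float) -> float:
    """Worst-case breach of the penalised-likelihood optimality conditions."""
    W = np.linalg.inv(est.theta)
    G = W - S
    p = S.shape[0]
    viol = np.abs(np.diag(G)).max()  # W_ii = S_ii
    off = ~np.eye(p, dtype=bool)
    zero = off & ~est.adjacency
    nonzero = off & est.adjacency
    if zero.any():
        viol = max(viol, float(np.maximum(np.abs(G[zero]) - lam, 0).max()))
    if nonzero.any():
        target = lam * np.sign(est.theta[nonzero])
        viol = max(viol, float(np.abs(G[nonzero] - target).max()))
    return float(viol)
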