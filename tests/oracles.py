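"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the LASSO oracle is a
plain coordinate-descent solver, the PCA oracle is an eigendecomposition of
the covariance matrix, and the cis-window oracle sorts everything and
truncates.
"""

from __future__ import annotations

import numpy as np


def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, alpha: float) -> float:
    """(1 / 2n) ||y - X beta||^2 + alpha ||beta||_1  (sklearn's scaling)."""
    n = y.shape[0]
    resid = y - X @ beta
    return float(resid @ resid / (2 * n) + alpha * np.abs(beta).sum())


def cd_lasso(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Cyclic coordinate descent for the LASSO (no intercept; y pre-centered)."""
    n, m = X.shape
    beta = np.zeros(m)
    col_sq = (X**2).sum(axis=0) / n
    resid = y.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(m):
            if col_sq[j] == 0.0:
                continue
            rho = X[:, j] @ resid / n + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - alpha, 0.0) / col_sq[j]
            delta = new - beta[j]
            if delta != 0.0:
                resid -= X[:, j] * delta
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return beta


def nearest_w_snps(cpg, snps, w: int) -> list[str]:
    """Sort-all-then-truncate oracle for cis-SNP selection."""
    ranked = sorted(
        (s for s in snps if s.chromosome == cpg.chromosome),
        key=lambda s: (abs(s.position - cpg.position), s.position, s.site_id),
    )
    return [s.site_id for s in ranked[:w]]


def eig_pca(matrix: np.ndarray, n_pcs: int):
    """PCA via eigendecomposition of the covariance of standardized columns.

    Returns (scores, explained_variance_ratio) with each component's sign fixed
    so its largest-magnitude loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = X - mean
    nz = sd > 0
    Z[:, nz] /= sd[nz]
    Z[:, ~nz] = 0.0
    cov = Z.T @ Z
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    scores = Z @ evecs[:, :n_pcs]
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
            scores[:, j] *= -1
    return scores, evals[:n_pcs] / total
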