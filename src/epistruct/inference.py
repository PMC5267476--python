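"""Population-structure inference from methylation (and genotype) matrices.

The supervised path (``epistructure``) restricts the methylation matrix to a
reference list of genetically informative CpGs, optionally regresses out
cell-composition covariates, and takes the top principal components as the
population-structure estimate. The unsupervised path is plain ``pca`` on the
full matrix, with or without covariate adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import (
    CovariateMatrix,
    GenotypeData,
    MethylationData,
    ReferenceList,
    apply_exclusion,
    standardize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PCResult",
    "regress_out",
    "pca",
    "epistructure",
    "genotype_pcs",
    "explained_variance_profile",
    "squared_correlation",
]


@dataclass
class PCResult:
    """Principal-component scores, loadings and explained-variance ratios."""

    sample_ids: list[str]
    scores: np.ndarray  # n_samples x n_pcs
    explained_variance_ratio: np.ndarray  # n_pcs, non-increasing
    loadings: np.ndarray  # n_sites x n_pcs
    site_ids: list[str]

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


def _align_covariates(
    sample_ids: list[str], covariates: CovariateMatrix
) -> np.ndarray:
    if set(sample_ids) != set(covariates.sample_ids):
        raise ValueError("covariate sample ids do not match methylation sample ids")
    order = [covariates.sample_ids.index(s) for s in sample_ids]
    return covariates.values[order, :]


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns that do not increase design rank."""
    bad: list[str] = []
    kept = np.empty((design.shape[0], 0))
    rank = 0
    for j, name in enumerate(names):
        cand = np.column_stack([kept, design[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(name)
    return bad


def regress_out(
    meth: MethylationData, covariates: CovariateMatrix
) -> MethylationData:
    """Replace each CpG by its OLS residual on an intercept plus covariates.

    This is how cell-type composition surrogates (e.g. the first six
    reference-free components) are removed before PCA; the result carries
    scale_tag "adjusted".
    """
    C = _align_covariates(meth.sample_ids, covariates)
    design = np.column_stack([np.ones(meth.n_samples), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, ["intercept"] + covariates.covariate_names)
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, meth.values, rcond=None)
    resid = meth.values - design @ beta
    return MethylationData(
        sample_ids=list(meth.sample_ids),
        cpgs=list(meth.cpgs),
        values=resid,
        scale_tag="adjusted",
    )


def pca(
    matrix: np.ndarray,
    n_pcs: int,
    sample_ids: list[str] | None = None,
    site_ids: list[str] | None = None,
) -> PCResult:
    """PCA on the column-standardized samples x sites matrix.

    Scores are U * s of the thin SVD of the standardized matrix; explained
    variance ratios are squared singular values over total variance. Each
    component's sign is fixed so its largest-magnitude loading is positive.
    If n_pcs exceeds the matrix rank, components are truncated with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("pca expects a 2-D matrix")
    n, m = X.shape
    if n_pcs < 1 or n_pcs > min(n, m):
        raise ValueError(f"n_pcs must be in [1, {min(n, m)}]: {n_pcs}")
    Z = standardize(X)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = s[0] * max(n, m) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank == 0:
        raise ValueError("matrix has rank 0 after standardization")
    k = n_pcs
    if n_pcs > rank:
        warnings.warn(
            f"requested {n_pcs} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        k = rank
    total = float((s**2).sum())
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T.copy()
    # sign convention: dominant loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCResult(
        sample_ids=list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n)],
        scores=scores,
        explained_variance_ratio=(s[:k] ** 2) / total,
        loadings=loadings,
        site_ids=list(site_ids) if site_ids is not None else [f"x{j}" for j in range(m)],
    )


def epistructure(
    meth: MethylationData,
    ref: ReferenceList,
    covariates: CovariateMatrix | None = None,
    n_pcs: int = 2,
    exclusions: set[str] | None = None,
) -> PCResult:
    """Methylation-based population-structure PCs from reference CpGs.

    Pipeline order: restrict to reference CpGs present in the data, apply the
    optional probe-exclusion list, regress out optional covariates, then PCA.
    Reference CpGs absent from the platform are dropped silently but counted.
    """
    ref_ids = set(ref.cpg_ids)
    present_mask = [c.site_id in ref_ids for c in meth.cpgs]
    n_found = sum(present_mask)
    if n_found == 0:
        raise ValueError("no reference CpG present in the methylation data")
    logger.info(
        "reference CpGs found in data: %d of %d (%d missing)",
        n_found,
        len(ref),
        len(ref) - n_found,
    )
    mask = np.asarray(present_mask, dtype=bool)
    sub = MethylationData(
        sample_ids=list(meth.sample_ids),
        cpgs=[c for c, kept in zip(meth.cpgs, present_mask) if kept],
        values=meth.values[:, mask],
        scale_tag=meth.scale_tag,
    )
    if exclusions:
        sub = apply_exclusion(sub, exclusions).data
    if covariates is not None and covariates.values.shape[1] > 0:
        sub = regress_out(sub, covariates)
    return pca(sub.values, n_pcs, sample_ids=sub.sample_ids, site_ids=sub.cpg_ids)


def genotype_pcs(geno: GenotypeData, n_pcs: int = 2) -> PCResult:
    """Genotype-based population-structure PCs (PCA on standardized dosages)."""
    if geno.has_missing():
        raise ValueError("genotypes must be imputed before genotype_pcs")
    return pca(
        geno.dosages, n_pcs, sample_ids=geno.sample_ids, site_ids=geno.snp_ids
    )


def explained_variance_profile(
    pcs: PCResult | np.ndarray, target: np.ndarray, max_j: int
) -> list[float]:
    """In-sample OLS R^2 of a target on the first j PCs, for j = 1..max_j.

    The profile is non-decreasing in j (nested models). The target must be
    non-constant.
    """
    S = pcs.scores if isinstance(pcs, PCResult) else np.asarray(pcs, dtype=float)
    t = np.asarray(target, dtype=float).ravel()
    if t.shape[0] != S.shape[0]:
        raise ValueError(f"target length {t.shape[0]} != {S.shape[0]} samples")
    if np.std(t) == 0.0:
        raise ValueError("target is constant; R^2 undefined")
    if not 1 <= max_j <= S.shape[1]:
        raise ValueError(f"max_j must be in [1, {S.shape[1]}]: {max_j}")
    sst = float(((t - t.mean()) ** 2).sum())
    profile: list[float] = []
    for j in range(1, max_j + 1):
        design = np.column_stack([np.ones(S.shape[0]), S[:, :j]])
        beta, *_ = np.linalg.lstsq(design, t, rcond=None)
        sse = float(((t - design @ beta) ** 2).sum())
        profile.append(1.0 - sse / sst)
    return profile


def squared_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two vectors (0 if either constant)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)
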