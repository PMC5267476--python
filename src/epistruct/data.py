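"""Core data containers and matrix-level preprocessing.

The containers are thin, validated wrappers around numpy arrays with explicit
sample and site labels. Genotypes are dosage-coded (0/1/2 copies of the coded
allele, real-valued after imputation or when imputed dosages are supplied);
methylation is carried on the beta scale (proportions in [0, 1]) or as
unconstrained residuals after covariate adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SiteAnnotation",
    "GenotypeData",
    "MethylationData",
    "CovariateMatrix",
    "ReferenceList",
    "ExclusionResult",
    "impute_genotypes",
    "standardize",
    "apply_exclusion",
]


@dataclass(frozen=True, order=True)
class SiteAnnotation:
    """Genomic address of a SNP or CpG probe (1-based position)."""

    site_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"position must be >= 1 (site {self.site_id!r}: {self.position})"
            )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def _check_axes(n_samples: int, n_sites: int, values: np.ndarray, what: str) -> None:
    if values.ndim != 2:
        raise ValueError(f"{what} matrix must be 2-D, got {values.ndim}-D")
    if values.shape != (n_samples, n_sites):
        raise ValueError(
            f"{what} matrix shape {values.shape} does not match "
            f"{n_samples} samples x {n_sites} sites"
        )


@dataclass
class GenotypeData:
    """Samples x SNPs dosage matrix; NaN marks a missing call."""

    sample_ids: list[str]
    snps: list[SiteAnnotation]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique([s.site_id for s in self.snps], "SNP")
        _check_axes(len(self.sample_ids), len(self.snps), self.dosages, "dosage")

    @property
    def snp_ids(self) -> list[str]:
        return [s.site_id for s in self.snps]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())


@dataclass
class MethylationData:
    """Samples x CpGs methylation matrix.

    ``scale_tag`` is ``"beta"`` for raw proportions (entries in [0, 1]) and
    ``"adjusted"`` for residuals after covariate regression.
    """

    sample_ids: list[str]
    cpgs: list[SiteAnnotation]
    values: np.ndarray
    scale_tag: str = "beta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in ("beta", "adjusted"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(self.sample_ids, "sample")
        _check_unique([c.site_id for c in self.cpgs], "CpG")
        _check_axes(len(self.sample_ids), len(self.cpgs), self.values, "methylation")
        if np.isnan(self.values).any():
            raise ValueError("missing methylation values are not supported")
        if self.scale_tag == "beta":
            if self.values.size and (
                self.values.min() < 0.0 or self.values.max() > 1.0
            ):
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def cpg_ids(self) -> list[str]:
        return [c.site_id for c in self.cpgs]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)


@dataclass
class CovariateMatrix:
    """Samples x covariates design block (no intercept column)."""

    sample_ids: list[str]
    covariate_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.covariate_names, "covariate")
        _check_axes(
            len(self.sample_ids), len(self.covariate_names), self.values, "covariate"
        )
        if np.isnan(self.values).any():
            raise ValueError("covariates must not contain missing values")


@dataclass
class ReferenceList:
    """Ordered list of genetically informative CpGs with CV scores.

    Entries are (cpg_id, score) pairs sorted by descending score (ties broken
    by id); scores are cross-validated squared correlations in [0, 1].
    """

    entries: list[tuple[str, float]]
    params: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        entries = [(str(c), float(s)) for c, s in self.entries]
        _check_unique([c for c, _ in entries], "reference CpG")
        for cpg_id, score in entries:
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"reference score for {cpg_id!r} outside [0, 1]: {score}"
                )
        self.entries = sorted(entries, key=lambda e: (-e[1], e[0]))

    @property
    def cpg_ids(self) -> list[str]:
        return [c for c, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def impute_genotypes(
    geno: GenotypeData, max_missing_rate: float = 0.05
) -> GenotypeData:
    """Drop high-missingness SNPs and mean-impute the rest.

    SNP columns with a missing fraction above ``max_missing_rate`` (default 5%)
    are removed; remaining missing dosages are replaced by the column mean over
    observed calls. Observed entries are never altered.
    """
    if not 0.0 <= max_missing_rate < 1.0:
        raise ValueError(f"max_missing_rate must be in [0, 1): {max_missing_rate}")
    D = geno.dosages
    missing = np.isnan(D)
    rate = missing.mean(axis=0)
    keep = rate <= max_missing_rate
    n_all_missing = int((rate == 1.0).sum())
    if n_all_missing:
        logger.info("dropping %d entirely missing SNP column(s)", n_all_missing)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropping %d of %d SNPs with missing rate > %.3g",
            n_dropped,
            geno.n_snps,
            max_missing_rate,
        )
    D = D[:, keep].copy()
    snps = [s for s, k in zip(geno.snps, keep) if k]
    col_missing = np.isnan(D)
    if col_missing.any():
        col_mean = np.nanmean(D, axis=0)
        idx = np.nonzero(col_missing)
        D[idx] = col_mean[idx[1]]
    logger.info("retained %d SNPs after imputation", len(snps))
    return GenotypeData(sample_ids=list(geno.sample_ids), snps=snps, dosages=D)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Column-standardize to mean 0, population (1/n) SD 1.

    Zero-variance columns become all-zero rather than raising: near-constant
    probes are routine in methylation arrays and must not abort a run.
    """
    X = np.array(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("standardize expects a 2-D matrix")
    if np.isnan(X).any():
        raise ValueError("standardize requires complete data")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population (1/n) SD
    X -= mean
    nonzero = sd > 0
    X[:, nonzero] /= sd[nonzero]
    X[:, ~nonzero] = 0.0
    n_const = int((~nonzero).sum())
    if n_const:
        logger.info("standardize: %d zero-variance column(s) set to zero", n_const)
    return X


class ExclusionResult(NamedTuple):
    data: MethylationData
    n_removed: int
    n_absent: int


def apply_exclusion(
    meth: MethylationData, exclusion_ids: Iterable[str]
) -> ExclusionResult:
    """Remove probes named in an exclusion list (e.g. polymorphic CpGs).

    Returns the filtered data plus how many listed probes were removed and how
    many were absent from the data. Raises if nothing would remain.
    """
    excl = set(exclusion_ids)
    keep_mask = [c.site_id not in excl for c in meth.cpgs]
    n_removed = len(meth.cpgs) - sum(keep_mask)
    n_absent = len(excl) - n_removed
    if not any(keep_mask):
        raise ValueError("exclusion list removes every CpG in the data")
    data = MethylationData(
        sample_ids=list(meth.sample_ids),
        cpgs=[c for c, k in zip(meth.cpgs, keep_mask) if k],
        values=meth.values[:, np.asarray(keep_mask, dtype=bool)],
        scale_tag=meth.scale_tag,
    )
    logger.info(
        "exclusion: removed %d probe(s), %d listed id(s) absent from data",
        n_removed,
        n_absent,
    )
    return ExclusionResult(data, n_removed, n_absent)


def subset_samples(data, indices: Sequence[int]):
    """Row-subset a GenotypeData or MethylationData by sample indices."""
    idx = list(indices)
    ids = [data.sample_ids[i] for i in idx]
    if isinstance(data, GenotypeData):
        return GenotypeData(ids, list(data.snps), data.dosages[idx, :])
    if isinstance(data, MethylationData):
        return MethylationData(
            ids, list(data.cpgs), data.values[idx, :], data.scale_tag
        )
    raise TypeError(f"cannot subset {type(data).__name__}")


__all__.append("subset_samples")
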