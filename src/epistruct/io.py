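"""Delimited-text readers and writers.

All files are tab-delimited UTF-8 with '.' decimal separators; lines starting
with '#' are comments. Matrices carry one header row and one id column and may
be stored samples-as-rows or sites-as-rows (``orientation``). Site annotations
live in a separate 3-column table (site_id, chromosome, position).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    CovariateMatrix,
    GenotypeData,
    MethylationData,
    ReferenceList,
    SiteAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "write_annotations",
    "read_genotypes",
    "read_methylation",
    "read_covariates",
    "read_exclusion_list",
    "read_reference_list",
    "write_reference_list",
]

_NA_STRINGS = {"", "NA", "na", "NaN", "nan"}


def _check_header_duplicates(path) -> None:
    # pandas silently mangles duplicate column headers, so inspect the raw line
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                cols = line.rstrip("\n").split("\t")[1:]
                seen: set[str] = set()
                for c in cols:
                    if c in seen:
                        raise ValueError(f"duplicate column id in {path}: {c!r}")
                    seen.add(c)
                return


def _read_labelled_table(path) -> pd.DataFrame:
    _check_header_duplicates(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    for axis, labels in (("row", df.index), ("column", df.columns)):
        dup = labels[labels.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {axis} id in {path}: {dup[0]!r}")
    return df


def _to_numeric(df: pd.DataFrame, path, allow_missing: bool) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna()
        is_na_token = raw.isin(_NA_STRINGS)
        nonnumeric = bad & ~is_na_token
        if nonnumeric.any():
            i = int(np.flatnonzero(nonnumeric.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell in {path} at row {raw.index[i]!r}, "
                f"column {col!r}: {raw.iloc[i]!r}"
            )
        if not allow_missing and bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"missing value in {path} at row {raw.index[i]!r}, column {col!r}"
            )
        out[:, j] = numeric.to_numpy(dtype=float)
    return out


def read_matrix(
    path, orientation: str = "samples", allow_missing: bool = False
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a labelled numeric matrix as (sample_ids, site_ids, samples x sites).

    ``orientation`` names what the file's *rows* are ("samples" or "sites");
    the returned matrix is always samples x sites.
    """
    if orientation not in ("samples", "sites"):
        raise ValueError(f"orientation must be 'samples' or 'sites': {orientation!r}")
    df = _read_labelled_table(path)
    values = _to_numeric(df, path, allow_missing)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if orientation == "sites":
        return cols, rows, values.T
    return rows, cols, values


def write_matrix(
    path,
    sample_ids: Sequence[str],
    site_ids: Sequence[str],
    values: np.ndarray,
    orientation: str = "samples",
    index_name: str = "id",
) -> None:
    """Write a samples x sites matrix as TSV (transposed if orientation='sites')."""
    df = pd.DataFrame(np.asarray(values), index=list(sample_ids), columns=list(site_ids))
    if orientation == "sites":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"orientation must be 'samples' or 'sites': {orientation!r}")
    df.index.name = index_name
    df.to_csv(path, sep="\t", na_rep="NA")


def read_annotations(path) -> dict[str, SiteAnnotation]:
    """Read a (site_id, chromosome, position) table keyed by site id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"annotation file {path} needs 3 columns, got {df.shape[1]}")
    out: dict[str, SiteAnnotation] = {}
    for sid, chrom, pos in df.iloc[:, :3].itertuples(index=False):
        if sid in out:
            raise ValueError(f"duplicate annotation id in {path}: {sid!r}")
        out[sid] = SiteAnnotation(str(sid), str(chrom), int(pos))
    return out


def write_annotations(path, sites: Iterable[SiteAnnotation]) -> None:
    pd.DataFrame(
        [(s.site_id, s.chromosome, s.position) for s in sites],
        columns=["site_id", "chromosome", "position"],
    ).to_csv(path, sep="\t", index=False)


def _join_annotations(site_ids, values, annots, what):
    """Keep sites that have an annotation; drop (and count) the rest."""
    kept = [i for i, s in enumerate(site_ids) if s in annots]
    n_dropped = len(site_ids) - len(kept)
    if n_dropped:
        logger.warning("%s: dropped %d site(s) lacking annotation", what, n_dropped)
    sites = [annots[site_ids[i]] for i in kept]
    return sites, values[:, kept]


def read_genotypes(
    matrix_path, annotation_path, orientation: str = "samples"
) -> GenotypeData:
    """Read a dosage matrix (missing cells allowed) plus SNP annotations."""
    sample_ids, snp_ids, values = read_matrix(
        matrix_path, orientation, allow_missing=True
    )
    annots = read_annotations(annotation_path)
    snps, values = _join_annotations(snp_ids, values, annots, "genotypes")
    return GenotypeData(sample_ids=sample_ids, snps=snps, dosages=values)


def read_methylation(
    matrix_path,
    annotation_path,
    orientation: str = "samples",
    scale_tag: str = "beta",
) -> MethylationData:
    """Read a complete methylation matrix plus CpG annotations."""
    sample_ids, cpg_ids, values = read_matrix(
        matrix_path, orientation, allow_missing=False
    )
    annots = read_annotations(annotation_path)
    cpgs, values = _join_annotations(cpg_ids, values, annots, "methylation")
    return MethylationData(
        sample_ids=sample_ids, cpgs=cpgs, values=values, scale_tag=scale_tag
    )


def read_covariates(path, orientation: str = "samples") -> CovariateMatrix:
    sample_ids, names, values = read_matrix(path, orientation, allow_missing=False)
    return CovariateMatrix(sample_ids=sample_ids, covariate_names=names, values=values)


def read_exclusion_list(path) -> set[str]:
    """Read a one-probe-id-per-line exclusion list ('#' comments allowed)."""
    ids: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


_INT_PARAMS = {"w", "p", "k_folds", "fold_seed"}


def write_reference_list(ref: ReferenceList, path) -> None:
    """Persist a reference list as TSV with '#' param header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(ref.params):
            fh.write(f"# {key}={ref.params[key]}\n")
        if ref.provenance:
            fh.write(f"# provenance={ref.provenance}\n")
        fh.write("cpg_id\tscore\n")
        for cpg_id, score in ref.entries:
            fh.write(f"{cpg_id}\t{score!r}\n")


def read_reference_list(path) -> ReferenceList:
    params: dict = {}
    provenance = ""
    entries: list[tuple[str, float]] = []
    header_seen = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                val = val.strip()
                if key == "provenance":
                    provenance = val
                elif key in _INT_PARAMS:
                    params[key] = int(val)
                else:
                    try:
                        params[key] = float(val)
                    except ValueError:
                        params[key] = val
            continue
        if not header_seen:
            header_seen = True  # column header line
            continue
        cpg_id, _, score = line.partition("\t")
        try:
            value = float(score)
        except ValueError as exc:
            raise ValueError(f"bad score for {cpg_id!r} in {path}: {score!r}") from exc
        if not 0.0 <= value <= 1.0:
            raise ValueError(
                f"score outside [0, 1] for {cpg_id!r} in {path}: {value}"
            )
        entries.append((cpg_id, value))
    return ReferenceList(entries=entries, params=params, provenance=provenance)
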