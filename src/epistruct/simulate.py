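"""Synthetic admixed cohorts with linked genotypes and methylation.

Genotypes follow a Balding-Nichols admixture model: ancestral allele
frequencies are Uniform(0.1, 0.9); each ancestry draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F) at divergence F; per-sample ancestry proportions
are Dirichlet; dosages are Binomial(2, q . p). Methylation mixes four CpG
kinds: *genetic* CpGs are linear in a few cis-SNPs with a planted variance
fraction rho^2, *cellular* CpGs are linear in simulated leukocyte proportions
(the dominant variance component, as in whole-blood arrays), *noise* CpGs are
pure Gaussian, and *polymorphic* CpGs copy a nearby SNP's scaled dosage
(probe-artifact emulation). Values are mapped to the beta scale by a mild
affine clamp so the linear model stays approximately correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from . import io as eio
from .data import (
    CovariateMatrix,
    GenotypeData,
    MethylationData,
    SiteAnnotation,
    subset_samples,
)
from .reference import select_cis_snps

logger = logging.getLogger(__name__)

__all__ = [
    "SimTruth",
    "CausalRecord",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_cohort",
    "make_fixture",
    "hudson_fst",
    "FIXTURE_PROFILES",
]

_SNP_SPACING = 1_000  # bp between adjacent simulated SNPs
_SQUASH_AMPLITUDE = 0.06  # beta-scale SD of one unit of raw signal
_SQUASH_CLIP = (0.02, 0.98)
_CELL_ALPHA = np.array([30.0, 12.0, 4.0, 2.5, 2.0, 1.5])  # 6 leukocyte types


class CausalRecord(NamedTuple):
    kind: str  # genetic | cellular | noise | polymorphic
    snp_ids: tuple[str, ...]
    betas: tuple[float, ...]
    rho2: float


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    admixture: np.ndarray  # n_samples x n_ancestries, rows on the simplex
    pop_freqs: np.ndarray  # n_ancestries x n_snps
    causal_map: dict[str, CausalRecord] = field(default_factory=dict)
    cell_props: np.ndarray | None = None  # n_samples x n_celltypes
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(self.admixture.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("admixture rows must sum to 1")

    def cpg_ids_of_kind(self, kind: str) -> list[str]:
        return [c for c, rec in self.causal_map.items() if rec.kind == kind]


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    n_ancestries: int = 2,
    fst: float = 0.1,
    admix_alpha: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[GenotypeData, SimTruth]:
    """Balding-Nichols admixed genotypes on two chromosomes.

    ``admix_alpha`` defaults to 0.25 per ancestry, giving the bimodal,
    two-cluster structure typical of strongly admixed two-way cohorts.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst must be in (0, 1): {fst}")
    if n_ancestries < 1:
        raise ValueError(f"n_ancestries must be >= 1: {n_ancestries}")
    alpha = (
        np.full(n_ancestries, 0.25)
        if admix_alpha is None
        else np.asarray(admix_alpha, dtype=float)
    )
    if alpha.shape != (n_ancestries,) or (alpha <= 0).any():
        raise ValueError("admix_alpha must be a positive vector of length n_ancestries")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_snps)
    ratio = (1.0 - fst) / fst
    pop_freqs = rng.beta(
        p_anc * ratio, (1.0 - p_anc) * ratio, size=(n_ancestries, n_snps)
    )
    Q = rng.dirichlet(alpha, size=n_samples)
    Q = Q / Q.sum(axis=1, keepdims=True)
    ind_freq = np.clip(Q @ pop_freqs, 0.0, 1.0)
    dosages = rng.binomial(2, ind_freq).astype(float)

    half = n_snps - n_snps // 2
    snps = [
        SiteAnnotation(
            f"snp{i:05d}",
            "1" if i < half else "2",
            _SNP_SPACING * ((i if i < half else i - half) + 1),
        )
        for i in range(n_snps)
    ]
    sample_ids = [f"ind{i:04d}" for i in range(n_samples)]
    geno = GenotypeData(sample_ids=sample_ids, snps=snps, dosages=dosages)
    truth = SimTruth(admixture=Q, pop_freqs=pop_freqs, seed=seed)
    return geno, truth


def _unit_var(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_methylation(
    geno: GenotypeData,
    truth: SimTruth,
    n_cpgs: int,
    frac_genetic: float = 0.25,
    frac_cellular: float = 0.5,
    rho2_genetic: float = 0.8,
    cell_var_scale: float = 3.0,
    frac_polymorphic: float = 0.0,
    w: int = 50,
    max_causal: int = 3,
    seed: int = 0,
) -> tuple[MethylationData, SimTruth]:
    """Methylation matrix with planted genetic / cellular / noise structure.

    Genetic CpGs draw 1..max_causal causal SNPs from their cis window (the w
    nearest same-chromosome SNPs) and are scaled so that in-sample
    var(genetic)/var(total) equals ``rho2_genetic`` exactly before squashing.
    Cellular CpGs carry a cell-composition signal with variance fraction
    cell_var_scale^2 / (cell_var_scale^2 + 1). Polymorphic CpGs copy their
    nearest SNP's standardized dosage.
    """
    if frac_genetic + frac_cellular + frac_polymorphic > 1.0 + 1e-12:
        raise ValueError("CpG kind fractions must sum to at most 1")
    if not 0.0 <= rho2_genetic <= 1.0:
        raise ValueError(f"rho2_genetic must be in [0, 1]: {rho2_genetic}")
    rng = np.random.default_rng(seed)
    n = geno.n_samples

    if truth.cell_props is None:
        truth.cell_props = rng.dirichlet(_CELL_ALPHA, size=n)
    cells_std = truth.cell_props - truth.cell_props.mean(axis=0)
    sds = cells_std.std(axis=0)
    cells_std = np.divide(cells_std, sds, out=np.zeros_like(cells_std), where=sds > 0)

    n_gen = int(round(frac_genetic * n_cpgs))
    n_cell = int(round(frac_cellular * n_cpgs))
    n_poly = int(round(frac_polymorphic * n_cpgs))
    kinds = (
        ["genetic"] * n_gen
        + ["cellular"] * n_cell
        + ["polymorphic"] * n_poly
        + ["noise"] * (n_cpgs - n_gen - n_cell - n_poly)
    )
    rng.shuffle(kinds)

    max_pos = max(s.position for s in geno.snps)
    chroms = sorted({s.chromosome for s in geno.snps})
    snp_index = {s.site_id: j for j, s in enumerate(geno.snps)}

    cpgs: list[SiteAnnotation] = []
    raw = np.empty((n, n_cpgs))
    causal_map: dict[str, CausalRecord] = {}
    for j, kind in enumerate(kinds):
        cpg_id = f"cg{j:06d}"
        cpg = SiteAnnotation(
            cpg_id,
            str(rng.choice(chroms)),
            int(rng.integers(1, max_pos + 1)),
        )
        window = select_cis_snps(cpg, geno.snps, w)
        while not window:  # can only happen on a SNP-free chromosome
            logger.info("reassigning cis window for %s", cpg_id)
            cpg = SiteAnnotation(
                cpg_id, str(rng.choice(chroms)), int(rng.integers(1, max_pos + 1))
            )
            window = select_cis_snps(cpg, geno.snps, w)
        noise = rng.standard_normal(n)
        noise = _unit_var(noise - noise.mean())
        if kind == "genetic" and rho2_genetic > 0.0:
            k_causal = int(rng.integers(1, max_causal + 1))
            chosen = list(rng.choice(window, size=min(k_causal, len(window)), replace=False))
            betas = rng.standard_normal(len(chosen))
            X = geno.dosages[:, [snp_index[s] for s in chosen]]
            g = (X - X.mean(axis=0)) @ betas
            if g.std() == 0.0:  # monomorphic picks: degrade to noise
                raw[:, j] = noise
                causal_map[cpg_id] = CausalRecord("noise", (), (), 0.0)
            else:
                g = _unit_var(g - g.mean())
                raw[:, j] = np.sqrt(rho2_genetic) * g + np.sqrt(1 - rho2_genetic) * noise
                causal_map[cpg_id] = CausalRecord(
                    "genetic", tuple(chosen), tuple(betas), rho2_genetic
                )
        elif kind == "genetic":  # rho2 = 0: genetic label, pure noise signal
            raw[:, j] = noise
            causal_map[cpg_id] = CausalRecord("genetic", (), (), 0.0)
        elif kind == "cellular":
            u = rng.standard_normal(cells_std.shape[1])
            c = cells_std @ u
            if c.std() == 0.0:
                raw[:, j] = noise
                causal_map[cpg_id] = CausalRecord("noise", (), (), 0.0)
            else:
                c = _unit_var(c - c.mean())
                raw[:, j] = cell_var_scale * c + noise
                causal_map[cpg_id] = CausalRecord("cellular", (), tuple(u), 0.0)
        elif kind == "polymorphic":
            snp_id = window[0]
            d = geno.dosages[:, snp_index[snp_id]]
            if d.std() == 0.0:
                raw[:, j] = noise
                causal_map[cpg_id] = CausalRecord("noise", (), (), 0.0)
            else:
                raw[:, j] = _unit_var(d - d.mean())
                causal_map[cpg_id] = CausalRecord(
                    "polymorphic", (snp_id,), (1.0,), 1.0
                )
        else:
            raw[:, j] = noise
            causal_map[cpg_id] = CausalRecord("noise", (), (), 0.0)
        cpgs.append(cpg)

    base = rng.uniform(0.35, 0.65, size=n_cpgs)
    beta_values = np.clip(base + _SQUASH_AMPLITUDE * raw, *_SQUASH_CLIP)
    meth = MethylationData(
        sample_ids=list(geno.sample_ids),
        cpgs=cpgs,
        values=beta_values,
        scale_tag="beta",
    )
    truth.causal_map.update(causal_map)
    return meth, truth


def simulate_cohort(
    n_samples: int,
    n_snps: int,
    n_cpgs: int,
    seed: int = 0,
    n_ancestries: int = 2,
    fst: float = 0.1,
    admix_alpha: Sequence[float] | None = None,
    **meth_kwargs,
) -> tuple[GenotypeData, MethylationData, CovariateMatrix, SimTruth]:
    """Genotypes + methylation + cell-proportion covariates in one call."""
    geno, truth = simulate_genotypes(
        n_samples, n_snps, n_ancestries=n_ancestries, fst=fst,
        admix_alpha=admix_alpha, seed=seed,
    )
    meth, truth = simulate_methylation(geno, truth, n_cpgs, seed=seed + 1, **meth_kwargs)
    # proportions sum to 1, so drop the last cell type to keep the design
    # full rank alongside an intercept
    covars = CovariateMatrix(
        sample_ids=list(geno.sample_ids),
        covariate_names=[f"cell{t}" for t in range(truth.cell_props.shape[1] - 1)],
        values=truth.cell_props[:, :-1],
    )
    return geno, meth, covars, truth


def hudson_fst(dosages: np.ndarray, labels: np.ndarray) -> float:
    """Hudson Fst (ratio of averages) between two labelled sample groups."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"hudson_fst needs exactly 2 groups, got {groups.size}")
    num = 0.0
    den = 0.0
    for snp in np.asarray(dosages, dtype=float).T:
        p = []
        m = []
        for g in groups:
            d = snp[labels == g]
            p.append(d.mean() / 2.0)
            m.append(2 * d.size)  # allele count
        p1, p2 = p
        m1, m2 = m
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


FIXTURE_PROFILES: dict[str, dict] = {
    "tiny": dict(
        n_train=60, n_test=0, n_snps=300, n_cpgs=120,
        frac_genetic=0.25, frac_cellular=0.4, frac_polymorphic=0.05,
        rho2_genetic=0.8, cell_var_scale=3.0, fst=0.1,
    ),
    "fullscale": dict(
        n_train=800, n_test=300, n_snps=4000, n_cpgs=5000,
        frac_genetic=0.1, frac_cellular=0.5, frac_polymorphic=0.05,
        rho2_genetic=0.8, cell_var_scale=3.0, fst=0.1,
    ),
}


def _write_cohort(out: Path, geno, meth, covars, truth, sample_idx) -> dict[str, Path]:
    out.mkdir(parents=True, exist_ok=True)
    g = subset_samples(geno, sample_idx)
    m = subset_samples(meth, sample_idx)
    paths = {
        "geno": out / "geno.tsv",
        "geno_annot": out / "geno_annot.tsv",
        "meth": out / "meth.tsv",
        "meth_annot": out / "meth_annot.tsv",
        "covars": out / "covars.tsv",
        "admixture": out / "truth_admixture.tsv",
        "cpg_kinds": out / "truth_cpg_kinds.tsv",
        "polymorphic": out / "polymorphic_ids.txt",
    }
    eio.write_matrix(paths["geno"], g.sample_ids, g.snp_ids, g.dosages)
    eio.write_annotations(paths["geno_annot"], g.snps)
    eio.write_matrix(paths["meth"], m.sample_ids, m.cpg_ids, m.values)
    eio.write_annotations(paths["meth_annot"], m.cpgs)
    eio.write_matrix(
        paths["covars"],
        g.sample_ids,
        covars.covariate_names,
        covars.values[sample_idx, :],
    )
    eio.write_matrix(
        paths["admixture"],
        g.sample_ids,
        [f"ancestry{k}" for k in range(truth.admixture.shape[1])],
        truth.admixture[sample_idx, :],
    )
    with open(paths["cpg_kinds"], "w", encoding="utf-8") as fh:
        fh.write("cpg_id\tkind\trho2\n")
        for cpg_id, rec in truth.causal_map.items():
            fh.write(f"{cpg_id}\t{rec.kind}\t{rec.rho2!r}\n")
    with open(paths["polymorphic"], "w", encoding="utf-8") as fh:
        for cpg_id in truth.cpg_ids_of_kind("polymorphic"):
            fh.write(cpg_id + "\n")
    return paths


def make_fixture(profile_name: str, seed: int, out_dir) -> dict[str, Path]:
    """Write a named simulation profile to disk as TSV inputs + truth tables.

    Profiles: ``tiny`` (single 60-sample cohort for unit tests) and
    ``fullscale`` (an 800-sample reference cohort plus a 300-sample target
    cohort sharing the same causal structure, under train/ and test/).
    """
    if profile_name not in FIXTURE_PROFILES:
        raise ValueError(
            f"unknown profile {profile_name!r}; choose from {sorted(FIXTURE_PROFILES)}"
        )
    prof = dict(FIXTURE_PROFILES[profile_name])
    n_train = prof.pop("n_train")
    n_test = prof.pop("n_test")
    n_snps = prof.pop("n_snps")
    n_cpgs = prof.pop("n_cpgs")
    fst = prof.pop("fst")
    geno, meth, covars, truth = simulate_cohort(
        n_train + n_test, n_snps, n_cpgs, seed=seed, fst=fst, **prof
    )
    out = Path(out_dir)
    if n_test == 0:
        return _write_cohort(out, geno, meth, covars, truth, list(range(n_train)))
    paths = {}
    train = _write_cohort(
        out / "train", geno, meth, covars, truth, list(range(n_train))
    )
    test = _write_cohort(
        out / "test", geno, meth, covars, truth,
        list(range(n_train, n_train + n_test)),
    )
    paths.update({f"train_{k}": v for k, v in train.items()})
    paths.update({f"test_{k}": v for k, v in test.items()})
    return paths
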