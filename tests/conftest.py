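import numpy as np
import pytest

from epistruct import BuilderParams, simulate_cohort
from epistruct.data import SiteAnnotation


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small admixed cohort with genetic, cellular, polymorphic and noise CpGs."""
    geno, meth, covars, truth = simulate_cohort(
        n_samples=80,
        n_snps=200,
        n_cpgs=60,
        seed=11,
        frac_genetic=0.3,
        frac_cellular=0.3,
        frac_polymorphic=0.1,
    )
    return geno, meth, covars, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_params():
    return BuilderParams(w=20, p=5, k_folds=5, score_threshold=0.5, fold_seed=3)


def make_site(site_id="cg0", chromosome="1", position=1000):
    return SiteAnnotation(site_id, chromosome, position)
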