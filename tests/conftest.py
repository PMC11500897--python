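import numpy as np
import pytest
from hypothesis import settings

from epissa import Dataset, SearchParams, find_dnme_model, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_dataset(genotypes, phenotype, names=None) -> Dataset:
    genotypes = np.asarray(genotypes)
    if names is None:
        names = [f"S{i}" for i in range(genotypes.shape[1])]
    return Dataset(genotypes=genotypes, phenotype=np.asarray(phenotype), snp_names=names)


@pytest.fixture(scope="session")
def dnme_model():
    """A 2-SNP no-marginal-effect model at MAF 0.2, heritability 0.2."""
    return find_dnme_model(2, (0.2, 0.2), 0.2, rng=np.random.default_rng(20240101))


@pytest.fixture(scope="session")
def dnme_dataset(dnme_model):
    """One simulated case-control file: 100 SNPs, 800 cases + 800 controls."""
    return generate_dataset(
        dnme_model, 800, 800, 100, rng=np.random.default_rng(20240102)
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Phenotype independent of every SNP: 800 + 800 samples, 30 SNPs."""
    rng = np.random.default_rng(20240103)
    geno = rng.integers(0, 3, size=(1600, 30), dtype=np.int8)
    phen = np.repeat([0, 1], 800).astype(np.int8)
    return Dataset(genotypes=geno, phenotype=phen, snp_names=[f"S{i}" for i in range(30)])


@pytest.fixture
def small_params():
    return SearchParams(n=10, max_generations=5, seed=3)
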