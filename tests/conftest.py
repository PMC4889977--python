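import numpy as np
import pytest
from hypothesis import settings

from sexreg import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but fully structured cohort shared by read-only tests."""
    cfg = synthetic.SimConfig(
        n_male=60, n_female=120, n_genes_auto=24, n_genes_x=10,
        variants_per_gene=3, ase_n_het_per_sex=8, n_peaks=80,
        gwas_n_traits=2, gwas_variants_per_trait=8, seed=42)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
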