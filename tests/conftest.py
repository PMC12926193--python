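import numpy as np
import pandas as pd
import pytest

from scaqtl import caqtl
from scaqtl.synthdata import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured dataset shared across module tests."""
    cfg = SimConfig(
        n_donors=24,
        n_libraries_per_study=3,
        cells_per_donor=(30, 40),
        n_peaks=60,
        snps_per_peak=6,
        frac_caqtl_peaks=0.5,
        seed=123,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    return caqtl.make_cell_design(small_dataset.adata.obs)


def make_poisson_glmm_data(
    seed,
    beta=0.5,
    n_donors=40,
    cells_per_donor=100,
    sigma_donor=0.25,
    sigma_library=0.15,
    maf=0.3,
    base_rate=5e-3,
    n_libraries=4,
):
    """One-peak Poisson GLMM dataset with known genotype effect."""
    r = np.random.default_rng(seed)
    donor = np.repeat(np.arange(n_donors), cells_per_donor)
    n = donor.size
    lib = r.integers(0, n_libraries, n)
    g_d = r.binomial(2, maf, n_donors).astype(float)
    a = r.normal(0, sigma_donor, n_donors)
    b = r.normal(0, sigma_library, n_libraries)
    depth = r.lognormal(5.5, 0.4, n)
    eta = np.log(depth * base_rate) + beta * g_d[donor] + a[donor] + b[lib]
    y = r.poisson(np.exp(eta))
    obs = pd.DataFrame(
        {
            "donor": donor,
            "library": lib,
            "TSSEnrichment": r.normal(8, 2, n),
            "MTratio": r.uniform(0.01, 0.1, n),
            "log10nFrags": np.log10(depth),
            "depth": depth,
        }
    )
    design = caqtl.make_cell_design(obs)
    return y, design, g_d[donor], g_d
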