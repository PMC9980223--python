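import numpy as np
import pandas as pd
import pytest

from triomr import SimConfig, simulate_trio_cohort
from triomr.wfmr import design_from_cohort


@pytest.fixture(scope="session")
def one_snp_cohort():
    """Moderate one-locus cohort under the dynastic model, phi = 0.5."""
    cfg = SimConfig(n_couples=4000, n_snps=1, assortment_phi=0.5, seed=11)
    return simulate_trio_cohort(cfg)


@pytest.fixture(scope="session")
def one_snp_design(one_snp_cohort):
    return design_from_cohort(one_snp_cohort)


@pytest.fixture()
def five_snp_table():
    """Hand-set summary statistics for arithmetic-oracle checks."""
    return pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(1, 6)],
        "beta_exposure": [0.10, 0.20, 0.15, 0.30, 0.25],
        "se_exposure": [0.01, 0.01, 0.01, 0.01, 0.01],
        "beta_outcome": [0.05, 0.11, 0.07, 0.16, 0.12],
        "se_outcome": [0.02, 0.03, 0.025, 0.04, 0.03],
        "effect_allele": ["G"] * 5,
    })
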