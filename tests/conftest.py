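import numpy as np
import pandas as pd
import pytest

from sexstrat.panel import GenotypePanel, X_CHROM
from sexstrat.synthetic_data import SimulationConfig, simulate_genotypes


def make_panel(dosages, sex, chrom=None):
    """Construct a panel from explicit dosages for hand-worked tests."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": np.asarray(chrom, dtype=int),
            "pos": np.arange(1, m + 1),
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return GenotypePanel(dosages=dosages, sex=np.asarray(sex), variants=variants)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixed_panel():
    """Small mixed-sex panel with autosomal and X variants, no missingness."""
    cfg = SimulationConfig(
        n_male=150, n_female=150, m_auto=300, m_x=60, maf_low=0.1, maf_high=0.5, seed=42
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def hwe_panel():
    """Autosome-only panel under HWE used for GRM distribution checks."""
    cfg = SimulationConfig(
        n_male=150, n_female=150, m_auto=1000, maf_low=0.05, maf_high=0.5, seed=7
    )
    return simulate_genotypes(cfg)
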