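import numpy as np
import pandas as pd
import pytest

from cvsem.datasets import CATEGORY_ORDER, GenotypeDataset
from cvsem.simulate import SimulationConfig, simulate_genotypes

STUDY_LOADINGS = np.array([0.842, 0.657, 0.787, 0.823])


def make_category_data(
    rng: np.random.Generator,
    n: int,
    loadings: np.ndarray = STUDY_LOADINGS,
    latent: np.ndarray | None = None,
) -> pd.DataFrame:
    """Continuous category scores from the one-factor model (unit latent)."""
    if latent is None:
        latent = rng.standard_normal(n)
    y = latent[:, None] * loadings + rng.standard_normal((n, 4)) * np.sqrt(
        1.0 - loadings**2
    )
    return pd.DataFrame(y, columns=CATEGORY_ORDER)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeDataset:
    cfg = SimulationConfig(
        n_samples=500, n_variants=300, ld_block_size=10, ld_rho=0.8, seed=5
    )
    return simulate_genotypes(cfg)


@pytest.fixture
def toy_genotypes() -> GenotypeDataset:
    dosages = np.array(
        [
            [0, 1, 2],
            [1, 0, np.nan],
        ]
    ).T  # 3 samples x 2 variants
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1"],
            "pos": [100, 200],
            "id": ["v1", "v2"],
            "ref": ["A", "C"],
            "alt": ["G", "T"],
        }
    )
    return GenotypeDataset(dosages, variants, ["s1", "s2", "s3"])
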