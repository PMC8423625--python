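import math

import numpy as np
import pandas as pd
import pytest

import eqtlkit as ek


def beta_for_variance_explained(frac: float, maf: float) -> float:
    """Effect size for which beta*g explains `frac` of trait variance (unit noise)."""
    return math.sqrt(frac / (1 - frac) / (2 * maf * (1 - maf)))


@pytest.fixture(scope="session")
def small_genotypes() -> pd.DataFrame:
    """500 samples x 50 variants, moderate LD, MAF 0.3."""
    return ek.simulate_genotypes(500, 50, 0.3, 0.8, seed=11)


@pytest.fixture(scope="session")
def ld_region_genotypes() -> pd.DataFrame:
    """1000 samples x 200 variants with strong local LD (rho=0.9)."""
    return ek.simulate_genotypes(1000, 200, 0.3, 0.9, seed=12)


def random_sumstats(rng: np.random.Generator, n_variants: int,
                    positions: np.ndarray | None = None) -> pd.DataFrame:
    """Random per-variant summary stats with moderate z so Bayes factors stay finite."""
    if positions is None:
        positions = np.sort(rng.choice(10**6, n_variants, replace=False)) + 1
    return pd.DataFrame(
        {
            "variant": [f"1_{p}_A_G" for p in positions],
            "chromosome": "1",
            "position": positions,
            "ref": "A",
            "alt": "G",
            "beta": rng.normal(0, 0.3, n_variants),
            "se": rng.uniform(0.08, 0.3, n_variants),
            "maf": rng.uniform(0.05, 0.39, n_variants),
            "n": 500,
        }
    )
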