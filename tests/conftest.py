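import numpy as np
import pandas as pd
import pytest

from pantemap import GenotypeMatrix, simulate_genotypes


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    """6 variants x 8 accessions with known MAF/missing/het structure."""
    acc = [f"a{i}" for i in range(8)]
    d = pd.DataFrame(
        [
            [2, 2, 2, 2, 2, 2, 2, 2],        # fixed present
            [0, 0, 0, 0, 0, 0, 0, 0],        # fixed absent
            [2, 2, 2, 2, 0, 0, 0, 0],        # MAF 0.5
            [2, 0, 0, 0, 0, 0, 0, 0],        # MAF 0.125
            [1, 1, 1, 1, 2, 2, 0, 0],        # het 0.5
            [2, np.nan, np.nan, np.nan, np.nan, 0, 2, 2],  # missing 0.5
        ],
        index=[f"v{i}" for i in range(6)], columns=acc, dtype=float)
    return GenotypeMatrix(d)


@pytest.fixture
def sim_gm():
    gm, truth = simulate_genotypes(
        n_accessions=200, n_tes=100, fixed_fraction=0.5,
        missing_rate=0.05, seed=11)
    return gm, truth
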