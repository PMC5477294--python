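import numpy as np
import pandas as pd
import pytest

from heteropath import genotype_core, simdata

VARS = list(simdata.VARIABLES)

#: Printed pairwise correlations for the two introgression libraries
#: (order: PHT, BR, GA, heterozygosity).
PIFB47_CORR = pd.DataFrame(
    [
        [1.00, 0.46, 0.59, 0.72],
        [0.46, 1.00, 0.52, 0.34],
        [0.59, 0.52, 1.00, 0.53],
        [0.72, 0.34, 0.53, 1.00],
    ],
    index=["PHT", "BR", "GA", "heterozygosity"],
    columns=["PHT", "BR", "GA", "heterozygosity"],
)
PIFZ51_CORR = pd.DataFrame(
    [
        [1.00, 0.51, 0.58, 0.70],
        [0.51, 1.00, 0.54, 0.32],
        [0.58, 0.54, 1.00, 0.41],
        [0.70, 0.32, 0.41, 1.00],
    ],
    index=["PHT", "BR", "GA", "heterozygosity"],
    columns=["PHT", "BR", "GA", "heterozygosity"],
)


@pytest.fixture(scope="session")
def small_map():
    return simdata.simulate_genome_map(
        n_chrom=5, chrom_length_bp=100_000_000, n_markers=200, seed=42
    )


@pytest.fixture(scope="session")
def default_params():
    return simdata.default_structural_params()


@pytest.fixture
def tiny_matrix():
    """Hand-written 4-entry x 5-marker matrix with one missing call."""
    calls = pd.DataFrame(
        [
            ["A", "H", "A", "A", "H"],
            ["A", "H", "A", "A", "H"],
            ["A", "A", "N", "A", "A"],
            ["H", "A", "B", "A", "A"],
        ],
        index=["e1", "e2", "e3", "e4"],
        columns=[f"m{i}" for i in range(1, 6)],
    )
    markers = pd.DataFrame(
        {"chrom": [1, 1, 1, 2, 2], "bp": [100, 200, 300, 100, 250]},
        index=calls.columns,
    )
    return genotype_core.MarkerMatrix(calls=calls, markers=markers)


def mvn_sample(corr: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Multivariate normal draws with the given correlation matrix."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr.to_numpy())
    z = rng.standard_normal((n, corr.shape[0]))
    return pd.DataFrame(z @ L.T, columns=corr.columns)
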