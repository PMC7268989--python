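import numpy as np
import pytest

from wings import GeneScoreMatrix, NEGLOG10, PVALUE, SimulationConfig, generate_matrix


def make_scores(values, phen=None, genes=None, scale=NEGLOG10) -> GeneScoreMatrix:
    """Build a score matrix from a raw array with auto-generated labels."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    phen = phen or [f"P{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(g)]
    return GeneScoreMatrix(phen, genes, values, scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_sim_config():
    """Reduced-scale simulation: fast, but same structure as the full protocol."""
    return SimulationConfig(
        n_phenotypes=20,
        n_genes=400,
        n_significant_per_phenotype=20,
        shared_fraction=0.75,
        cluster_size_range=(2, 4),
    )


@pytest.fixture
def small_instance(small_sim_config):
    return generate_matrix(small_sim_config, 123)
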