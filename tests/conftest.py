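import numpy as np
import pytest

from tscevo import Gene, Genome, SimulationParams, random_genome


@pytest.fixture
def params() -> SimulationParams:
    """Default model parameters (E. coli-like chromosome, two environments)."""
    return SimulationParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def genome60(params, rng) -> Genome:
    """A random 60-gene genome at the default genome parameters."""
    return random_genome(
        params.n_genes_per_type,
        params.gene_length,
        params.intergene,
        params.sigma_basal,
        rng,
    )


def make_pair(left_orient: str, right_orient: str, spacing: int = 125,
              gene_length: int = 1000, L: int = 67_500, sigma_basal: float = -0.066,
              types=("A", "B")) -> Genome:
    """Two adjacent genes on a large circle, in the given orientations."""
    genes = [
        Gene(0, types[0], 0, gene_length, left_orient),
        Gene(1, types[1], gene_length + spacing, gene_length, right_orient),
    ]
    return Genome(genes, L, sigma_basal)


def isolated_oracle(params: SimulationParams, delta: float) -> float:
    """Independent closed-form chain for a neighbor-less gene: background
    supercoiling -> opening energy sigmoid -> exponential expression law."""
    sigma = params.sigma_basal + delta
    U = 1.0 / (1.0 + np.exp((sigma - params.sigma_half) / params.epsilon))
    return float(np.exp(params.m * (U - 1.0)))
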