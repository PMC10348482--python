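import numpy as np
import pytest

from abguilds import BinaryMatrix, generate_base_matrix


def random_binary_matrix(G: int, F: int, density: float, seed: int) -> BinaryMatrix:
    rng = np.random.default_rng(seed)
    values = (rng.random((G, F)) < density).astype(np.uint8)
    return BinaryMatrix([f"g{i}" for i in range(G)],
                        [f"f{j}" for j in range(F)], values)


@pytest.fixture
def small_matrix() -> BinaryMatrix:
    return random_binary_matrix(50, 20, 0.3, seed=42)


@pytest.fixture
def two_block_matrix() -> BinaryMatrix:
    """40 genomes x 10 functions: genomes 0-19 carry functions 0-4,
    genomes 20-39 carry functions 5-9."""
    values = np.zeros((40, 10), dtype=np.uint8)
    values[:20, :5] = 1
    values[20:, 5:] = 1
    return BinaryMatrix([f"g{i}" for i in range(40)],
                        [f"f{j}" for j in range(10)], values)


@pytest.fixture
def four_block_matrix() -> BinaryMatrix:
    """40 genomes x 12 functions in four disjoint 10-genome / 3-function
    blocks; with K=4 each aspect captures one block and has
    representatives (threshold 2/4 = 0.5 < Gamma of a block genome)."""
    values = np.zeros((40, 12), dtype=np.uint8)
    for b in range(4):
        values[10 * b:10 * (b + 1), 3 * b:3 * (b + 1)] = 1
    return BinaryMatrix([f"g{i}" for i in range(40)],
                        [f"f{j:02d}" for j in range(12)], values)


@pytest.fixture(scope="session")
def surrogate_base() -> BinaryMatrix:
    """Small surrogate background with genuine aspect structure."""
    return generate_base_matrix(300, 60, n_latent=4, density=0.3, seed=7)
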