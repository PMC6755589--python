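import numpy as np
import pytest

from sbdfp import BitMatrix, default_spec, sample_bitmatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """200 x 166 random binary matrix with moderate bit density."""
    rows = (rng.random((200, 166)) < 0.3).astype(np.uint8)
    return BitMatrix(
        ids=[f"m{i}" for i in range(200)], rows=rows, scheme_tag="synthetic"
    )


@pytest.fixture
def small_matrix():
    return BitMatrix(
        ids=["a", "b"],
        rows=np.array([[1, 1, 0], [0, 1, 1]]),
        scheme_tag="toy",
    )


@pytest.fixture
def enriched_spec():
    """Generator spec with 20 planted enriched bits (0.2 -> 0.6)."""
    return default_spec(n_bits=166, n_enriched=20, seed=7)


def brute_force_tanimoto(a, b):
    """Reference Tanimoto via explicit set logic (independent oracle)."""
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return inter / union if union else 0.0
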