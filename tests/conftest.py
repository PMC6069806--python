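import numpy as np
import pytest

from semrel import EmbeddingMatrix, PlantedSpec


@pytest.fixture
def toy_embedding() -> EmbeddingMatrix:
    """Three 2-D vectors with hand-computable cosines."""
    return EmbeddingMatrix(
        ["x", "y", "z"],
        np.array([[1.0, 0.0], [0.0, 1.0], [0.7071, 0.7071]]),
    )


@pytest.fixture
def random_embedding() -> EmbeddingMatrix:
    rng = np.random.default_rng(42)
    terms = [f"w{i}" for i in range(50)]
    return EmbeddingMatrix(terms, rng.standard_normal((50, 10)))


@pytest.fixture
def default_spec() -> PlantedSpec:
    return PlantedSpec(seed=7)


def brute_force_neighbors(E: EmbeddingMatrix, query, k, exclude=frozenset()):
    """Independent exhaustive-scan oracle: cosine to every row, full sort."""
    q = np.asarray(query, dtype=float)
    scored = []
    for i, term in enumerate(E.terms):
        if term in exclude:
            continue
        row = E.vectors[i]
        nr = np.linalg.norm(row)
        if nr == 0.0:
            continue
        cos = float(q @ row / (np.linalg.norm(q) * nr))
        scored.append((term, cos, i))
    scored.sort(key=lambda x: (-x[1], x[2]))
    return [(t, c) for t, c, _ in scored[:k]]
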