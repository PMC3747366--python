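import numpy as np
import pandas as pd
import pytest

from bcrpqsar import (
    DescriptorMatrix,
    PolyspecificGeneratorConfig,
    ScoredRanking,
    generate_polyspecific,
)

# A tiny hand-written SMILES set covering two obvious scaffold families
# (substituted benzenes vs linear alkanes) for molecule-based code paths.
BENZENES = [
    ("o-xylene", "Cc1ccccc1C"),
    ("p-xylene", "Cc1ccc(C)cc1"),
    ("m-xylene", "Cc1cccc(C)c1"),
    ("pseudocumene", "Cc1ccc(C)c(C)c1"),
    ("mesitylene", "Cc1cc(C)cc(C)c1"),
    ("2-ethyltoluene", "CCc1ccccc1C"),
]
ALKANES = [
    ("hexane", "CCCCCC"),
    ("heptane", "CCCCCCC"),
    ("octane", "CCCCCCCC"),
    ("nonane", "CCCCCCCCC"),
    ("decane", "CCCCCCCCCC"),
    ("undecane", "CCCCCCCCCCC"),
]


@pytest.fixture(scope="session")
def smiles_families():
    return BENZENES, ALKANES


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-rule synthetic dataset shared across tests."""
    return generate_polyspecific(
        PolyspecificGeneratorConfig(n_compounds=120, n_blocks=6,
                                    descriptors_per_block=20, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ranking(rng, n, n_hits, ties=False):
    scores = rng.standard_normal(n)
    if ties:
        scores = np.round(scores, 1)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[rng.choice(n, size=n_hits, replace=False)] = True
    return ScoredRanking(ids=[f"c{i}" for i in range(n)], scores=scores, is_hit=is_hit)


@pytest.fixture
def make_ranking(rng):
    def _make(n=50, n_hits=20, ties=False):
        return random_ranking(rng, n, n_hits, ties)
    return _make


@pytest.fixture
def toy_matrix():
    """4 compounds x 4 descriptors in two blocks."""
    values = pd.DataFrame(
        {
            "a1": [1.0, 2.0, 3.0, 4.0],
            "a2": [7.0, 7.0, 7.0, 7.0],
            "b1": [0.1, 0.2, 0.1, 0.9],
            "b2": [5.0, 4.0, 3.0, 2.0],
        },
        index=["w", "x", "y", "z"],
    )
    return DescriptorMatrix(values, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
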