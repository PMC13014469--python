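import numpy as np
import pandas as pd
import pytest

from ccibae import (
    CCIM,
    ExpressionMatrix,
    LigandReceptorDB,
    PlantedCCIMSpec,
    generate_ccim,
    standardize_features,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_expr():
    """3 cells x 4 genes with two ligand-receptor pairs represented."""
    values = np.array(
        [
            [2.0, 0.0, 1.0, 0.5],
            [0.0, 3.0, 0.0, 1.0],
            [1.0, 1.0, 2.0, 0.0],
        ]
    )
    return ExpressionMatrix(
        values,
        cell_ids=["A", "B", "C"],
        gene_ids=["L1", "R1", "L2", "R2"],
        cell_types=["alpha", "beta", "alpha"],
    )


@pytest.fixture
def toy_db():
    return LigandReceptorDB([("L1", "R1"), ("L2", "R2")])


def make_ccim(scores, standardized=False):
    n, p = scores.shape
    pair_meta = pd.DataFrame(
        {
            "sender_id": [f"s{i}" for i in range(n)],
            "receiver_id": [f"r{i}" for i in range(n)],
            "sender_type": ["t"] * n,
            "receiver_type": ["u"] * n,
        }
    )
    feature_meta = pd.DataFrame(
        {"ligand": [f"L{j}" for j in range(p)], "receptor": [f"R{j}" for j in range(p)]}
    )
    return CCIM(np.asarray(scores, dtype=float), pair_meta, feature_meta, standardized)


@pytest.fixture
def random_ccim(rng):
    return make_ccim(rng.normal(size=(20, 10)))


@pytest.fixture(scope="session")
def small_planted():
    """2 planted clusters x 60 pairs, 12 features, standardized; with truth."""
    spec = PlantedCCIMSpec(
        k_clusters=2, n_pairs_per_cluster=60, n_features=12, signature_size=3, seed=3
    )
    ccim, truth = generate_ccim(spec)
    return standardize_features(ccim), truth
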