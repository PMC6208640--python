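import numpy as np
import pytest

from traitforest.forest import train_forest
from traitforest.traitspace import (CompositeDataset, InteractionTable,
                                    LabelRule, TraitMatrix, assemble_dataset)


def random_binary_dataset(n_samples, n_features, rng, rule="linear"):
    """Synthetic (X, y) with a learnable structure.

    ``linear``: label = x0 OR (x1 AND x2) — greedy Gini splits can always
    purify this, so full-mTry trees reach 100% in-bag accuracy.
    ``noise``: labels independent of X.
    """
    X = rng.integers(0, 2, size=(n_samples, n_features)).astype(np.int8)
    if rule == "linear":
        y = (X[:, 0] | (X[:, 1] & X[:, 2])).astype(np.int8)
    else:
        y = rng.integers(0, 2, size=n_samples).astype(np.int8)
    return X, y


@pytest.fixture(scope="session")
def small_traits():
    rng = np.random.default_rng(42)
    n, p = 10, 8
    values = rng.integers(0, 2, size=(n, p)).astype(np.int8)
    values[:, 0] = 1  # keep every vector nonzero for Jaccard
    return TraitMatrix(tuple(f"org{i}" for i in range(n)),
                       tuple(f"feat{j}" for j in range(p)), values)


@pytest.fixture(scope="session")
def small_table(small_traits):
    rng = np.random.default_rng(7)
    n = len(small_traits.organism_ids)
    resp = rng.normal(0, 1, size=(n, n))
    np.fill_diagonal(resp, 1.0)  # B_ii
    return InteractionTable(small_traits.organism_ids, resp, "relative_yield")


@pytest.fixture(scope="session")
def small_dataset(small_traits, small_table):
    return assemble_dataset(small_traits, small_table, LabelRule(mode="sign"))


@pytest.fixture(scope="session")
def small_forest(small_dataset):
    return train_forest(small_dataset, n_trees=60, seed=11)


@pytest.fixture(scope="session")
def flagship_study():
    """The standard simulated competition community used across tests.

    Session-scoped because the full campaign plus a 500-tree forest takes
    a few seconds; everything downstream treats it as read-only.
    """
    from traitforest.pipeline import mechanism_recovery_study
    return mechanism_recovery_study(1)
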