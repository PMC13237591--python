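import numpy as np
import pandas as pd
import pytest

import ptrubric as pt


@pytest.fixture(scope="session")
def vocab():
    return pt.load_default_vocabulary()


@pytest.fixture(scope="session")
def rubric_table():
    return pt.load_default_rubric_table()


@pytest.fixture(scope="session")
def unified_hierarchy():
    return pt.load_default_hierarchy()


@pytest.fixture(scope="session")
def fig2_sample():
    """One generated realisation of the canned 72-PT block scenario.

    Session-scoped because the n=5000 draw and its Spearman matrix are used
    by several structural tests.
    """
    S, truth = pt.synthetic_reference_matrix(seed=7, n_articles=5000)
    return S, truth


def make_similarity(values, names=None):
    """Build a SimilarityMatrix from a raw square array."""
    arr = np.asarray(values, dtype=float)
    names = names or [f"PT{i + 1}" for i in range(arr.shape[0])]
    return pt.SimilarityMatrix(pd.DataFrame(arr, index=names, columns=names))


def make_probability(values, names=None, ids=None):
    arr = np.asarray(values, dtype=float)
    names = names or [f"PT{j + 1}" for j in range(arr.shape[1])]
    ids = ids or [f"a{i + 1}" for i in range(arr.shape[0])]
    return pt.ProbabilityMatrix(pd.DataFrame(arr, index=ids, columns=names))
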