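import numpy as np
import pytest

from polystest import ComparisonSpec, Design, ExpressionMatrix


def make_matrix(values, conditions=None, feature_ids=None, meta=None):
    """Build a small two-condition matrix; columns split evenly A then B."""
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    if conditions is None:
        r = s // 2
        labels = [f"A_{i}" for i in range(1, r + 1)] + [f"B_{i}" for i in range(1, s - r + 1)]
        conditions = {"A": labels[:r], "B": labels[r:]}
    else:
        labels = [s for ss in conditions.values() for s in ss]
    ids = feature_ids or [f"f{i}" for i in range(1, n + 1)]
    return ExpressionMatrix(values, ids, labels, Design.from_conditions(conditions), meta)


@pytest.fixture
def toy_matrix():
    """6 features x (3+3) samples with a strongly separated feature and missing cells."""
    nan = np.nan
    values = [
        [1.0, 1.2, 0.9, 5.0, 5.2, 4.9],   # strong up in B
        [2.0, 2.1, 1.9, 2.0, 2.2, 1.8],   # null
        [nan, nan, nan, 3.0, 3.2, 2.9],   # all missing in A
        [0.5, nan, 0.4, 0.6, 0.5, nan],   # scattered missing
        [4.0, 4.1, 3.9, 4.0, nan, 4.2],   # high abundance null
        [1.5, 1.4, nan, nan, 1.6, 1.3],   # sparse null
    ]
    return make_matrix(values)


@pytest.fixture
def ab_comparison():
    return ComparisonSpec("A", "B")
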