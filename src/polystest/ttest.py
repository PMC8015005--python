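"""Plain t-test (Welch unpaired / one-sample paired) as the reference method.

Excluded from the unified PolySTest FDR: the plain t-test is known to
underestimate the false discovery rate at low replicate numbers.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .data import ComparisonSpec, ExpressionMatrix

__all__ = ["t_test"]

_TINY_P = np.nextafter(0.0, 1.0)


def _group_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.sum(~np.isnan(x), axis=1)
    mean = np.where(n > 0, np.nansum(x, axis=1) / np.maximum(n, 1), np.nan)
    dev = x - mean[:, None]
    ss = np.nansum(dev * dev, axis=1)
    var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


def t_test(m: ExpressionMatrix, c: ComparisonSpec) -> np.ndarray:
    """Per-feature two-sided p-values.

    Unpaired comparisons use the Welch (unequal-variance) statistic over the
    observed values; paired comparisons a one-sample test on complete-pair
    differences.  Features with fewer than two observations in either group
    (or fewer than two complete pairs) are discarded with ``p = 1``.
    Zero-variance features with a non-zero difference get the smallest
    positive representable p-value.
    """
    c.validate(m.design)
    a = m.condition_values(c.condition_a)
    b = m.condition_values(c.condition_b)
    n_features = m.n_features
    p = np.ones(n_features)

    if c.paired:
        d = b - a
        n, mean, var = _group_stats(d)
        usable = n >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(var / n)
            t = mean / se
        df = n - 1.0
        zero_var = usable & np.isclose(var, 0.0)
        degenerate = zero_var & (mean != 0)
        normal = usable & ~zero_var
        p[normal] = 2.0 * stats.t.sf(np.abs(t[normal]), df[normal])
        p[zero_var & (mean == 0)] = 1.0
    else:
        na, ma, va = _group_stats(a)
        nb, mb, vb = _group_stats(b)
        usable = (na >= 2) & (nb >= 2)
        diff = mb - ma
        with np.errstate(invalid="ignore", divide="ignore"):
            se2 = va / na + vb / nb
            t = diff / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        zero_var = usable & np.isclose(se2, 0.0)
        degenerate = zero_var & (diff != 0)
        normal = usable & ~zero_var
        p[normal] = 2.0 * stats.t.sf(np.abs(t[normal]), df[normal])
        p[zero_var & (diff == 0)] = 1.0

    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} features have zero variance but a non-zero "
            "difference; reporting the smallest representable positive p-value",
            stacklevel=2,
        )
        p[degenerate] = _TINY_P
    return np.minimum(p, 1.0)
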