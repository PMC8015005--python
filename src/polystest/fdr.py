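"""Multiple-testing corrections and the unified PolySTest FDR.

Per-test correction routing: Benjamini-Hochberg for the tests that discard
features by assigning ``p = 1`` (Miss test, rank products, permutation test)
and Storey q-values for the t and moderated tests, which produce a full
p-value spectrum suitable for background (pi0) estimation.

The unified PolySTest FDR applies, per feature, the Hommel adjustment (valid
under positive dependence) to the four per-test FDRs from the moderated
test, Miss test, rank products and permutation test, and reports the
smallest adjusted value.  The plain t-test never participates.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from scipy.interpolate import make_smoothing_spline
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "estimate_pi0",
    "qvalue_adjust",
    "hommel_adjust",
    "hommel_adjust_rows",
    "polystest_fdr",
    "assign_corrections",
    "BH_TESTS",
    "QVALUE_TESTS",
    "UNIFIED_TESTS",
]

BH_TESTS = frozenset({"miss", "rank_products", "permutation"})
QVALUE_TESTS = frozenset({"t", "limma"})
UNIFIED_TESTS = ("limma", "miss", "rank_products", "permutation")

_MIN_N_FOR_PI0 = 100
_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def _check_unit(p: np.ndarray, what: str = "p-values") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValueError(f"{what} must lie in [0, 1]")
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = _check_unit(p)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _bh_uncapped(p: np.ndarray) -> np.ndarray:
    """Step-up values before the cap at 1 (needed for Storey scaling)."""
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = adj
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    ``pi0(lambda) = #{p > lambda} / (n (1 - lambda))`` is smoothed with a
    cubic smoothing spline and read off at the largest lambda.  Returns NaN
    when the estimate is degenerate (caller falls back to pi0 = 1).
    """
    p = _check_unit(p)
    n = p.size
    if n < _MIN_N_FOR_PI0:
        return float("nan")
    pi0_lam = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in lambdas])
    try:
        spline = make_smoothing_spline(lambdas, pi0_lam)
        pi0 = float(spline(lambdas[-1]))
    except Exception:  # degenerate smoother input
        return float("nan")
    if not np.isfinite(pi0) or pi0 <= 0 or pi0 > 1:
        return float("nan")
    return pi0


def qvalue_adjust(p: np.ndarray) -> np.ndarray:
    """Storey q-values; falls back to BH (pi0 = 1) when pi0 estimation fails."""
    p = _check_unit(p)
    if p.size == 0:
        return p.copy()
    pi0 = estimate_pi0(p)
    if np.isnan(pi0):
        logger.info("qvalue_adjust: pi0 estimation unavailable (n=%d); using pi0=1 (BH)", p.size)
        pi0 = 1.0
    return np.minimum(pi0 * _bh_uncapped(p), 1.0)


def hommel_adjust(p: np.ndarray) -> np.ndarray:
    """Hommel adjusted p-values for one small family (closed testing with Simes)."""
    p = _check_unit(p)
    return hommel_adjust_rows(p[None, :])[0]


def hommel_adjust_rows(P: np.ndarray) -> np.ndarray:
    """Row-wise Hommel adjustment for many small families at once.

    Vectorized port of the standard stepwise algorithm; equivalent to the
    closed-testing procedure with Simes local tests.
    """
    P = _check_unit(np.atleast_2d(P))
    n_rows, n = P.shape
    if n == 1:
        return P.copy()
    order = np.argsort(P, axis=1, kind="mergesort")
    ps = np.take_along_axis(P, order, axis=1)
    i = np.arange(1, n + 1)
    q = np.tile((n * ps / i).min(axis=1)[:, None], (1, n))
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        i1 = np.arange(n - m + 1)
        i2 = np.arange(n - m + 1, n)
        q1 = (m * ps[:, i2] / np.arange(2, m + 1)).min(axis=1)
        q[:, i1] = np.minimum(m * ps[:, i1], q1[:, None])
        q[:, i2] = q[:, n - m][:, None]
        pa = np.maximum(pa, q)
    adj = np.maximum(pa, ps)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=1)
    return out


def polystest_fdr(
    fdr_limma: np.ndarray,
    fdr_miss: np.ndarray,
    fdr_rp: np.ndarray,
    fdr_perm: np.ndarray,
) -> np.ndarray:
    """Unified per-feature FDR: minimum of the Hommel-adjusted four FDRs."""
    vs = [np.asarray(v, dtype=float) for v in (fdr_limma, fdr_miss, fdr_rp, fdr_perm)]
    lengths = {v.shape for v in vs}
    if len(lengths) != 1 or vs[0].ndim != 1:
        raise ValueError("the four FDR vectors must be 1-D and of equal length")
    stacked = np.column_stack(vs)
    return hommel_adjust_rows(stacked).min(axis=1)


def assign_corrections(raw_p: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Route each test's raw p-values to its correction and add the unified FDR.

    Returns ``{test: fdr, ...}`` plus key ``"polystest"`` when all four
    unified tests are present.
    """
    fdrs: dict[str, np.ndarray] = {}
    for test, p in raw_p.items():
        if test in BH_TESTS:
            fdrs[test] = bh_adjust(p)
        elif test in QVALUE_TESTS:
            fdrs[test] = qvalue_adjust(p)
        else:
            raise KeyError(f"unknown test {test!r}")
    if all(t in fdrs for t in UNIFIED_TESTS):
        fdrs["polystest"] = polystest_fdr(*(fdrs[t] for t in UNIFIED_TESTS))
    else:
        logger.warning(
            "unified PolySTest FDR omitted: requires all of %s", ", ".join(UNIFIED_TESTS)
        )
    return fdrs
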