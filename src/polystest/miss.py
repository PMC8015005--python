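"""The Miss test: differential abundance evidence from missing-value counts.

The test treats missingness itself as data.  Under the null hypothesis values
are missing at random with probability ``p_NA`` (the fraction of missing
cells in the whole matrix), so the number of missing values among the ``r``
replicates of one condition is Binomial(r, p_NA).  The probability of
observing a difference of ``k`` missing values between two conditions follows
by convolving two such binomials and folding at zero:

    P_0 = sum_j b_j^2,    P_k = 2 * sum_j b_{j+k} b_j   (k >= 1),

with ``b_i = C(r, i) p_NA^i (1 - p_NA)^(r - i)``.

To couple missingness to abundance, the test scans detection-limit
scenarios: the distribution of all observed values is cut into ``n_quantiles``
quantiles, and for each quantile threshold all values below it are censored
to missing, which raises ``p_NA`` and changes each feature's missing-count
difference ``k``.  The per-feature p-value is the smallest ``P_k`` over all
scenarios, multiplied by ``r + 1`` (the number of attainable ``k`` values)
and capped at one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import comb

from .data import ComparisonSpec, ExpressionMatrix

__all__ = [
    "DiffProbabilityTable",
    "MissScenario",
    "binom_missing",
    "diff_probabilities",
    "scenario_scan",
    "miss_test",
]


def _check_p(p_na: float) -> float:
    p_na = float(p_na)
    if not (0.0 <= p_na <= 1.0):
        raise ValueError(f"p_na must lie in [0, 1], got {p_na}")
    return p_na


def binom_missing(r: int, p_na: float) -> np.ndarray:
    """Probabilities ``b_0..b_r`` of ``i`` missing values among ``r`` replicates."""
    r = int(r)
    if r < 1:
        raise ValueError("r must be >= 1")
    p_na = _check_p(p_na)
    i = np.arange(r + 1)
    # explicit binomial pmf: exact for dyadic p_na, no special-function rounding
    return comb(r, i) * p_na**i * (1.0 - p_na) ** (r - i)


@dataclass(frozen=True)
class DiffProbabilityTable:
    """Null distribution of the absolute missing-count difference ``k``."""

    r_a: int
    r_b: int
    p_na: float
    P: np.ndarray  # index k = 0..max(r_a, r_b)

    @property
    def multiplier(self) -> int:
        """The scan correction factor: number of attainable ``k`` values."""
        return max(self.r_a, self.r_b) + 1


def diff_probabilities(r: int, p_na: float, r_b: int | None = None) -> DiffProbabilityTable:
    """Distribution of ``k = |#missing_a - #missing_b|`` under random missingness.

    With equal replicate counts this is the folded self-convolution of the
    binomial: ``P_0 = sum b_j**2`` and ``P_k = 2 sum_j b_{j+k} b_j`` for
    ``k >= 1`` (the difference-zero case is self-symmetric and not doubled).
    Unequal counts generalize via ``|X - Y|`` with independent
    ``X ~ Bin(r_a, p_NA)``, ``Y ~ Bin(r_b, p_NA)``.
    """
    r_a = int(r)
    r_b = r_a if r_b is None else int(r_b)
    p_na = _check_p(p_na)
    b_a = binom_missing(r_a, p_na)
    b_b = binom_missing(r_b, p_na)
    k_max = max(r_a, r_b)
    P = np.zeros(k_max + 1)
    P[0] = float(np.dot(b_a[: min(r_a, r_b) + 1], b_b[: min(r_a, r_b) + 1]))
    for k in range(1, k_max + 1):
        # P(X - Y = k) + P(Y - X = k)
        up = sum(b_a[j + k] * b_b[j] for j in range(0, min(r_a - k, r_b) + 1)) if k <= r_a else 0.0
        dn = sum(b_b[j + k] * b_a[j] for j in range(0, min(r_b - k, r_a) + 1)) if k <= r_b else 0.0
        P[k] = float(up + dn)
    return DiffProbabilityTable(r_a, r_b, p_na, P)


@dataclass
class MissScenario:
    """One detection-limit scenario of the abundance-quantile scan."""

    threshold: float
    p_na: float
    diff_counts: dict[str, np.ndarray]  # comparison key -> per-feature k


def scenario_scan(
    m: ExpressionMatrix,
    comparisons: Sequence[ComparisonSpec],
    n_quantiles: int = 100,
) -> list[MissScenario]:
    """Censoring scan over abundance-quantile detection limits.

    Thresholds are the ``q / n_quantiles`` empirical quantiles
    (``q = 0..n_quantiles - 1``) of all observed values; ``q = 0`` reproduces
    the uncensored data and the degenerate all-missing scenario is excluded.
    A cell is censored when its value is strictly below the threshold.
    ``p_na`` is the missing fraction of the entire matrix after censoring.
    """
    values = m.values
    observed = values[np.isfinite(values)]
    if observed.size == 0:
        raise ValueError("matrix has no observed values")
    n_quantiles = int(n_quantiles)
    if n_quantiles < 1:
        raise ValueError("n_quantiles must be >= 1")
    thresholds = np.quantile(observed, np.arange(n_quantiles) / n_quantiles)
    total = values.size
    finite = np.isfinite(values)
    cols = {c.key: (m.column_indices(c.condition_a), m.column_indices(c.condition_b)) for c in comparisons}
    scenarios: list[MissScenario] = []
    for t in thresholds:
        missing = ~finite | (finite & (values < t))
        p_na = float(missing.sum()) / total
        diff_counts = {}
        for key, (ia, ib) in cols.items():
            ka = missing[:, ia].sum(axis=1)
            kb = missing[:, ib].sum(axis=1)
            diff_counts[key] = np.abs(ka - kb).astype(int)
        scenarios.append(MissScenario(float(t), p_na, diff_counts))
    return scenarios


def miss_test(
    m: ExpressionMatrix,
    c: ComparisonSpec,
    n_quantiles: int = 100,
) -> np.ndarray:
    """Per-feature Miss test p-values for one comparison.

    For every detection-limit scenario the feature's missing-count difference
    ``k`` is scored with the scenario's null table; the smallest probability
    over scenarios times ``max(r_a, r_b) + 1`` (capped at 1) is the p-value.
    Fully observed features still receive a valid p-value because the scan
    introduces abundance-driven missingness.
    """
    c.validate(m.design)
    r_a = m.design.n_replicates(c.condition_a)
    r_b = m.design.n_replicates(c.condition_b)
    scenarios = scenario_scan(m, [c], n_quantiles=n_quantiles)
    best = np.full(m.n_features, np.inf)
    multiplier = max(r_a, r_b) + 1
    for s in scenarios:
        table = diff_probabilities(r_a, s.p_na, r_b)
        best = np.minimum(best, table.P[s.diff_counts[c.key]])
    return np.minimum(best * multiplier, 1.0)
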