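"""Rank products: paired natively, unpaired via averaged random pairings.

For each replicate pair the per-feature log-ratio (b - a) is ranked twice:
ascending (rank 1 = most down-regulated) for the "down" list and descending
for the "up" list, ranks restricted to the features observed in that pair.
A feature's rank product is the product of its normalized ranks
(rank / n_observed) over the pairs where it is observed.  Under the null the
normalized ranks behave like independent Uniform(0, 1] variables, so
``-log rho`` is referred to a Gamma(k_eff, 1) tail for the one-sided
p-values; the two-sided p-value doubles the smaller side (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import spawn_rng
from .data import ComparisonSpec, ExpressionMatrix

__all__ = ["RankProductResult", "paired_rank_product", "unpaired_rank_product"]


@dataclass
class RankProductResult:
    """Per-feature rank products (normalized), effective pair counts and p-values."""

    rho_up: np.ndarray
    rho_down: np.ndarray
    k_eff: np.ndarray
    p_up: np.ndarray
    p_down: np.ndarray
    p: np.ndarray


def _gamma_tail_p(log_rho: np.ndarray, k: np.ndarray) -> np.ndarray:
    """P(product of k uniforms <= rho) = P(Gamma(k,1) >= -log rho); 1 when k=0."""
    p = np.ones(log_rho.shape)
    pos = k > 0
    p[pos] = stats.gamma.sf(-log_rho[pos], k[pos])
    return p


def _rank_product_from_ratios(ratios: np.ndarray) -> RankProductResult:
    """Core computation given the per-pair ratio matrix (features x pairs)."""
    n_features, n_pairs = ratios.shape
    log_up = np.zeros(n_features)
    log_down = np.zeros(n_features)
    k_eff = np.zeros(n_features, dtype=int)
    for j in range(n_pairs):
        col = ratios[:, j]
        obs = np.isfinite(col)
        n_obs = int(obs.sum())
        if n_obs == 0:
            continue
        asc = stats.rankdata(col[obs], method="average")
        desc = n_obs + 1.0 - asc
        log_down[obs] += np.log(asc / n_obs)
        log_up[obs] += np.log(desc / n_obs)
        k_eff[obs] += 1
    p_up = _gamma_tail_p(log_up, k_eff)
    p_down = _gamma_tail_p(log_down, k_eff)
    p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    p[k_eff == 0] = 1.0
    return RankProductResult(
        rho_up=np.exp(log_up),
        rho_down=np.exp(log_down),
        k_eff=k_eff,
        p_up=p_up,
        p_down=p_down,
        p=p,
    )


def paired_rank_product(m: ExpressionMatrix, c: ComparisonSpec) -> RankProductResult:
    """Rank-product test pairing replicates by index; requires equal counts."""
    c.validate(m.design)
    r_a = m.design.n_replicates(c.condition_a)
    r_b = m.design.n_replicates(c.condition_b)
    if r_a != r_b:
        raise ValueError(
            "paired rank product requires equal replicate counts; "
            "use unpaired_rank_product for unequal designs"
        )
    a = m.condition_values(c.condition_a)
    b = m.condition_values(c.condition_b)
    return _rank_product_from_ratios(b - a)


def unpaired_rank_product(
    m: ExpressionMatrix,
    c: ComparisonSpec,
    n_pairings: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Unpaired variant: mean two-sided p over random replicate pairings.

    Each iteration draws a uniformly random bijection between the two
    conditions' replicates (matching ``min(r_a, r_b)`` randomly chosen
    columns when counts differ) and runs the paired test on the induced
    ratios.  Returns the per-feature mean p-value.
    """
    c.validate(m.design)
    a = m.condition_values(c.condition_a)
    b = m.condition_values(c.condition_b)
    r_a, r_b = a.shape[1], b.shape[1]
    k = min(r_a, r_b)
    rng = spawn_rng(seed, f"rank_products:{c.key}")
    acc = np.zeros(m.n_features)
    for _ in range(int(n_pairings)):
        ia = rng.permutation(r_a)[:k]
        ib = rng.permutation(r_b)[:k]
        res = _rank_product_from_ratios(b[:, ib] - a[:, ia])
        acc += res.p
    return acc / n_pairings
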