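"""Permutation test with low-replicate augmentation.

The per-feature statistic rewards both effect size and evidence quantity:

    unpaired: u = |mean(b) - mean(a)| / sqrt(var(a) + var(b)) * n
    paired:   u = |mean(d) / std(d)| * n_pairs

with ``n`` the number of non-missing values used, so sparsely observed
features are penalized.  The test requires at least 7 replicates per
condition; below that, pseudo-replicate columns are appended whose cells are
drawn with replacement from the pool of all observed values of the compared
columns.  The null is built from per-feature randomizations (unpaired:
random re-partitions of the feature's pooled observed values; paired:
independent sign flips of pair differences), and

    p = (#{u_rand >= u_obs} + 1) / (n_rand + 1),

ties counting as exceedances.  Features with fewer than two observations in
either group before augmentation are discarded with ``p = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._util import spawn_rng
from .data import ComparisonSpec, Design, ExpressionMatrix

__all__ = ["PermStatistic", "perm_statistic", "augment_replicates", "permutation_p"]

_CHUNK = 256  # features per vectorized randomization block


@dataclass(frozen=True)
class PermStatistic:
    """Value of the permutation statistic and the evidence count behind it."""

    u: float
    n_obs: int


def perm_statistic(a_values: np.ndarray, b_values: np.ndarray, paired: bool) -> PermStatistic:
    """The statistic for one feature from its observed (or paired) values.

    A zero denominator yields ``u = 0`` when the numerator is zero and
    ``u = inf`` otherwise.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if paired:
        d = (b - a)[np.isfinite(b - a)]
        n = d.size
        num = abs(float(np.mean(d))) if n else 0.0
        den = float(np.std(d, ddof=1)) if n > 1 else 0.0
    else:
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        n = a.size + b.size
        num = abs(float(np.mean(b) - np.mean(a))) if a.size and b.size else 0.0
        va = float(np.var(a, ddof=1)) if a.size > 1 else 0.0
        vb = float(np.var(b, ddof=1)) if b.size > 1 else 0.0
        den = float(np.sqrt(va + vb))
    if den == 0.0:
        u = 0.0 if num == 0.0 else np.inf
    else:
        u = num / den * n
    return PermStatistic(u=float(u), n_obs=int(n))


def augment_replicates(
    m: ExpressionMatrix,
    c: ComparisonSpec,
    target: int = 7,
    seed: int = 0,
) -> ExpressionMatrix:
    """Append pseudo-replicate columns until both conditions reach ``target``.

    New cells are drawn uniformly with replacement from the pool of all
    observed values of the compared columns; original columns are unchanged.
    """
    c.validate(m.design)
    r_a = m.design.n_replicates(c.condition_a)
    r_b = m.design.n_replicates(c.condition_b)
    if r_a >= target and r_b >= target:
        return m
    pool = np.concatenate(
        [m.condition_values(c.condition_a).ravel(), m.condition_values(c.condition_b).ravel()]
    )
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("cannot augment: no observed values in the compared columns")
    rng = spawn_rng(seed, f"augment:{c.key}")
    new_cols = []
    new_labels = []
    assignment = {s: (m.design.condition_of(s), m.design.replicate_of(s)) for s in m.sample_labels}
    for cond, r in ((c.condition_a, r_a), (c.condition_b, r_b)):
        for i in range(r + 1, target + 1):
            label = f"{cond}__aug{i}"
            new_cols.append(rng.choice(pool, size=m.n_features))
            new_labels.append(label)
            assignment[label] = (cond, i)
    values = np.column_stack([m.values] + new_cols)
    return ExpressionMatrix(
        values,
        list(m.feature_ids),
        list(m.sample_labels) + new_labels,
        Design(assignment),
        m.feature_meta,
    )


def _u_unpaired(a: np.ndarray, b: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    """Vectorized unpaired statistic over the trailing axis (no missing values)."""
    num = np.abs(b.mean(axis=-1) - a.mean(axis=-1))
    den = np.sqrt(a.var(axis=-1, ddof=1) + b.var(axis=-1, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        u = num / den * n_total
    u = np.where(den == 0.0, np.where(num == 0.0, 0.0, np.inf), u)
    return u


def _u_paired(d: np.ndarray, n_pairs: np.ndarray) -> np.ndarray:
    num = np.abs(d.mean(axis=-1))
    den = d.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = num / den * n_pairs
    u = np.where(den == 0.0, np.where(num == 0.0, 0.0, np.inf), u)
    return u


def permutation_p(
    m: ExpressionMatrix,
    c: ComparisonSpec,
    n_rand: int = 1000,
    seed: int = 0,
    target_replicates: int = 7,
) -> np.ndarray:
    """Per-feature permutation p-values for one comparison."""
    c.validate(m.design)
    n_rand = int(n_rand)
    a_pre = m.condition_values(c.condition_a)
    b_pre = m.condition_values(c.condition_b)
    ok_pre = (np.sum(np.isfinite(a_pre), axis=1) >= 2) & (np.sum(np.isfinite(b_pre), axis=1) >= 2)

    aug = augment_replicates(m, c, target=target_replicates, seed=seed)
    a = aug.condition_values(c.condition_a)
    b = aug.condition_values(c.condition_b)
    rng = spawn_rng(seed, f"permutation:{c.key}")
    p = np.ones(m.n_features)

    if c.paired:
        d = b - a
        obs = np.isfinite(d)
        n_pairs = obs.sum(axis=1)
        compute = ok_pre & (n_pairs >= 2)
        groups: dict[int, list[int]] = {}
        for f in np.flatnonzero(compute):
            groups.setdefault(int(n_pairs[f]), []).append(f)
        for np_k, feats in groups.items():
            feats = np.asarray(feats)
            D = np.stack([d[f][obs[f]] for f in feats])  # (F, np_k)
            u_obs = _u_paired(D, np.full(len(feats), np_k))
            for start in range(0, len(feats), _CHUNK):
                sl = slice(start, start + _CHUNK)
                block = D[sl]  # (f, np_k)
                signs = rng.integers(0, 2, size=(block.shape[0], n_rand, np_k)) * 2 - 1
                d_rand = block[:, None, :] * signs
                u_rand = _u_paired(d_rand, np_k)
                exceed = (u_rand >= u_obs[sl, None]).sum(axis=1)
                p[feats[sl]] = (exceed + 1.0) / (n_rand + 1.0)
        return p

    obs_a = np.isfinite(a)
    obs_b = np.isfinite(b)
    na = obs_a.sum(axis=1)
    nb = obs_b.sum(axis=1)
    compute = ok_pre & (na >= 2) & (nb >= 2)
    groups = {}
    for f in np.flatnonzero(compute):
        groups.setdefault((int(na[f]), int(nb[f])), []).append(f)
    for (na_k, nb_k), feats in groups.items():
        feats = np.asarray(feats)
        n_tot = na_k + nb_k
        X = np.stack(
            [np.concatenate([a[f][obs_a[f]], b[f][obs_b[f]]]) for f in feats]
        )  # (F, n_tot), group a first
        u_obs = _u_unpaired(X[:, :na_k], X[:, na_k:], n_tot)
        for start in range(0, len(feats), _CHUNK):
            sl = slice(start, start + _CHUNK)
            block = X[sl]
            keys = rng.random((block.shape[0], n_rand, n_tot))
            idx = np.argsort(keys, axis=-1)
            perm = np.take_along_axis(
                np.broadcast_to(block[:, None, :], idx.shape), idx, axis=-1
            )
            u_rand = _u_unpaired(perm[..., :na_k], perm[..., na_k:], n_tot)
            exceed = (u_rand >= u_obs[sl, None]).sum(axis=1)
            p[feats[sl]] = (exceed + 1.0) / (n_rand + 1.0)
    return p
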