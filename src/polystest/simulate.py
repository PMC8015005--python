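"""Ground-truth simulator for benchmarking the statistical tests.

Datasets are two-condition matrices of i.i.d. standard-normal log abundances.
A fraction of the features is regulated: each regulated feature is displaced
by +delta or -delta (sign drawn per feature) in the second condition.
Missingness is then introduced by removing a global fraction of cells by
weighted sampling without replacement, with per-column weights
``(1 - rank/N)**mu`` over the abundance ranks, so that ``mu = 0`` gives
missing-at-random and large ``mu`` concentrates removal on low-abundance
cells (missing-not-at-random, detection-limit-like).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import spawn_rng
from .data import Design, ExpressionMatrix

__all__ = ["SimulationParams", "GroundTruth", "generate_dataset", "remove_values"]

#: Table of admitted parameter ranges (values outside warn, not fail).
_RANGES = {
    "n_features": (500, 10_000),
    "n_replicates": (3, 10),
    "frac_regulated": (0.0, 50.0),
    "delta": (1.0, 5.0),
    "frac_missing": (0.0, 50.0),
    "mu": (0.0, 100.0),
}


@dataclass(frozen=True)
class SimulationParams:
    """Benchmark parameters (percentages are 0-100).

    Defaults correspond to a noisy but recoverable study condition: 1000
    features, 5 replicates per condition, 5% regulated at displacement 2,
    20% missing values with moderate abundance dependence (mu = 10).
    """

    n_features: int = 1000
    n_replicates: int = 5
    frac_regulated: float = 5.0
    delta: float = 2.0
    frac_missing: float = 20.0
    mu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                warnings.warn(
                    f"{name}={v} outside the benchmark range [{lo}, {hi}]", stacklevel=3
                )
        if self.frac_missing >= 100:
            raise ValueError("frac_missing must be < 100")

    @property
    def n_regulated(self) -> int:
        return int(round(self.n_features * self.frac_regulated / 100.0))


@dataclass(frozen=True)
class GroundTruth:
    """Per-feature regulation direction: -1 (down in B), 0 (null), +1 (up in B)."""

    direction: np.ndarray = field(repr=False)

    @property
    def regulated(self) -> np.ndarray:
        return self.direction != 0

    @property
    def n_regulated(self) -> int:
        return int(np.count_nonzero(self.direction))


def generate_dataset(params: SimulationParams) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a two-condition matrix (conditions "A" and "B") with ground truth."""
    n, r = params.n_features, params.n_replicates
    rng = spawn_rng(params.seed, "simulate:values")
    values = rng.standard_normal((n, 2 * r))
    direction = np.zeros(n, dtype=np.int8)
    n_reg = params.n_regulated
    if n_reg:
        reg_idx = rng.choice(n, size=n_reg, replace=False)
        signs = rng.choice([-1, 1], size=n_reg)
        direction[reg_idx] = signs
        # displacement applied to every replicate of condition B
        values[reg_idx, r:] += signs[:, None] * params.delta
    labels = [f"A_{i}" for i in range(1, r + 1)] + [f"B_{i}" for i in range(1, r + 1)]
    design = Design.from_conditions({"A": labels[:r], "B": labels[r:]})
    ids = [f"feature_{i + 1:05d}" for i in range(n)]
    matrix = ExpressionMatrix(values, ids, labels, design)
    if params.frac_missing > 0:
        matrix = remove_values(matrix, params.frac_missing, params.mu, seed=params.seed)
    return matrix, GroundTruth(direction=direction)


def remove_values(
    m: ExpressionMatrix,
    frac_missing: float,
    mu: float,
    seed: int = 0,
) -> ExpressionMatrix:
    """Remove a global fraction of cells by abundance-weighted sampling.

    Within each sample column the observed values are ranked ascending
    (rank 1 = lowest abundance) and given removal weight
    ``(1 - rank/N)**mu``; exactly ``round(frac_missing% * total cells)``
    cells are then removed without replacement, proportionally to the
    weights (Gumbel top-k).  The per-column top-ranked value has zero weight
    for ``mu > 0`` and is never removed; ``mu = 0`` removes uniformly.
    """
    if not (0 <= frac_missing < 100):
        raise ValueError("frac_missing must lie in [0, 100)")
    if frac_missing == 0:
        return m
    values = m.values.copy()
    n, s = values.shape
    n_remove = int(round(frac_missing / 100.0 * values.size))
    if n_remove == 0:
        return m
    rng = spawn_rng(seed, "simulate:removal")
    log_w = np.full((n, s), -np.inf)
    for j in range(s):
        col = values[:, j]
        obs = np.isfinite(col)
        n_obs = int(obs.sum())
        if n_obs == 0:
            continue
        ranks = np.empty(n_obs)
        ranks[np.argsort(col[obs], kind="mergesort")] = np.arange(1, n_obs + 1)
        frac = 1.0 - ranks / n_obs
        if mu == 0:
            lw = np.zeros(n_obs)
        else:
            with np.errstate(divide="ignore"):
                lw = mu * np.log(frac)
        log_w[obs, j] = lw
    flat_lw = log_w.ravel()
    candidates = flat_lw > -np.inf
    if n_remove > candidates.sum():
        raise ValueError(
            f"cannot remove {n_remove} cells: only {int(candidates.sum())} have positive weight"
        )
    gumbel = rng.gumbel(size=flat_lw.size)
    keys = np.where(candidates, flat_lw + gumbel, -np.inf)
    drop = np.argpartition(keys, -n_remove)[-n_remove:]
    flat = values.ravel()
    flat[drop] = np.nan
    return m.with_values(flat.reshape(n, s))
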