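"""Validation metrics against simulation ground truth.

The headline quantities are the measured *true FDR*, ``tFDR = FP/(FP+TP)``,
and the sensitivity ``TP/(TP+FN)`` of a test's detections at a fixed FDR
cutoff, plus null-data calibration checks (false-positive counts on
pure-noise datasets and a Kolmogorov-Smirnov uniformity check on p-values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .data import ComparisonSpec
from .fdr import bh_adjust
from .miss import miss_test
from .moderated import moderated_t
from .permutation import permutation_p
from .rankprod import unpaired_rank_product
from .simulate import GroundTruth, SimulationParams, generate_dataset
from .ttest import t_test

__all__ = [
    "ConfusionAtThreshold",
    "confusion",
    "roc_points",
    "null_calibration",
    "uniformity_check",
]


@dataclass(frozen=True)
class ConfusionAtThreshold:
    """Detection counts at one FDR cutoff (detection means FDR strictly below)."""

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def true_fdr(self) -> float:
        """FP/(FP+TP); zero by convention when there are no detections."""
        detected = self.tp + self.fp
        return self.fp / detected if detected else 0.0

    @property
    def sensitivity(self) -> float:
        positives = self.tp + self.fn
        return self.tp / positives if positives else 0.0


def _truth_labels(truth: GroundTruth | np.ndarray) -> np.ndarray:
    if isinstance(truth, GroundTruth):
        return truth.regulated
    return np.asarray(truth, dtype=bool)


def confusion(
    fdr: np.ndarray, truth: GroundTruth | np.ndarray, threshold: float
) -> ConfusionAtThreshold:
    """Confusion counts of detections (``fdr < threshold``) against the truth."""
    fdr = np.asarray(fdr, dtype=float)
    labels = _truth_labels(truth)
    if fdr.shape != labels.shape:
        raise ValueError("fdr and truth must have equal length")
    detected = fdr < threshold
    return ConfusionAtThreshold(
        threshold=float(threshold),
        tp=int(np.sum(detected & labels)),
        fp=int(np.sum(detected & ~labels)),
        fn=int(np.sum(~detected & labels)),
        tn=int(np.sum(~detected & ~labels)),
    )


def roc_points(fdr: np.ndarray, truth: GroundTruth | np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) points sweeping the detection threshold over the FDR vector."""
    fdr = np.asarray(fdr, dtype=float)
    labels = _truth_labels(truth)
    if labels.all() or not labels.any():
        raise ValueError("truth must contain at least one positive and one negative")
    fpr, tpr, _ = roc_curve(labels.astype(int), -fdr)
    return list(zip(fpr.tolist(), tpr.tolist()))


_NULL_TESTS = {"miss", "limma", "rank_products", "permutation", "t"}


def _run_single_test(test: str, matrix, comparison: ComparisonSpec, seed: int) -> np.ndarray:
    if test == "miss":
        return miss_test(matrix, comparison)
    if test == "limma":
        return moderated_t(matrix, comparison)[2]
    if test == "rank_products":
        return unpaired_rank_product(matrix, comparison, seed=seed)
    if test == "permutation":
        return permutation_p(matrix, comparison, seed=seed)
    if test == "t":
        return t_test(matrix, comparison)
    raise KeyError(f"unknown test {test!r}; expected one of {sorted(_NULL_TESTS)}")


def null_calibration(
    test: str,
    grid: Sequence[SimulationParams],
    fdr_threshold: float = 0.1,
) -> tuple[np.ndarray, float]:
    """False-positive behaviour of one test on pure-noise datasets.

    Every grid entry must have no regulated features.  Returns the
    per-dataset count of features with BH-adjusted FDR below the cutoff and
    the fraction of datasets containing at least one such false positive.
    """
    counts = []
    for params in grid:
        if params.n_regulated != 0:
            raise ValueError("null_calibration requires grids with zero regulated features")
        matrix, _ = generate_dataset(params)
        comparison = ComparisonSpec("A", "B")
        p = _run_single_test(test, matrix, comparison, seed=params.seed)
        fdr = bh_adjust(p)
        counts.append(int(np.sum(fdr < fdr_threshold)))
    counts = np.asarray(counts, dtype=int)
    frac_any = float(np.mean(counts > 0)) if counts.size else 0.0
    return counts, frac_any


def uniformity_check(p: np.ndarray, alpha: float = 0.01) -> tuple[float, bool]:
    """One-sample Kolmogorov-Smirnov check of p-values against Uniform(0,1)."""
    p = np.asarray(p, dtype=float)
    if p.size < 100:
        raise ValueError("uniformity_check needs at least 100 p-values")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), bool(res.pvalue >= alpha)
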