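"""Core data structures, matrix IO and preprocessing.

Quantification matrices are feature x sample arrays of log2 abundances in
which missing cells are ``NaN``.  A zero is a legitimate log-abundance and is
never treated as missing; imputation is deliberately absent from this package.
The experimental design assigns every sample column to exactly one condition
and a replicate index (1..r, contiguous), which is the pairing key for paired
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "ComparisonSpec",
    "ExpressionMatrix",
    "load_matrix",
    "write_matrix",
    "sum_technical_replicates",
    "log2_transform",
    "median_normalize",
    "filter_min_observed",
    "mean_log_ratio",
]


class Design:
    """Assignment of sample labels to (condition, replicate index).

    Replicate indices within each condition must be 1..r without gaps; they
    define the pairing for paired comparisons.
    """

    def __init__(self, assignment: Mapping[str, tuple[str, int]]):
        self._assignment = {str(s): (str(c), int(r)) for s, (c, r) in assignment.items()}
        by_cond: dict[str, list[int]] = {}
        for _, (cond, rep) in self._assignment.items():
            by_cond.setdefault(cond, []).append(rep)
        for cond, reps in by_cond.items():
            if sorted(reps) != list(range(1, len(reps) + 1)):
                raise ValueError(
                    f"replicate indices for condition {cond!r} must be 1..{len(reps)} "
                    f"without gaps, got {sorted(reps)}"
                )
        self._by_cond = {c: len(r) for c, r in by_cond.items()}

    @classmethod
    def from_conditions(cls, conditions: Mapping[str, Sequence[str]]) -> "Design":
        """Build a design from ``{condition: [sample, ...]}`` (replicates in list order)."""
        assignment: dict[str, tuple[str, int]] = {}
        for cond, samples in conditions.items():
            for i, s in enumerate(samples, start=1):
                if s in assignment:
                    raise ValueError(f"sample {s!r} assigned to more than one condition")
                assignment[s] = (cond, i)
        return cls(assignment)

    def __contains__(self, sample: str) -> bool:
        return sample in self._assignment

    def __len__(self) -> int:
        return len(self._assignment)

    def condition_of(self, sample: str) -> str:
        return self._assignment[sample][0]

    def replicate_of(self, sample: str) -> int:
        return self._assignment[sample][1]

    @property
    def samples(self) -> list[str]:
        return list(self._assignment)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, (c, _) in self._assignment.items():
            seen.setdefault(c)
        return list(seen)

    def n_replicates(self, condition: str) -> int:
        try:
            return self._by_cond[condition]
        except KeyError:
            raise KeyError(f"condition {condition!r} not in design") from None

    def samples_for(self, condition: str) -> list[str]:
        """Samples of a condition ordered by replicate index."""
        if condition not in self._by_cond:
            raise KeyError(f"condition {condition!r} not in design")
        members = [(r, s) for s, (c, r) in self._assignment.items() if c == condition]
        return [s for _, s in sorted(members)]

    def to_dict(self) -> dict[str, dict[str, object]]:
        return {s: {"condition": c, "replicate": r} for s, (c, r) in self._assignment.items()}


@dataclass(frozen=True)
class ComparisonSpec:
    """An ordered pair of conditions; positive effects mean higher in ``condition_b``."""

    condition_a: str
    condition_b: str
    paired: bool = False

    def __post_init__(self):
        if self.condition_a == self.condition_b:
            raise ValueError("condition_a and condition_b must differ")

    @property
    def key(self) -> str:
        """Column-name key, treatment first: ``B.vs.A``."""
        return f"{self.condition_b}.vs.{self.condition_a}"

    def validate(self, design: Design) -> None:
        for cond in (self.condition_a, self.condition_b):
            if cond not in design.conditions:
                raise ValueError(f"condition {cond!r} not present in design")
        if self.paired and design.n_replicates(self.condition_a) != design.n_replicates(
            self.condition_b
        ):
            raise ValueError("paired comparison requires equal replicate counts")


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance matrix with explicit missing cells (NaN)."""

    values: np.ndarray
    feature_ids: list[str]
    sample_labels: list[str]
    design: Design
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_labels = [str(s) for s in self.sample_labels]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x samples)")
        if self.values.shape != (len(self.feature_ids), len(self.sample_labels)):
            raise ValueError(
                f"shape {self.values.shape} does not match {len(self.feature_ids)} features "
                f"x {len(self.sample_labels)} samples"
            )
        dupes = pd.Index(self.feature_ids)[pd.Index(self.feature_ids).duplicated()].unique()
        if len(dupes):
            raise ValueError(f"duplicate feature ids: {list(dupes)}")
        missing_design = [s for s in self.sample_labels if s not in self.design]
        if missing_design:
            raise ValueError(f"samples not covered by design: {missing_design}")
        if np.isinf(self.values).any():
            raise ValueError("matrix contains infinite values")
        if self.feature_meta is not None and list(self.feature_meta.index) != self.feature_ids:
            self.feature_meta = self.feature_meta.reindex(self.feature_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column_indices(self, condition: str) -> np.ndarray:
        """Column indices for a condition, ordered by replicate index."""
        pos = {s: i for i, s in enumerate(self.sample_labels)}
        return np.array([pos[s] for s in self.design.samples_for(condition)], dtype=int)

    def condition_values(self, condition: str) -> np.ndarray:
        return self.values[:, self.column_indices(condition)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_labels)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=np.asarray(values, dtype=float))


_NA_TOKENS = ["", "NA", "NaN", "nan", "NAN", "na", "N/A", "#N/A", "null", "None"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_matrix(
    path: str | Path,
    design: Design | Mapping[str, Sequence[str]],
    feature_meta_columns: Sequence[str] = (),
) -> ExpressionMatrix:
    """Read a delimited matrix (first column feature ids, one column per sample).

    Empty cells, ``NA``/``NaN`` tokens and any non-numeric token parse as
    missing.  ``design`` must map every quantitative column; columns not in
    the design or in ``feature_meta_columns`` are ignored with a log message.
    """
    path = Path(path)
    if not isinstance(design, Design):
        design = Design.from_conditions(design)
    raw = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_TOKENS, keep_default_na=False, dtype=str)
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate feature ids in {path.name}: {sorted(dup)}")
    absent = [s for s in design.samples if s not in raw.columns]
    if absent:
        raise ValueError(f"design references columns not found in {path.name}: {absent}")
    values = np.column_stack(
        [pd.to_numeric(raw[s], errors="coerce").to_numpy(dtype=float) for s in design.samples]
    )
    meta = None
    if feature_meta_columns:
        absent_meta = [c for c in feature_meta_columns if c not in raw.columns]
        if absent_meta:
            raise ValueError(f"feature_meta columns not found: {absent_meta}")
        meta = raw[list(feature_meta_columns)].apply(pd.to_numeric, errors="coerce")
        meta.index = list(ids)
    ignored = [c for c in raw.columns if c != id_col and c not in design.samples and c not in feature_meta_columns]
    if ignored:
        logger.info("ignoring %d non-design columns: %s", len(ignored), ignored)
    return ExpressionMatrix(values, list(ids), list(design.samples), design, meta)


def write_matrix(m: ExpressionMatrix, path: str | Path, id_column: str = "feature") -> None:
    """Write the matrix back to TSV/CSV; missing cells become empty strings."""
    path = Path(path)
    frame = m.to_frame()
    frame.index.name = id_column
    frame.to_csv(path, sep=_sep_for(path), na_rep="", float_format="%.17g")


def sum_technical_replicates(
    m: ExpressionMatrix, groups: Mapping[str, str], design: Design | None = None
) -> ExpressionMatrix:
    """Sum technical replicates into biological samples (raw-scale input).

    ``groups`` maps each sample label to a biological-sample id.  Sums ignore
    missing values; a group whose members are all missing stays missing.  All
    members of a group must share a condition; output replicate indices are
    re-enumerated per condition in group first-appearance order.
    """
    unmapped = [s for s in m.sample_labels if s not in groups]
    if unmapped:
        raise ValueError(f"samples without a technical-replicate group: {unmapped}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, s in enumerate(m.sample_labels):
        g = str(groups[s])
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(i)
    for g in order:
        if not members[g]:
            raise ValueError(f"technical-replicate group {g!r} has no members")
    cols = []
    assignment: dict[str, tuple[str, int]] = {}
    per_cond_counter: dict[str, int] = {}
    for g in order:
        idx = members[g]
        conds = {m.design.condition_of(m.sample_labels[i]) for i in idx}
        if len(conds) != 1:
            raise ValueError(f"group {g!r} mixes conditions {sorted(conds)}")
        cond = conds.pop()
        block = m.values[:, idx]
        all_missing = np.all(np.isnan(block), axis=1)
        summed = np.where(all_missing, np.nan, np.nansum(block, axis=1))
        cols.append(summed)
        per_cond_counter[cond] = per_cond_counter.get(cond, 0) + 1
        assignment[g] = (cond, per_cond_counter[cond])
    new_design = design if design is not None else Design(assignment)
    return ExpressionMatrix(np.column_stack(cols), list(m.feature_ids), order, new_design, m.feature_meta)


def log2_transform(m: ExpressionMatrix, on_nonpositive: str = "missing") -> ExpressionMatrix:
    """log2-transform every non-missing cell.

    Zeros or negative values either become missing (default) or raise,
    depending on ``on_nonpositive`` ("missing" | "error").
    """
    if on_nonpositive not in ("missing", "error"):
        raise ValueError("on_nonpositive must be 'missing' or 'error'")
    bad = np.isfinite(m.values) & (m.values <= 0)
    if bad.any():
        if on_nonpositive == "error":
            raise ValueError(f"{int(bad.sum())} cells are <= 0; cannot take log2")
        logger.info("log2_transform: converting %d non-positive cells to missing", int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, np.log2(m.values))
    return m.with_values(out)


def median_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample column's median of observed values (log-scale input)."""
    n_obs = np.sum(~np.isnan(m.values), axis=0)
    if (n_obs == 0).any():
        empty = [m.sample_labels[i] for i in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"columns with no observed values cannot be normalized: {empty}")
    medians = np.nanmedian(m.values, axis=0)
    return m.with_values(m.values - medians[None, :])


def filter_min_observed(
    m: ExpressionMatrix,
    min_total: int,
    min_meta: tuple[str, float] | None = None,
) -> ExpressionMatrix:
    """Keep features with >= ``min_total`` observed cells (and optional meta cutoff).

    ``min_meta=(column, threshold)`` additionally requires
    ``feature_meta[column] >= threshold`` (missing meta counts as failing).
    Row order is preserved.
    """
    keep = np.sum(~np.isnan(m.values), axis=1) >= int(min_total)
    if min_meta is not None:
        key, threshold = min_meta
        if m.feature_meta is None or key not in m.feature_meta.columns:
            raise ValueError(f"feature_meta column {key!r} not available")
        meta_vals = m.feature_meta[key].to_numpy(dtype=float)
        keep &= np.nan_to_num(meta_vals, nan=-np.inf) >= float(threshold)
    removed = int((~keep).sum())
    logger.info("filter_min_observed: removed %d of %d features", removed, m.n_features)
    idx = np.flatnonzero(keep)
    meta = m.feature_meta.iloc[idx] if m.feature_meta is not None else None
    return ExpressionMatrix(
        m.values[idx], [m.feature_ids[i] for i in idx], list(m.sample_labels), m.design, meta
    )


def mean_log_ratio(m: ExpressionMatrix, c: ComparisonSpec) -> np.ndarray:
    """Per-feature log2 fold change of ``condition_b`` over ``condition_a``.

    Unpaired: difference of group means over observed values.  Paired: mean of
    per-pair differences over complete pairs.  NaN where undefined.
    """
    c.validate(m.design)
    a = m.condition_values(c.condition_a)
    b = m.condition_values(c.condition_b)

    def _mean(x: np.ndarray) -> np.ndarray:
        cnt = np.sum(~np.isnan(x), axis=1)
        sums = np.nansum(x, axis=1)
        return np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)

    if c.paired:
        return _mean(b - a)
    return _mean(b) - _mean(a)
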