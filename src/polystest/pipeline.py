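"""End-to-end orchestration: preprocessing, tests, corrections, output table."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    ComparisonSpec,
    Design,
    ExpressionMatrix,
    filter_min_observed,
    load_matrix,
    log2_transform,
    mean_log_ratio,
    median_normalize,
    sum_technical_replicates,
)
from .fdr import UNIFIED_TESTS, assign_corrections
from .miss import miss_test
from .moderated import moderated_t
from .permutation import permutation_p
from .rankprod import paired_rank_product, unpaired_rank_product
from .ttest import t_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_tests", "run", "ALL_TESTS"]

ALL_TESTS = ("miss", "limma", "rank_products", "permutation", "t")


@dataclass
class RunConfig:
    """Declarative description of one analysis run (YAML-loadable)."""

    input_path: str
    output_path: str
    conditions: Mapping[str, Sequence[str]]
    comparisons: Sequence[tuple[str, str]]  # (reference, treatment) pairs
    paired: bool = False
    tests: Sequence[str] = ALL_TESTS
    seed: int = 0
    miss_quantiles: int = 100
    rp_pairings: int = 100
    perm_n: int = 1000
    perm_target_reps: int = 7
    log2: bool = False
    normalize: bool = True
    min_observed: int = 0
    technical_groups: Mapping[str, str] | None = None
    feature_meta_columns: Sequence[str] = ()
    min_meta: tuple[str, float] | None = None
    fdr_threshold: float = 0.05

    def __post_init__(self):
        unknown = [t for t in self.tests if t not in ALL_TESTS]
        if unknown:
            raise ValueError(f"unknown tests {unknown}; valid: {ALL_TESTS}")
        if not self.tests:
            raise ValueError("at least one test must be enabled")
        if not self.comparisons:
            raise ValueError("at least one comparison is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = raw.pop("design", {})
        kwargs = dict(
            conditions=design.get("conditions", raw.pop("conditions", {})),
            paired=bool(design.get("paired", raw.pop("paired", False))),
            comparisons=[tuple(cmp) for cmp in raw.pop("comparisons", [])],
        )
        pre = raw.pop("preprocessing", {})
        for key in ("log2", "normalize", "min_observed", "technical_groups", "min_meta",
                    "feature_meta_columns"):
            if key in pre:
                kwargs[key] = pre[key]
        kwargs.update(raw)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(kwargs.get("min_meta"), (list, tuple)):
            key, thr = kwargs["min_meta"]
            kwargs["min_meta"] = (str(key), float(thr))
        kwargs.setdefault("input_path", "")
        kwargs.setdefault("output_path", "")
        return cls(**kwargs)

    @property
    def comparison_specs(self) -> list[ComparisonSpec]:
        return [ComparisonSpec(a, b, paired=self.paired) for a, b in self.comparisons]


def run_tests(
    matrix: ExpressionMatrix,
    comparisons: Sequence[ComparisonSpec],
    tests: Sequence[str] = ALL_TESTS,
    seed: int = 0,
    miss_quantiles: int = 100,
    rp_pairings: int = 100,
    perm_n: int = 1000,
    perm_target_reps: int = 7,
) -> pd.DataFrame:
    """Run the enabled tests per comparison and assemble the result table.

    Columns per comparison key ``K``: ``log_ratio_K``, ``<test>_p_K``,
    ``<test>_FDR_K`` and, when all four unified tests are enabled,
    ``PolySTest_FDR_K``.
    """
    unknown = [t for t in tests if t not in ALL_TESTS]
    if unknown:
        raise ValueError(f"unknown tests {unknown}")
    out = pd.DataFrame(index=pd.Index(matrix.feature_ids, name="feature"))
    for c in comparisons:
        c.validate(matrix.design)
        key = c.key
        out[f"log_ratio_{key}"] = mean_log_ratio(matrix, c)
        raw: dict[str, np.ndarray] = {}
        for test in tests:
            if test == "miss":
                raw[test] = miss_test(matrix, c, n_quantiles=miss_quantiles)
            elif test == "limma":
                raw[test] = moderated_t(matrix, c)[2]
            elif test == "rank_products":
                if c.paired:
                    raw[test] = paired_rank_product(matrix, c).p
                else:
                    raw[test] = unpaired_rank_product(
                        matrix, c, n_pairings=rp_pairings, seed=seed
                    )
            elif test == "permutation":
                raw[test] = permutation_p(
                    matrix, c, n_rand=perm_n, seed=seed, target_replicates=perm_target_reps
                )
            elif test == "t":
                raw[test] = t_test(matrix, c)
        fdrs = assign_corrections(raw)
        for test in tests:
            out[f"{test}_p_{key}"] = raw[test]
            out[f"{test}_FDR_{key}"] = fdrs[test]
        if "polystest" in fdrs:
            out[f"PolySTest_FDR_{key}"] = fdrs["polystest"]
    return out


def run(config: RunConfig) -> pd.DataFrame:
    """Execute a full configured run; writes the result TSV and a run log."""
    matrix = load_matrix(
        config.input_path,
        Design.from_conditions(config.conditions),
        feature_meta_columns=config.feature_meta_columns,
    )
    n_initial = matrix.n_features
    if config.technical_groups:
        matrix = sum_technical_replicates(matrix, config.technical_groups)
    if config.log2:
        matrix = log2_transform(matrix)
    if config.normalize:
        matrix = median_normalize(matrix)
    if config.min_observed or config.min_meta:
        matrix = filter_min_observed(matrix, config.min_observed, config.min_meta)
    table = run_tests(
        matrix,
        config.comparison_specs,
        tests=config.tests,
        seed=config.seed,
        miss_quantiles=config.miss_quantiles,
        rp_pairings=config.rp_pairings,
        perm_n=config.perm_n,
        perm_target_reps=config.perm_target_reps,
    )
    out_path = Path(config.output_path)
    table.to_csv(out_path, sep="\t", na_rep="", float_format="%.10g")
    summary = {
        "version": __version__,
        "seed": config.seed,
        "tests": list(config.tests),
        "comparisons": [list(cmp) for cmp in config.comparisons],
        "paired": config.paired,
        "features_input": n_initial,
        "features_tested": int(matrix.n_features),
        "parameters": {
            "miss_quantiles": config.miss_quantiles,
            "rp_pairings": config.rp_pairings,
            "perm_n": config.perm_n,
            "perm_target_reps": config.perm_target_reps,
        },
        "significant_at_threshold": {
            col: int((table[col] < config.fdr_threshold).sum())
            for col in table.columns
            if "_FDR_" in col
        },
        "fdr_threshold": config.fdr_threshold,
    }
    log_path = out_path.with_suffix(out_path.suffix + ".log")
    log_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %s and %s", out_path, log_path)
    return table
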