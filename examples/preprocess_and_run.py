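"""Preprocessing a raw-scale quantification table the standard way.

Technical replicates are summed, intensities log2-transformed, each sample
centred on its median, and sparse features removed before testing — the
usual treatment of label-free protein intensities.
"""

import numpy as np

from polystest import (
    ComparisonSpec,
    Design,
    ExpressionMatrix,
    filter_min_observed,
    log2_transform,
    median_normalize,
    run_tests,
    sum_technical_replicates,
)

rng = np.random.default_rng(0)
# 300 proteins x (2 conditions x 3 biological x 2 technical) raw intensities
n = 300
base = 2 ** rng.normal(20, 2, size=n)
tech = np.empty((n, 12))
for b in range(6):
    for t in range(2):
        tech[:, 2 * b + t] = base * 2 ** rng.normal(0, 0.3, size=n)
tech[:10, 6:] *= 8.0  # first 10 proteins 8-fold up in condition B
tech[rng.random((n, 12)) < 0.1] = np.nan

labels = [f"{cond}{b}_t{t}" for cond in "AB" for b in (1, 2, 3) for t in (1, 2)]
design = Design({lab: (lab[0], 1 + (i % 6)) for i, lab in enumerate(labels)})
m = ExpressionMatrix(tech, [f"prot{i}" for i in range(n)], labels, design)

groups = {lab: lab.split("_")[0] for lab in labels}  # A1..A3, B1..B3
m = sum_technical_replicates(m, groups)
m = log2_transform(m)
m = median_normalize(m)
m = filter_min_observed(m, min_total=2)
print(f"after preprocessing: {m.n_features} features x {m.n_samples} biological samples")

table = run_tests(m, [ComparisonSpec("A", "B")],
                  tests=("miss", "limma", "rank_products", "permutation"), seed=1)
hits = table.index[table["PolySTest_FDR_B.vs.A"] < 0.05].tolist()
print(f"features at unified FDR < 0.05: {hits}")
print("the spiked 8-fold proteins (prot0..prot9) dominate the detections with")
print("three biological replicates per condition.")
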