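"""The missingness statistic on its own, plus the detection-limit scan.

With r = 3 replicates per condition and a 50% chance of a missing value,
every missing/present pattern over the six cells has probability 1/64; the
probability of a missing-count difference k between the conditions follows
by convolving two binomials.  A feature missing in all replicates of one
condition but observed in the other corresponds to k = 3.
"""

import numpy as np

from polystest import ComparisonSpec, diff_probabilities, miss_test
from polystest.data import Design, ExpressionMatrix

table = diff_probabilities(r=3, p_na=0.5)
print("P(k) for k = 0..3 at r=3, p_NA=0.5:", table.P)
print("as fractions: 5/16, 15/32, 3/16, 1/32")
print("all-missing-versus-none (k=3):", table.P[3], "= 1/32")

# a tiny matrix: feature f1 is absent in condition A and abundant in B
nan = np.nan
values = np.array([
    [nan, nan, nan, 8.1, 8.3, 8.0],   # f1: rescued only by missingness evidence
    [5.0, 5.2, 5.1, 5.1, 5.0, 5.2],   # f2: unchanged
    [2.0, 2.2, 2.1, 6.9, 7.2, 7.0],   # f3: shifted and fully observed
    [3.0, nan, 3.1, 3.2, 3.0, nan],   # f4: scattered missingness, no shift
])
labels = ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
m = ExpressionMatrix(values, ["f1", "f2", "f3", "f4"], labels,
                     Design.from_conditions({"A": labels[:3], "B": labels[3:]}))
p = miss_test(m, ComparisonSpec("A", "B"))
for fid, pv in zip(m.feature_ids, p):
    print(f"{fid}: Miss test p = {pv:.4g}")
print("f1 and f3 get small p-values: f1 from its missing values alone, f3 because")
print("the scan censors its low condition-A values below the detection limit.")
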