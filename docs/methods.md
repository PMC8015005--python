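# Methods

This note records the statistical models implemented in `polystest`, the
choices made where the published descriptions leave room, and what the
simulation-based tests do and do not establish.

## Data model

A quantification matrix holds log2 abundances, features × samples, with
missing cells represented as NaN. Zero is a legitimate log abundance and is
never conflated with missingness; no routine in the package imputes. The
design assigns each sample to one condition with replicate indices 1..r
(contiguous); replicate index is the pairing key for paired analyses, since
quantification tables carry no other pairing structure. Preprocessing
mirrors common label-free practice: technical replicates are summed on the
raw scale (missing values ignored; an all-missing group stays missing),
intensities are log2-transformed (non-positive cells become missing by
default, or raise if configured), each sample column is centred on its
observed median, and features below a minimum observation count (optionally
also a feature-metadata threshold such as unique-peptide count) are removed.

## Miss test

Null hypothesis: values are missing at random with probability p_NA, the
missing fraction of the entire matrix. The count of missing values among the
r replicates of one condition is then Binomial(r, p_NA) with pmf b_i, and
the absolute difference k of missing counts between two conditions has

    P_0 = sum_j b_j^2,        P_k = 2 * sum_j b_{j+k} b_j   (k >= 1).

The factor 2 applies only for k >= 1: the k = 0 event is self-symmetric, and
doubling it would both break normalization and contradict the r = 3,
p_NA = 1/2 reference values (5/16, 15/32, 3/16, 1/32). Unequal replicate
counts are handled by the distribution of |X − Y| with independent
X ~ Bin(r_a, p_NA), Y ~ Bin(r_b, p_NA), which reduces exactly to the
expression above when r_a = r_b.

Abundance-dependence enters through a detection-limit scan. Thresholds are
the q/100 empirical quantiles (q = 0..99) of all observed values; q = 0
reproduces the uncensored data and the degenerate all-censored scenario is
excluded. In each scenario, cells strictly below the threshold are treated
as missing, p_NA is recomputed over the whole matrix, and each feature's k
is recounted on the compared columns. The p-value is the minimum P_k over
scenarios, multiplied by max(r_a, r_b) + 1 (the number of attainable k
values) and capped at 1. Direction is not tested (k is unsigned).

Calibration properties, as measured on simulated null data: the small-p tail
is approximately valid (sub-uniform ECDF; at BH FDR < 0.1 a 48-dataset noise
grid yields at most 1–2 stray detections in roughly 5–10% of datasets,
seed-dependent). The full p-value distribution is deliberately *not*
uniform: the cap at 1 and the discrete support of the scenario-minimum put a
large point mass at p = 1, so a global Kolmogorov–Smirnov test against
Uniform(0,1) always rejects. This is a property of the construction — the
r + 1 multiplier corrects the selection over k but not the minimum over the
100 correlated scenarios — and is why per-test correction uses
Benjamini–Hochberg (robust to the p = 1 mass) rather than q-values.

## Moderated t-test

Two-group contrasts are fit per comparison over observed values: unpaired
comparisons use the pooled two-group variance with d_g = n_a + n_b − 2 and
unscaled error sqrt(1/n_a + 1/n_b); paired comparisons the variance of
complete-pair differences with d_g = n_pairs − 1. Hyperparameters (d0, s0²)
of the scaled-F variance prior are estimated by moment matching on
log s²_g via digamma/trigamma identities, with d0 from trigamma inversion of
the excess dispersion. When the empirical dispersion of the log variances
does not exceed its expected sampling variance, d0 is infinite; in that
degenerate branch the prior variance is the geometric mean of the sample
variances (no sampling-noise offset is applied, so identical inputs return
exactly their common value). The finite-d0 path reproduces Bioconductor
limma to ~1e-15 on shared inputs (verified in the test suite through an
Rscript oracle). The moderated statistic uses the posterior variance
(d0 s0² + d_g s²_g)/(d0 + d_g) and a t reference with d_g + d0 degrees of
freedom (normal when d0 is infinite). Features with d_g < 1 receive p = 1
rather than being dropped, so output length always equals feature count. No
multi-condition joint fit, intensity-dependent variance trend or sample
weighting is attempted.

## Rank products

Per replicate pair, the log-ratios (b − a) of the features observed in that
pair are ranked ascending (down list) and descending (up list); a feature's
rank product is the product of rank/n_observed over the pairs where it is
observed (k_eff). Under the null each normalized rank is treated as
Uniform(0,1], so −log(rho) is referred to the Gamma(k_eff, 1) tail; the
continuous approximation is within 2/n of exact rank enumeration for n ≥ 50
(asserted in tests, with an exhaustive-enumeration oracle retained there).
The two-sided p-value doubles the smaller one-sided value, capped at 1,
keeping thresholds comparable with the other tests. Missing ratios shrink
k_eff instead of being imputed; k_eff = 0 yields p = 1. Unpaired designs run
the paired procedure on each of 100 uniformly random replicate bijections
(matching min(r_a, r_b) columns when counts differ) and report the
per-feature mean p-value.

## Permutation test

The statistic is u = |mean(d)/sd(d)| · n for paired differences, and
u = |mean(b) − mean(a)| / sqrt(var(a) + var(b)) · n for unpaired values,
where n counts the observed values used — sparse features are penalized
directly. A zero denominator yields u = 0 (zero numerator) or u = ∞.
Conditions with fewer than 7 replicates are augmented to 7 with
pseudo-replicate columns drawn with replacement from the pool of all
observed values of the compared columns (a column-set-wide pool, drawn
independently per cell). The null uses 1000 per-feature randomizations —
random re-partitions of the feature's pooled observed values (unpaired) or
independent sign flips of its pair differences (paired) — with n held fixed,
since the multiplier models evidence quantity. The p-value is the standard
exceedance fraction (#{u_rand ≥ u_obs} + 1)/(n_rand + 1), ties counting as
exceedances, bounded in [1/(n_rand+1), 1]. Features with fewer than two
observed values in either group before augmentation are discarded with
p = 1. Monotonicity holds in the expected direction: widening an existing
positive separation never raises a feature's p-value at fixed seed; features
whose separation is initially negative can transiently gain p as a global
shift first cancels their difference.

## Multiple testing and the unified score

Benjamini–Hochberg corrects the Miss, rank-product and permutation tests
(which assign p = 1 to discarded features and therefore lack the full
p-value spectrum a background fit needs). Storey q-values correct the t and
moderated tests: pi0(λ) = #{p > λ}/(n(1 − λ)) on λ = 0.05..0.95 is smoothed
with a cubic smoothing spline (GCV) and read off at λ = 0.95; estimation
falls back to pi0 = 1 (plain BH) for fewer than 100 p-values or a degenerate
estimate, and the fallback is logged. The unified PolySTest FDR applies the
Hommel adjustment — equivalent to closed testing with Simes local tests, and
valid under positive dependence — to the four per-test FDRs of each feature
and takes the minimum. The adjustment is applied to FDRs, not raw p-values,
reproducing the published construction faithfully even though FDRs are not
formally p-values. The plain t-test never enters the unified score (it
underestimates the FDR at low replicate numbers).

## Simulator

Each dataset is an N × 2R matrix of i.i.d. Normal(0, 1) log abundances with
conditions A and B. round(N · N_R) features are regulated: each receives a
single sign (± with probability ½) and all its condition-B replicates are
shifted by that signed δ — a per-feature shift is the only reading that
creates detectable group differences. Missingness removes exactly
round(m% · total cells) cells globally by weighted sampling without
replacement (Gumbel top-k), with per-column weights (1 − rank/N)^mu over
ascending abundance ranks; mu = 0 is missing-at-random, large mu
concentrates removal below an effective detection limit (the top-ranked cell
per column is never removed for mu > 0). Removal quotas are global, not
per-column, matching a stated global fraction. Defaults (N = 1000, R = 5,
N_R = 5%, δ = 2, m = 20%, mu = 10) describe a noisy but recoverable regime
where roughly half of the regulated features are too sparse for
variance-based testing — the regime in which the Miss test's rescue
behaviour is visible. The simulator deliberately omits peptide-level
structure, batch effects and heteroscedastic noise, so passing benchmarks
demonstrate calibration and complementarity under idealized missingness
mechanisms, not performance on any particular instrument platform.

## Evaluation

Detections are features with FDR strictly below the cutoff. True FDR is
FP/(FP+TP), defined as 0 when nothing is detected so grid summaries
aggregate cleanly; sensitivity is TP/(TP+FN). ROC points sweep the
detection threshold (delegated to scikit-learn; the trapezoid AUC equals the
pairwise-ordering probability, asserted in tests). Null calibration runs a
test over a grid of pure-noise datasets and reports per-dataset
false-positive counts; the uniformity check is a one-sample KS test against
Uniform(0,1) at α = 0.01 (appropriate for the continuous tests; the Miss
test fails it by construction, see above).

## Problem sizes and determinism

The packaged benchmark loops use 48 null datasets (up to 10000 features) and
50 signal datasets of 1000 features × 10 samples — large enough for stable
rates while keeping the full suite in the low minutes on one CPU. Every
stochastic component (simulation, value removal, replicate augmentation,
random pairings, permutation draws) takes an explicit seed; a single global
seed is expanded into independent per-component streams via
`SeedSequence([seed, crc32(tag)])`, so enabling or disabling one test never
alters another's randomness, and repeated runs are byte-identical.
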