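# Methods

## Model and statistic

The test targets features where a subset of cases shows consistent extreme
values ("aberration enrichment") rather than a broad group difference.  Let
`x_1..x_n` be one feature's measurements with binary labels (`n1` cases,
`n0` controls).  Weights are absolute pooled z-scores floored at 0.5:

    w_i = max(|x_i − mean(x)| / sd(x), 0.5),

with mean and sd (ddof = 1) over all samples.  Pooling keeps the weights a
function of the values alone, so they are fixed under label permutation;
this both preserves exchangeability and allows all per-rank quantities to be
precomputed once per direction (a diagnostic with control-only
standardization produced indistinguishable statistics on the simulation
designs below).  The 0.5 floor keeps near-mean samples contributing, so the
walk is a rank walk modulated — not dominated — by effect size.

Samples are sorted by value (descending for the `high_in_cases` direction,
ascending for `low_in_cases`; ties broken by original sample index so
discrete features are reproducible).  The running score

    S_k = (1/n1) Σ_{i≤k} w_(i) X_(i) − (1/n0) Σ_{i≤k} w_(i) (1 − X_(i))

rises at cases and falls at controls.  Under uniformly random assignment of
the `n1` case labels to ranks, `E[S_k] = 0` for every `k` and

    Var_k = (n Σ_{i≤k} w_(i)² − W_k²) / (n1 n0 (n − 1)),

which follows from sampling-without-replacement covariances
(`Cov(X_i, X_j) = −n1 n0 / (n²(n−1))` for `i ≠ j`) and is exact — the unit
tests verify it against exhaustive enumeration at `n ≤ 8` to 1e−12 and
against 1e5 Monte-Carlo permutations at larger `n` to 2%.  The statistic is

    T = max over usable k of  S_k / √Var_k,

maximized over both directions (ties resolved to `high_in_cases`).
Positions with `Var_k = 0` (only `k = n`, and only when all weights are
equal) are excluded.  The signed maximum is used rather than `|Z_k|`: a
strongly negative prefix indicates case *depletion* at that end, which the
opposite-direction run captures, so taking the signed maximum in each
direction avoids counting the same pattern twice.

No closed form for the null distribution of `T` is attempted (the maximum
of dependent standardized hypergeometric-flavoured variables does not match
standard families); permutation is the contract.

### Interpretation of k\* and r̂

From the maximizing prefix (ranks `1..k*`) the package reports

    r̂ = max(0, prefix_cases/n1 − prefix_controls/n0),

an estimate of the proportion of cases carrying the aberration: the control
prefix fraction subtracts the background rate of aberrant values also seen
in controls, and the floor at 0 covers prefixes where controls dominate.
Both raw counts are exposed alongside so the undifferenced case fraction can
be read off too.  The value at rank `k*` bounds the *aberrant interval*
(inclusive); `transform_feature` zeroes all samples outside it, a non-linear
reduction that lets linear classifiers exploit heterogeneous markers.

Two caveats.  First, r̂ is mildly biased low in simulations (by ~0.01–0.03
at r = 0.1–0.3, d = 3, 500/arm) because the weakest aberrant cases fall
below the maximizing cut.  Second, when the signal is a broad weighted
enrichment rather than a compact subgroup, the maximum can land near the end
of the walk (`k* ≈ n`, where the standardized endpoint behaves like a
weighted-sum statistic); the p-value remains calibrated — the permutation
null includes those positions — but `r̂` then describes a small *excess*
over a large prefix and should not be read as a subgroup size.

## Significance

`p = (1 + #{T_perm ≥ T_obs}) / (1 + B)`.  The add-one estimator never
returns 0 and satisfies `P(p ≤ α) ≤ α` under the null.  Permutations
reassign case labels uniformly over ranks with weights and orderings fixed,
in geometrically growing batches (256, 512, …, capped at 2²⁰); in adaptive
mode the run stops at the first batch boundary with at least
`min_exceedances = 25` exceedances, at which point the relative Monte-Carlo
error of p̂ is ≈ 20% and the feature cannot be significant at screening
thresholds.  Stopping at batch boundaries overshoots the sequential stopping
time, which keeps the estimator's null distribution close to uniform (the
calibration test checks rejection at 0.05 and a KS test of uniformity over
2000 null features).  Exhaustive mode enumerates all `C(n, n1)` label
arrangements (refused above 1e6) and reports the exact unshifted fraction.

Permuted statistics tied with the observed one (within 1e−9 relative) count
as exceedances — the conservative side.  The inner loop is a numba kernel;
random subsets come from an inline splitmix64-seeded xorshift64 partial
Fisher–Yates, validated against the exact enumeration p on small instances.
Per-feature streams in matrix screens are spawned from the master seed keyed
by feature index, so results are independent of evaluation order.  Constant
features (detected by zero range, which is robust to floating-point drift in
the mean) are reported as degenerate with p = 1.

Multiple testing uses Benjamini–Hochberg or Bonferroni via statsmodels.

## Comparators

All comparators share the single-feature interface and return two-sided
p-values.  t (Welch), Wilcoxon rank-sum (tie-corrected normal
approximation), two-sample KS, ANOVA and the logistic-regression
likelihood-ratio test come from scipy/statsmodels.  Levene defaults to the
median-centered Brown–Forsythe variant (the common software default; the
mean center is exposed).  The moderated-t family is represented by the plain
Welch t-test, which is equivalent at the benchmark sample sizes (n ≥ 200).

COPA: values centered by the pooled median and scaled by the pooled MAD;
statistic = q-th quantile of transformed case values (q ∈ {0.75, 0.9,
0.95}), low tail via negation, two-sided = max; label-permutation p with the
add-one correction.  Outlier-sum: same transform; outliers are values beyond
`q75 + IQR` (resp. `q25 − IQR`), statistic = sum of case outliers, two-sided
= max of the two tails with the null built on the same max.  Fisher
combination: `−2(ln p_t + ln p_levene)` against chi-squared with 4 df — the
components are dependent, which makes the combination anticonservative (the
genome benchmark reproduces its inflated false discovery proportion).
2-means baseline: deterministic 1-D Lloyd iteration initialised at the two
extreme values, then a 2×2 chi-squared without continuity correction.
Matrix-wide screens share one permutation stream across features, which is
valid per feature and pairs the methods for comparison.

## Simulation designs

**Single feature.**  `n0` controls and `n1` cases drawn i.i.d. from a base
family with mean `m` and sd `s` (Gaussian by default; Student-t (df > 2) and
a log-normal with log-sd 0.5, both rescaled to mean `m` / sd `s`, provide
heavy-tailed and skewed stand-ins).  Exactly `round(r·n1)` cases — a
deterministic count, so ground truth is exact — are shifted by `d·s` in one
direction.  Scale/location of the base family provably do not affect the
test (invariance is a property test), so `m = 0, s = 1` everywhere.

**Genome-wide.**  Each replicate resamples whole sample profiles (columns)
with replacement from a healthy-control backbone — preserving inter-feature
correlation — adds N(0, δ²) noise, downsizes to `n_genes = 1000` random
features, and perturbs `g = 10` random features in `round(r·n)` random cases
by `d` times that feature's backbone standard deviation (computed before
noise), with a random per-feature direction.  Defaults `r = 0.1, d = 2,
δ = 0.01, g = 10` and 600 samples per arm.  The bundled synthetic backbone
(238 samples × 4000 features by default) is a shared-factor multivariate
Student-t model: one latent factor giving pairwise feature correlation ≈ 0.3,
a per-sample chi-squared mixing variable giving t marginals with 10 df
(heavier-tailed than Gaussian, as microarray intensities are), and
heterogeneous per-feature means (U(5,12)) and sds (U(0.2,2)).  It emulates
the correlation, tail weight and scale heterogeneity of real expression
panels but not probe-level artefacts, batch structure, or biological
pathway geometry — so benchmark results on it establish method *orderings*
and calibration, not absolute power transferable to any particular dataset.

**Harnesses.**  Power runs repeat a scenario (default 200 times) with all
methods paired on identical datasets; a signal counts as *detected* at a
threshold when the p-value beats it in more than half the repeats
(equivalently, the median p is below it — the cheaper audit).  Thresholds
0.05 (nominal) and 2×10⁻⁶ (a Bonferroni-scale expression-wide cut) are the
defaults.  The FDR harness thresholds BH-adjusted p-values at 0.1 per
method and reports mean recovered-spike fraction and mean false discovery
proportion.

## Numerical choices and problem sizes

* Zero-variance walk positions are masked by a relative threshold
  (`Var_k ≤ 1e−9 · max Var`), which separates the analytic zero at `k = n`
  from genuine small variances.
* Detection of the 2×10⁻⁶ threshold uses `B = 5·10⁵` permutations with
  `min_exceedances = 1`: any exceedance already forces p̂ ≥ 2/(B+1) >
  2×10⁻⁶, so the detection decision equals that of a full run at a fraction
  of the cost.
* Desk-scale sizes: calibration uses 2000 null features at 100/arm;
  regime checks 200 repeats per cell; r̂ recovery 200 repeats per r at
  500/arm; the genome benchmark 12 replicates of 1000 features at 600/arm
  with a 2·10⁴ permutation budget (BH at 0.1 over 1000 features needs p
  resolution of 1e−4, which that budget provides).  `scripts/acceptance.py`
  uses slightly smaller sizes (30 power repeats, 4 genome replicates) and
  states each size in its output.
* All randomness flows from explicit seeds through `numpy.random.SeedSequence`
  spawning; no global RNG state is used anywhere.

## Known limitations

* The test is label-asymmetric by design (it looks for aberrations enriched
  in *cases*); swapping labels changes the question and generally the answer.
* p-values are bounded below by 1/(B+1); screens needing very small
  Bonferroni thresholds must raise the permutation budget accordingly.
* Covariate handling is a plain linear residualizer; hidden-factor removal
  (PEER-style) is expected upstream, and confounders acting on the variance
  rather than the mean are not removed by either.
* COPA and Outlier-sum inherit their sensitivity to tail weight from their
  fixed outlier definitions; their benchmark performance on the heavy-tailed
  backbone degrades accordingly, which is part of what the benchmark is
  designed to show.
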