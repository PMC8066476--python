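"""Benchmark roster: classical two-group tests and outlier-based methods.

Every method maps one feature (values + binary labels) to a two-sided
p-value.  Classical tests delegate to scipy/statsmodels; COPA, Outlier-sum,
and the 2-means baseline are implemented here because no maintained
implementation exists in the scientific Python stack.  The empirical-Bayes
moderated t-test is represented by the plain Welch t-test, which is its
designated stand-in at the sample sizes these benchmarks use.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import scipy.stats as ss
import statsmodels.api as sm

from . import _perm
from .walk import (
    DegenerateFeatureError,
    InsufficientSamplesError,
    LabeledSampleSet,
)

__all__ = [
    "CLASSICAL_METHODS",
    "METHOD_IDS",
    "classical_test",
    "copa_test",
    "outlier_sum_test",
    "fisher_combination_test",
    "kmeans_chi2_test",
    "feature_pvalue",
    "matrix_pvalues",
]

CLASSICAL_METHODS = ("t_test", "wilcoxon", "ks", "levene", "logistic_lrt", "anova")

#: methods accepted by :func:`feature_pvalue` / :func:`matrix_pvalues`
METHOD_IDS = (
    "aberration",
    *CLASSICAL_METHODS,
    "copa75",
    "copa9",
    "copa95",
    "outlier_sum",
    "fisher_combination",
    "kmeans_chi2",
)


def _split(sample_set: LabeledSampleSet) -> tuple[np.ndarray, np.ndarray]:
    mask = sample_set.labels.astype(bool)
    return sample_set.values[mask], sample_set.values[~mask]


def _require_group_sizes(sample_set: LabeledSampleSet, method: str, k: int) -> None:
    if sample_set.n1 < k or sample_set.n0 < k:
        raise InsufficientSamplesError(
            f"{method} requires at least {k} cases and {k} controls"
        )


def classical_test(
    sample_set: LabeledSampleSet,
    method: str,
    levene_center: str = "median",
) -> float:
    """Two-sided p-value from a standard two-group test.

    ``levene`` defaults to the median-centered (Brown-Forsythe) variant.
    ``logistic_lrt`` is the likelihood-ratio test of the single feature in a
    logistic regression of the labels; it and ``anova`` are numerically
    equivalent in significance to the t-test on near-Gaussian features.
    """
    _require_group_sizes(sample_set, method, 2)
    cases, controls = _split(sample_set)
    if method == "t_test":
        return float(ss.ttest_ind(cases, controls, equal_var=False).pvalue)
    if method == "wilcoxon":
        return float(
            ss.mannwhitneyu(cases, controls, method="asymptotic").pvalue
        )
    if method == "ks":
        return float(ss.ks_2samp(cases, controls).pvalue)
    if method == "levene":
        return float(ss.levene(cases, controls, center=levene_center).pvalue)
    if method == "anova":
        return float(ss.f_oneway(cases, controls).pvalue)
    if method == "logistic_lrt":
        return _logistic_lrt(sample_set)
    raise ValueError(f"unknown classical method: {method!r}")


def _logistic_lrt(sample_set: LabeledSampleSet) -> float:
    x = sample_set.values
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateFeatureError("feature has zero variance")
    design = sm.add_constant((x - x.mean()) / sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(sample_set.labels, design)
        try:
            fit = model.fit(disp=0, maxiter=100)
        except Exception:
            fit = model.fit(disp=0, method="bfgs", maxiter=500)
    return float(fit.llr_pvalue)


def _median_mad_transform(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = ss.median_abs_deviation(values, scale="normal")
    if mad == 0:
        raise DegenerateFeatureError("median absolute deviation is zero")
    return (values - med) / mad


def _perm_case_indices(
    rng: np.random.Generator, chunk: int, n: int, n1: int
) -> np.ndarray:
    # indices of the n1 smallest iid uniforms per row = uniform n1-subset
    u = rng.random((chunk, n))
    return np.argpartition(u, n1 - 1, axis=1)[:, :n1]


def _stat_permutation_pvalue(
    stat_fn,
    n: int,
    n1: int,
    t_obs: float,
    b: int,
    seed: int | None,
    adaptive: bool,
    min_exceedances: int,
    exact: bool,
) -> float:
    """Label-permutation p for a case-set statistic, with +1/+1 correction.

    ``stat_fn`` maps a (B, n1) matrix of case sample-indices to statistics.
    ``exact=True`` enumerates all C(n, n1) case sets and returns the exact
    unshifted fraction.
    """
    threshold = _perm.exceedance_threshold(t_obs)
    if exact:
        total = comb(n, n1)
        if total > 10**6:
            raise ValueError(f"C({n}, {n1}) = {total} too large for exact mode")
        idx = np.array(list(combinations(range(n), n1)), dtype=np.int64)
        return float((stat_fn(idx) >= threshold).mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    used = 0
    for size in _perm.chunk_schedule(b):
        idx = _perm_case_indices(rng, size, n, n1)
        exceed += int((stat_fn(idx) >= threshold).sum())
        used += size
        if adaptive and exceed >= min_exceedances:
            break
    return (1 + exceed) / (1 + used)


def _copa_stat_fn(transformed: np.ndarray, q: float, two_sided: bool):
    def stat(case_idx: np.ndarray) -> np.ndarray:
        cv = transformed[case_idx]
        if not two_sided:
            return np.quantile(cv, q, axis=1)
        # q-quantile of -x equals -(1-q)-quantile of x (linear interpolation)
        both = np.quantile(cv, [q, 1.0 - q], axis=1)
        return np.maximum(both[0], -both[1])

    return stat


def copa_test(
    sample_set: LabeledSampleSet,
    q: float = 0.95,
    b: int = 10_000,
    seed: int | None = None,
    two_sided: bool = True,
    adaptive: bool = True,
    min_exceedances: int = 25,
    exact: bool = False,
) -> float:
    """Cancer-outlier profile analysis: a case-quantile statistic.

    Values are centered by the pooled median and scaled by the pooled MAD;
    the statistic is the q-th quantile of the transformed case values (the
    low tail uses the same quantile of the negated values; two-sided takes
    the larger).  Significance is by case/control label permutation.
    """
    if not 0.5 < q < 1:
        raise ValueError("copa quantile must lie in (0.5, 1)")
    _require_group_sizes(sample_set, "copa", 2)
    t = _median_mad_transform(sample_set.values)
    stat_fn = _copa_stat_fn(t, q, two_sided)
    case_idx = np.flatnonzero(sample_set.labels)[None, :]
    t_obs = float(stat_fn(case_idx)[0])
    return _stat_permutation_pvalue(
        stat_fn, sample_set.n, sample_set.n1, t_obs, b, seed,
        adaptive, min_exceedances, exact,
    )


def _outlier_sum_stat_fn(transformed: np.ndarray, two_sided: bool):
    q25, q75 = np.percentile(transformed, [25, 75])
    iqr = q75 - q25
    hi_thr = q75 + iqr
    lo_thr = q25 - iqr

    def stat(case_idx: np.ndarray) -> np.ndarray:
        cv = transformed[case_idx]
        hi = np.where(cv > hi_thr, cv, 0.0).sum(axis=1)
        if not two_sided:
            return hi
        lo = np.where(cv < lo_thr, -cv, 0.0).sum(axis=1)
        return np.maximum(hi, lo)

    return stat


def outlier_sum_test(
    sample_set: LabeledSampleSet,
    b: int = 10_000,
    seed: int | None = None,
    two_sided: bool = True,
    adaptive: bool = True,
    min_exceedances: int = 25,
    exact: bool = False,
) -> float:
    """Outlier-sum test: sum of case values beyond an IQR-based threshold.

    Values are median/MAD standardized over all samples; outliers are values
    beyond ``q75 + IQR`` (high tail) or ``q25 - IQR`` (low tail, negated);
    two-sided takes the larger of the two sums.  Significance is by label
    permutation with the +1/+1 correction.
    """
    _require_group_sizes(sample_set, "outlier_sum", 2)
    t = _median_mad_transform(sample_set.values)
    stat_fn = _outlier_sum_stat_fn(t, two_sided)
    case_idx = np.flatnonzero(sample_set.labels)[None, :]
    t_obs = float(stat_fn(case_idx)[0])
    if t_obs == 0.0:
        # no case outlier in either tail: every permutation ties or beats it
        return 1.0
    return _stat_permutation_pvalue(
        stat_fn, sample_set.n, sample_set.n1, t_obs, b, seed,
        adaptive, min_exceedances, exact,
    )


def fisher_combination_test(
    sample_set: LabeledSampleSet, levene_center: str = "median"
) -> float:
    """Joint scale-location test: Fisher combination of t and Levene.

    ``X^2 = -2 (ln p_t + ln p_levene)`` referred to chi-squared with 4 df.
    The two component tests are not independent, which is why this
    combination is anticonservative on null data.
    """
    p_t = classical_test(sample_set, "t_test")
    p_l = classical_test(sample_set, "levene", levene_center=levene_center)
    x2 = -2.0 * (np.log(p_t) + np.log(p_l))
    return float(ss.chi2.sf(x2, df=4))


def _two_means_1d(values: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Deterministic 1-D Lloyd iteration initialised at the two extremes."""
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise DegenerateFeatureError("all values identical")
    c0, c1 = float(lo), float(hi)
    assign = values > (c0 + c1) / 2
    for _ in range(200):
        m0 = values[~assign]
        m1 = values[assign]
        if m0.size == 0 or m1.size == 0:  # guard; extreme-point init fills both
            rng = rng or np.random.default_rng(0)
            c0, c1 = np.sort(rng.choice(values, 2, replace=False))
            assign = values > (c0 + c1) / 2
            continue
        c0, c1 = m0.mean(), m1.mean()
        new = values > (c0 + c1) / 2
        if np.array_equal(new, assign):
            break
        assign = new
    return assign


def kmeans_chi2_test(
    sample_set: LabeledSampleSet, seed: int | None = None
) -> float:
    """Clustering baseline: 1-D 2-means then a 2x2 chi-squared test.

    Tests whether cluster membership is associated with case/control status
    (no continuity correction).  Low power when affected cases form a heavy
    tail rather than a separate mode.
    """
    if sample_set.n < 4 or np.unique(sample_set.values).size < 2:
        raise DegenerateFeatureError("need n >= 4 with at least 2 distinct values")
    assign = _two_means_1d(sample_set.values, np.random.default_rng(seed))
    table = np.array(
        [
            [np.sum(~assign & (sample_set.labels == 0)),
             np.sum(~assign & (sample_set.labels == 1))],
            [np.sum(assign & (sample_set.labels == 0)),
             np.sum(assign & (sample_set.labels == 1))],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 1.0
    return float(ss.chi2_contingency(table, correction=False).pvalue)


def feature_pvalue(
    values,
    labels,
    method: str,
    seed: int | None = None,
    perm_budget: int = 10_000,
    min_exceedances: int = 25,
    adaptive: bool = True,
) -> float:
    """Uniform single-feature interface over the full method roster."""
    from .significance import permutation_pvalue  # local: avoid cycle

    sset = LabeledSampleSet(np.asarray(values), np.asarray(labels))
    try:
        if method == "aberration":
            return permutation_pvalue(
                sset,
                b_max=perm_budget,
                adaptive=adaptive,
                min_exceedances=min_exceedances,
                seed=seed,
            ).p_value
        if method in CLASSICAL_METHODS:
            return classical_test(sset, method)
        if method in ("copa75", "copa9", "copa95"):
            q = {"copa75": 0.75, "copa9": 0.9, "copa95": 0.95}[method]
            return copa_test(
                sset, q=q, b=perm_budget, seed=seed,
                adaptive=adaptive, min_exceedances=min_exceedances,
            )
        if method == "outlier_sum":
            return outlier_sum_test(
                sset, b=perm_budget, seed=seed,
                adaptive=adaptive, min_exceedances=min_exceedances,
            )
        if method == "fisher_combination":
            return fisher_combination_test(sset)
        if method == "kmeans_chi2":
            return kmeans_chi2_test(sset, seed=seed)
    except DegenerateFeatureError:
        return 1.0
    raise ValueError(f"unknown method: {method!r}")


def _screen_quantile_method(
    values: np.ndarray,
    labels: np.ndarray,
    method: str,
    b_max: int,
    seed: int | None,
    min_exceedances: int,
) -> np.ndarray:
    """Matrix-wide COPA / Outlier-sum screen sharing permutations.

    One stream of permuted case-index chunks is reused across features
    (valid per feature; it also pairs the features for comparisons), and
    features whose p-value is already resolved drop out after each chunk.
    """
    n = labels.size
    n1 = int(labels.sum())
    case_idx_obs = np.flatnonzero(labels)[None, :]
    stat_fns = []
    t_obs = np.empty(values.shape[0])
    degenerate = np.zeros(values.shape[0], dtype=bool)
    for i in range(values.shape[0]):
        try:
            t = _median_mad_transform(values[i])
        except DegenerateFeatureError:
            stat_fns.append(None)
            degenerate[i] = True
            t_obs[i] = 0.0
            continue
        if method == "outlier_sum":
            fn = _outlier_sum_stat_fn(t, True)
        else:
            q = {"copa75": 0.75, "copa9": 0.9, "copa95": 0.95}[method]
            fn = _copa_stat_fn(t, q, True)
        stat_fns.append(fn)
        t_obs[i] = fn(case_idx_obs)[0]
    thresholds = t_obs - 1e-9 * np.maximum(1.0, np.abs(t_obs))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[0], dtype=np.int64)
    used = np.zeros(values.shape[0], dtype=np.int64)
    active = ~degenerate
    for size in _perm.chunk_schedule(b_max):
        if not active.any():
            break
        idx = _perm_case_indices(rng, size, n, n1)
        for i in np.flatnonzero(active):
            exceed[i] += int((stat_fns[i](idx) >= thresholds[i]).sum())
            used[i] += size
        active &= exceed < min_exceedances
    p = (1 + exceed) / (1 + used)
    p[degenerate] = 1.0
    # zero observed outlier-sum means no case outlier at all: p = 1
    if method == "outlier_sum":
        p[t_obs == 0.0] = 1.0
    return p


def matrix_pvalues(
    values,
    labels,
    method: str,
    seed: int | None = None,
    perm_budget: int = 10_000,
    min_exceedances: int = 25,
) -> np.ndarray:
    """Per-feature p-values for one method over a features x samples matrix.

    Vectorised where scipy supports it; permutation methods share one
    permutation stream across features.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    mask = labels.astype(bool)
    cases, controls = values[:, mask], values[:, ~mask]
    if method == "aberration":
        from .significance import test_matrix

        return test_matrix(
            values, labels, b_max=perm_budget,
            min_exceedances=min_exceedances, seed=seed,
        )["p_value"].to_numpy()
    if method == "t_test":
        return np.asarray(ss.ttest_ind(cases, controls, axis=1, equal_var=False).pvalue)
    if method == "anova":
        return np.asarray(ss.f_oneway(cases, controls, axis=1).pvalue)
    if method == "wilcoxon":
        return np.asarray(ss.mannwhitneyu(cases, controls, axis=1, method="asymptotic").pvalue)
    if method in ("copa75", "copa9", "copa95", "outlier_sum"):
        return _screen_quantile_method(
            values, labels, method, perm_budget, seed, min_exceedances
        )
    out = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        out[i] = feature_pvalue(values[i], labels, method, seed=seed)
    return out
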