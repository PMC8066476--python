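"""Comparator roster: correctness, oracles, and calibration."""

import shutil
import subprocess

import numpy as np
import pytest
import scipy.stats as ss

from abenrich import (
    DegenerateFeatureError,
    InsufficientSamplesError,
    LabeledSampleSet,
    classical_test,
    copa_test,
    feature_pvalue,
    fisher_combination_test,
    kmeans_chi2_test,
    matrix_pvalues,
    outlier_sum_test,
)

R_SCRIPT = """
args <- commandArgs(trailingOnly = TRUE)
d <- read.table(args[1], header = TRUE, sep = "\\t")
suppressMessages(library(car))
out <- NULL
for (i in unique(d$dataset)) {
  di <- d[d$dataset == i, ]
  x <- di$value[di$group == 1]; y <- di$value[di$group == 0]
  g <- factor(di$group)
  m1 <- glm(g ~ di$value, family = binomial)
  m0 <- glm(g ~ 1, family = binomial)
  out <- rbind(out, data.frame(
    dataset = i,
    t_test = t.test(x, y)$p.value,
    wilcoxon = wilcox.test(x, y, exact = FALSE, correct = TRUE)$p.value,
    ks = ks.test(x, y)$p.value,
    levene = leveneTest(di$value, g, center = median)[1, 3],
    anova = oneway.test(di$value ~ g, var.equal = TRUE)$p.value,
    logistic_lrt = pchisq(m0$deviance - m1$deviance, 1, lower.tail = FALSE)
  ))
}
write.table(format(out, digits = 15), args[2], sep = "\\t",
            row.names = FALSE, quote = FALSE)
"""


def _make_set(rng, n1=12, n0=14, shift=0.0, scale=1.0):
    values = np.concatenate(
        [rng.normal(shift, scale, n1), rng.normal(0, 1, n0)]
    )
    labels = np.array([1] * n1 + [0] * n0, dtype=np.int8)
    return LabeledSampleSet(values, labels)


class TestClassical:
    def test_t_textbook_example(self):
        sset = LabeledSampleSet(
            np.array([1.0, 2, 3, 4, 5, 6]), np.array([1, 1, 1, 0, 0, 0])
        )
        # equal group variances: Welch coincides with the pooled t here
        assert classical_test(sset, "t_test") == pytest.approx(0.021312, abs=2e-5)

    def test_identical_groups_p_one(self):
        sset = LabeledSampleSet(
            np.array([1.0, 2, 3, 1, 2, 3]), np.array([1, 1, 1, 0, 0, 0])
        )
        assert classical_test(sset, "t_test") == pytest.approx(1.0)

    def test_group_size_preconditions(self):
        sset = LabeledSampleSet(np.array([1.0, 2, 3]), np.array([1, 0, 0]))
        with pytest.raises(InsufficientSamplesError, match="at least 2"):
            classical_test(sset, "t_test")

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError):
            classical_test(_make_set(rng), "median_test")

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_r_reference(self, rng, tmp_path):
        """All six classical tests agree with R to 6 significant digits on
        50 random fixed inputs."""
        rows = []
        sets = []
        for i in range(50):
            n1 = int(rng.integers(8, 25))
            n0 = int(rng.integers(8, 25))
            sset = _make_set(rng, n1, n0, shift=rng.normal(0, 0.8),
                             scale=rng.uniform(0.5, 2.0))
            sets.append(sset)
            for v, g in zip(sset.values, sset.labels):
                rows.append(f"{i}\t{v:.17g}\t{g}")
        data = tmp_path / "data.tsv"
        data.write_text("dataset\tvalue\tgroup\n" + "\n".join(rows) + "\n")
        script = tmp_path / "ref.R"
        script.write_text(R_SCRIPT)
        out = tmp_path / "out.tsv"
        subprocess.run(
            ["Rscript", str(script), str(data), str(out)],
            check=True, capture_output=True,
        )
        import pandas as pd

        ref = pd.read_csv(out, sep="\t").set_index("dataset")
        for i, sset in enumerate(sets):
            for method in ("t_test", "wilcoxon", "ks", "levene", "anova",
                           "logistic_lrt"):
                ours = classical_test(sset, method)
                theirs = float(ref.loc[i, method])
                assert ours == pytest.approx(theirs, rel=1e-6), (i, method)

    def test_mean_family_equivalence(self, rng):
        """Logistic LRT, ANOVA and t produce matching significance order."""
        pvals = {m: [] for m in ("t_test", "anova", "logistic_lrt")}
        for _ in range(12):
            sset = _make_set(rng, 20, 20, shift=rng.normal(0, 0.6))
            for m in pvals:
                pvals[m].append(classical_test(sset, m))
        order_t = np.argsort(pvals["t_test"])
        for m in ("anova", "logistic_lrt"):
            assert np.array_equal(np.argsort(pvals[m]), order_t)

    def test_null_calibration(self, rng):
        reps, alpha = 400, 0.05
        for method in ("t_test", "wilcoxon", "levene"):
            rejected = sum(
                classical_test(_make_set(rng, 15, 15), method) < alpha
                for _ in range(reps)
            )
            lo, hi = ss.binom.interval(0.999, reps, alpha)
            assert lo <= rejected <= hi, method


class TestFisherCombination:
    def test_no_evidence(self):
        sset = LabeledSampleSet(
            np.array([1.0, 2, 3, 1, 2, 3]), np.array([1, 1, 1, 0, 0, 0])
        )
        # t gives exactly 1; combined p stays near 1
        assert fisher_combination_test(sset) > 0.5

    def test_hand_computed_tail(self):
        x2 = -2 * (np.log(0.05) + np.log(0.05))
        assert x2 == pytest.approx(11.98, abs=0.01)
        assert ss.chi2.sf(x2, 4) == pytest.approx(0.0175, abs=2e-4)


class TestKMeans:
    def test_separated_clusters(self):
        sset = LabeledSampleSet(
            np.array([10.0, 11, 12, 0, 1, 2]), np.array([1, 1, 1, 0, 0, 0])
        )
        # contingency [[3,0],[0,3]]: X2 = 6, p = P(chi2_1 > 6)
        assert kmeans_chi2_test(sset) == pytest.approx(0.0143, abs=2e-4)

    def test_constant_values_degenerate(self):
        sset = LabeledSampleSet(
            np.array([1.0, 1, 1, 1]), np.array([1, 1, 0, 0])
        )
        with pytest.raises(DegenerateFeatureError):
            kmeans_chi2_test(sset)

    def test_null_bimodal_calibrated(self, rng):
        reps = 400
        rejected = 0
        for _ in range(reps):
            values = np.concatenate([rng.normal(0, 1, 15), rng.normal(6, 1, 15)])
            rng.shuffle(values)
            labels = np.zeros(30, dtype=np.int8)
            labels[rng.choice(30, 15, replace=False)] = 1
            rejected += kmeans_chi2_test(LabeledSampleSet(values, labels)) < 0.05
        lo, hi = ss.binom.interval(0.999, reps, 0.05)
        assert lo <= rejected <= hi


class TestCopa:
    def test_cases_at_median_zero_statistic(self):
        values = np.array([5.0, 5, 5, 1, 2, 8, 9, 4.5, 5.5, 5])
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert np.all(values[labels == 1] == np.median(values))
        p = copa_test(LabeledSampleSet(values, labels), q=0.9, b=500, seed=0)
        assert p > 0.5

    def test_exact_matches_sampled(self, rng):
        values = np.concatenate([rng.normal(2, 1, 4), rng.normal(0, 1, 4)])
        labels = np.array([1] * 4 + [0] * 4, dtype=np.int8)
        sset = LabeledSampleSet(values, labels)
        exact = copa_test(sset, q=0.9, exact=True)
        b = 20_000
        sampled = copa_test(sset, q=0.9, b=b, seed=1, adaptive=False)
        se = np.sqrt(exact * (1 - exact) / b)
        assert abs(sampled - exact) < 3 * se + 2 / b

    def test_quantile_bounds(self, rng):
        with pytest.raises(ValueError):
            copa_test(_make_set(rng), q=0.4)

    def test_mad_zero_degenerate(self):
        values = np.array([3.0] * 7 + [9.0, 10.0, 11.0])
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1, 1, 0])
        with pytest.raises(DegenerateFeatureError):
            copa_test(LabeledSampleSet(values, labels))


class TestOutlierSum:
    def test_no_outliers_p_one(self, rng):
        values = np.linspace(0, 1, 16)
        labels = np.tile([1, 0], 8)
        assert outlier_sum_test(LabeledSampleSet(values, labels), b=200) == 1.0

    def test_single_extreme_case_exact_p(self, rng):
        """With one huge case value, the exact p is the chance that sample
        is labeled a case: n1 / n."""
        n, n1 = 20, 6
        values = np.concatenate([np.linspace(0.0, 1.0, n - 1), [40.0]])
        labels = np.zeros(n, dtype=np.int8)
        labels[[19, 0, 2, 4, 6, 8]] = 1
        sset = LabeledSampleSet(values, labels)
        p = outlier_sum_test(sset, exact=True)
        assert p == pytest.approx(n1 / n)

    def test_exact_matches_sampled(self, rng):
        values = np.concatenate([rng.normal(0, 1, 5), [6.0], rng.normal(0, 1, 4)])
        labels = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 1], dtype=np.int8)
        sset = LabeledSampleSet(values, labels)
        exact = outlier_sum_test(sset, exact=True)
        b = 20_000
        sampled = outlier_sum_test(sset, b=b, seed=2, adaptive=False)
        se = np.sqrt(exact * (1 - exact) / b)
        assert abs(sampled - exact) < 3 * se + 2 / b

    def test_null_heavy_tail_calibrated(self, rng):
        reps = 300
        rejected = 0
        for _ in range(reps):
            values = rng.standard_t(3, 30)
            labels = np.zeros(30, dtype=np.int8)
            labels[rng.choice(30, 15, replace=False)] = 1
            p = outlier_sum_test(
                LabeledSampleSet(values, labels), b=400, seed=int(rng.integers(2**31))
            )
            rejected += p < 0.05
        assert rejected <= ss.binom.interval(0.999, reps, 0.05)[1]


class TestDispatch:
    def test_feature_pvalue_covers_roster(self, rng):
        sset = _make_set(rng, 15, 15)
        for method in ("aberration", "t_test", "wilcoxon", "ks", "levene",
                       "logistic_lrt", "anova", "copa75", "copa9", "copa95",
                       "outlier_sum", "fisher_combination", "kmeans_chi2"):
            p = feature_pvalue(sset.values, sset.labels, method, seed=0,
                               perm_budget=500)
            assert 0 < p <= 1, method

    def test_degenerate_maps_to_p_one(self):
        p = feature_pvalue(np.ones(10), np.tile([1, 0], 5), "aberration")
        assert p == 1.0

    def test_matrix_pvalues_match_single_feature(self, rng):
        values = rng.normal(size=(6, 40))
        labels = np.tile([1, 0], 20)
        for method in ("t_test", "anova", "wilcoxon", "ks", "levene"):
            batch = matrix_pvalues(values, labels, method)
            single = [
                feature_pvalue(values[i], labels, method) for i in range(6)
            ]
            np.testing.assert_allclose(batch, single, rtol=1e-9)

    def test_matrix_screen_copa_outlier_sum(self, rng):
        values = rng.normal(size=(8, 60))
        values[2, :5] += 8.0  # strong case outliers (cases are even columns)
        labels = np.tile([1, 0], 30)
        values[2, labels == 0] = rng.normal(size=30)  # keep spike in cases
        values[2, np.flatnonzero(labels)[:6]] += 8.0
        for method in ("copa95", "outlier_sum"):
            p = matrix_pvalues(values, labels, method, seed=0, perm_budget=4000)
            assert p.shape == (8,)
            assert p[2] == p.min()
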