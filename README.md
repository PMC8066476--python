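# abenrich — aberration-enrichment testing for case/control omics data

Classical two-group tests (t, Wilcoxon, Levene, Kolmogorov–Smirnov, limma-style
moderated tests) look for a *broad* difference between cases and controls: a
shift in mean, median or variance affecting most samples.  Many disease
signals do not look like that.  In complex disease, a causal gene is often
dysregulated in only a small fraction of patients — 10% of cases with an
extreme expression value, against 1% of controls — while the remaining cases
are indistinguishable from controls.  `abenrich` implements a statistical
test designed for exactly this *aberration enrichment* (heterogeneous-effect)
pattern, for gene/miRNA expression, DNA methylation residuals, or any other
continuous feature matrix with binary labels.

## The statistic

For one feature with values `x_i`, case indicator `X_i` (`n1` cases, `n0`
controls, `n = n1 + n0`), samples are ranked from most to least extreme in
the tested direction and a weighted running score is accumulated:

    S_k = (1/n1) Σ_{i≤k} w_i X_i  −  (1/n0) Σ_{i≤k} w_i (1 − X_i)

with weights `w_i = max(|z_i|, 0.5)`, the absolute pooled z-scores of the
measurement floored at 0.5, so larger aberrations push the walk harder.
Under the null that labels are assigned at random to ranks, `E[S_k] = 0` and

    Var_k = (n Σ_{i≤k} w_(i)² − W_k²) / (n1 · n0 · (n − 1)),   W_k = Σ_{i≤k} w_(i),

exactly (no approximation; validated in the test suite against brute-force
enumeration).  The test statistic is the maximum standardized score
`T = max_k S_k / √Var_k` over both ranking directions; significance comes
from label permutations with the add-one estimator
`p = (1 + #{T_perm ≥ T_obs}) / (1 + B)`, with adaptive early stopping so
screens over hundreds of thousands of features stay tractable.  From the
maximizing prefix (ranks `1..k*`) the package reports the estimated affected
proportion `r̂ = max(0, prefix cases/n1 − prefix controls/n0)` and the
boundary value of the aberrant interval.

The package also ships the comparator roster used to benchmark the test
(t/Welch, Wilcoxon, KS, Levene/Brown–Forsythe, logistic-regression LRT,
ANOVA, COPA, Outlier-sum, the t+Levene Fisher combination, a 2-means +
chi-squared baseline), simulators for single perturbed-Gaussian features and
genome-wide spiked matrices over a correlated heavy-tailed backbone, and
power / type-I / FDR harnesses.

## Worked example

Simulate 8 features where 15% of 150 cases carry a +3 sd aberration, screen
them, and read the results:

```sh
abenrich simulate -o expr.tsv --n1 150 --n0 150 --r 0.15 --d 3 \
    --features 8 --seed 11
abenrich test expr.tsv expr.tsv.labels.tsv -o results.tsv \
    --permutations 100000 --seed 11
```

`results.tsv` (abridged):

```
feature  statistic  p_value   p_bh     direction  k_star  r_hat
sim0000     4.7233   0.0000 0.0001 high_in_cases     274 0.0267
sim0001     4.5642   0.0000 0.0001 high_in_cases      21 0.1400
sim0003     4.9966   0.0000 0.0000 high_in_cases     251 0.1400
sim0005     4.3649   0.0002 0.0002 high_in_cases      19 0.1267
```

Every feature is significant after BH correction (`p_bh`).  `statistic` is
the maximal standardized enrichment score; `direction` says the aberrant
cases are *over*-expressed.  For `sim0001` the maximum occurs after 21
samples (`k_star`), a prefix containing 14% more of the cases than of the
controls (`r_hat ≈ 0.14`, matching the simulated 15%); all samples beyond
the boundary value belong to the aberrant interval, which
`abenrich transform` can use to zero out unaffected samples before
classification.  When `k_star` falls near the end of the walk (`sim0000`),
the signal resembles a broad weighted enrichment rather than a compact
aberrant subgroup, and `r_hat` is accordingly small.

The same screen is available in Python:

```python
from abenrich import LabeledSampleSet, permutation_pvalue
res = permutation_pvalue(LabeledSampleSet(values, labels), b_max=100_000, seed=0)
res.p_value, res.r_hat, res.direction
```

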