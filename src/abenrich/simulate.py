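"""Synthetic data generators and power / type-I / FDR benchmark harnesses.

Two designs are covered:

* a single perturbed feature — cases and controls drawn from a common
  distribution (Gaussian by default) with a proportion ``r`` of the cases
  shifted ``d`` standard deviations in one direction; and
* a genome-wide matrix — sample profiles resampled with replacement from a
  healthy-control backbone, light additive Gaussian noise, and ``g`` spiked
  features perturbed the same way.  A shared-factor Student-t backbone
  generator stands in for real expression data, reproducing heterogeneous
  per-feature scales, inter-feature correlation and heavier-than-Gaussian
  tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .comparators import feature_pvalue, matrix_pvalues
from .significance import adjust_pvalues
from .walk import Direction, LabeledSampleSet

__all__ = [
    "SimulationScenario",
    "GenomeSimConfig",
    "simulate_single",
    "power_experiment",
    "synthetic_backbone",
    "simulate_genomewide",
    "fdr_power_experiment",
    "DEFAULT_THRESHOLDS",
]

#: nominal and multiple-testing-scale detection thresholds
DEFAULT_THRESHOLDS = (0.05, 2e-6)

FAMILIES = ("gaussian", "student_t", "lognormal")


@dataclass(frozen=True)
class SimulationScenario:
    """Perturbed single-feature design.

    ``r`` is the proportion of cases carrying the aberration; exactly
    ``round(r * n1)`` cases are shifted by ``d * s`` in ``direction``.
    Non-Gaussian families are rescaled so the base distribution keeps mean
    ``m`` and standard deviation ``s`` (``student_t`` requires ``df > 2``;
    the lognormal uses log-sd 0.5 before rescaling).
    """

    n1: int = 500
    n0: int = 500
    r: float = 0.1
    m: float = 0.0
    s: float = 1.0
    d: float = 3.0
    direction: Direction = Direction.HIGH_IN_CASES
    family: str = "gaussian"
    df: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")
        if self.s <= 0 or self.d < 0:
            raise ValueError("require s > 0 and d >= 0")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "student_t" and self.df <= 2:
            raise ValueError("student_t family requires df > 2")

    @property
    def n_perturbed(self) -> int:
        return int(round(self.r * self.n1))


def _draw_base(
    rng: np.random.Generator, size: int, scenario: SimulationScenario
) -> np.ndarray:
    if scenario.family == "gaussian":
        std = rng.standard_normal(size)
    elif scenario.family == "student_t":
        std = rng.standard_t(scenario.df, size) / np.sqrt(
            scenario.df / (scenario.df - 2.0)
        )
    else:  # lognormal, standardized to mean 0 / sd 1
        sigma = 0.5
        raw = rng.lognormal(0.0, sigma, size)
        mu = np.exp(sigma**2 / 2)
        sd = np.sqrt((np.exp(sigma**2) - 1.0) * np.exp(sigma**2))
        std = (raw - mu) / sd
    return scenario.m + scenario.s * std


def simulate_single(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[LabeledSampleSet, np.ndarray]:
    """Draw one feature under ``scenario``.

    Returns the labeled sample set (cases first) and the indices of the
    perturbed cases (ground truth).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n_pert = scenario.n_perturbed
    if scenario.r > 0 and n_pert == 0:
        warnings.warn(
            f"r={scenario.r} with n1={scenario.n1} rounds to 0 perturbed "
            "cases; the scenario is effectively null",
            stacklevel=2,
        )
    values = _draw_base(rng, scenario.n1 + scenario.n0, scenario)
    labels = np.zeros(scenario.n1 + scenario.n0, dtype=np.int8)
    labels[: scenario.n1] = 1
    perturbed = rng.choice(scenario.n1, size=n_pert, replace=False)
    shift = scenario.d * scenario.s
    if Direction(scenario.direction) is Direction.LOW_IN_CASES:
        shift = -shift
    values[perturbed] += shift
    return LabeledSampleSet(values, labels), np.sort(perturbed)


def power_experiment(
    scenario: SimulationScenario,
    methods: list[str],
    reps: int = 200,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    seed: int | None = 0,
    perm_budget: int = 10_000,
    min_exceedances: int = 25,
) -> pd.DataFrame:
    """Rejection fractions and majority-rule detection flags per method.

    Every method sees the identical sequence of simulated datasets (paired
    comparison).  ``detected`` means the p-value beat the threshold in more
    than half of the repeats, which is equivalent to the median p being
    below the threshold.
    """
    children = np.random.SeedSequence(seed).spawn(reps)
    pvals = {m: np.empty(reps) for m in methods}
    for rep, child in enumerate(children):
        streams = child.spawn(len(methods) + 1)
        rng = np.random.default_rng(streams[0])
        sset, _ = simulate_single(scenario, rng)
        for j, method in enumerate(methods):
            mseed = int(streams[j + 1].generate_state(1, dtype=np.uint32)[0])
            pvals[method][rep] = feature_pvalue(
                sset.values,
                sset.labels,
                method,
                seed=mseed,
                perm_budget=perm_budget,
                min_exceedances=min_exceedances,
            )
    rows = []
    for method in methods:
        p = pvals[method]
        for thr in thresholds:
            rows.append(
                {
                    "method": method,
                    "threshold": thr,
                    "rejection_fraction": float((p < thr).mean()),
                    "detected": bool(np.median(p) < thr),
                    "mean_p": float(p.mean()),
                    "median_p": float(np.median(p)),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


def synthetic_backbone(
    samples: int,
    features: int,
    correlation: float = 0.3,
    tail_df: float = 10.0,
    seed: int | None = 0,
):
    """Healthy-control expression stand-in: correlated, heavy-tailed.

    A single shared factor induces pairwise feature correlation of about
    ``correlation``; a per-sample chi-squared mixing variable turns the
    Gaussian factor model into multivariate Student-t with ``tail_df``
    degrees of freedom (``tail_df = inf`` recovers Gaussian marginals).
    Features receive heterogeneous means and scales.  Returns a
    :class:`~abenrich.io.FeatureMatrix` (features x samples).
    """
    from .io import FeatureMatrix

    if samples < 2:
        raise ValueError("backbone requires at least 2 samples")
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    if not tail_df > 2.0:
        raise ValueError("tail_df must exceed 2 (or be inf)")
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(samples)
    eps = rng.standard_normal((features, samples))
    z = np.sqrt(correlation) * factor + np.sqrt(1.0 - correlation) * eps
    if np.isfinite(tail_df):
        mix = rng.chisquare(tail_df, samples) / tail_df
        z = z / np.sqrt(mix)
        z = z / np.sqrt(tail_df / (tail_df - 2.0))  # unit marginal variance
    means = rng.uniform(5.0, 12.0, features)
    sds = rng.uniform(0.2, 2.0, features)
    values = means[:, None] + sds[:, None] * z
    return FeatureMatrix(
        feature_ids=[f"g{i:05d}" for i in range(features)],
        sample_ids=[f"bb{j:05d}" for j in range(samples)],
        values=values,
    )


@dataclass(frozen=True)
class GenomeSimConfig:
    """Genome-wide spiked-matrix design.

    ``backbone`` may be a FeatureMatrix of healthy-control profiles; if
    None, a synthetic backbone with ``backbone_*`` parameters is generated.
    Each replicate downsizes to ``n_genes`` random features, resamples
    ``2 n`` whole sample profiles with replacement (preserving inter-feature
    correlation), adds N(0, delta^2) noise, and perturbs ``g`` random
    features in ``round(r * n)`` random cases by ``d`` times the feature's
    backbone standard deviation.
    """

    n: int = 600
    n_genes: int = 1000
    g: int = 10
    r: float = 0.1
    d: float = 2.0
    delta: float = 0.01
    reps: int = 1000
    fdr_level: float = 0.1
    backbone: object | None = None
    backbone_samples: int = 238
    backbone_features: int = 4000
    backbone_correlation: float = 0.3
    backbone_tail_df: float = 10.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.g > self.n_genes:
            raise ValueError("g must not exceed n_genes")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")


def _resolve_backbone(config: GenomeSimConfig):
    if config.backbone is not None:
        return config.backbone
    return synthetic_backbone(
        config.backbone_samples,
        config.backbone_features,
        config.backbone_correlation,
        config.backbone_tail_df,
        seed=np.random.SeedSequence((config.seed or 0, 0xB0E)).generate_state(1)[0],
    )


def simulate_genomewide(
    config: GenomeSimConfig, replicate_index: int = 0
) -> tuple[object, np.ndarray, list[str]]:
    """One spiked genome-wide replicate: (matrix, labels, spiked ids)."""
    from .io import FeatureMatrix

    backbone = _resolve_backbone(config)
    bvals = backbone.values_array
    if bvals.shape[1] < 2:
        raise ValueError("backbone must contain at least 2 samples")
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed or 0, 1, replicate_index))
    )
    gene_idx = rng.choice(bvals.shape[0], size=config.n_genes, replace=False)
    n_samples = 2 * config.n
    profile_idx = rng.integers(0, bvals.shape[1], size=n_samples)
    values = bvals[np.ix_(gene_idx, profile_idx)].copy()
    values += rng.normal(0.0, config.delta, size=values.shape)
    labels = np.zeros(n_samples, dtype=np.int8)
    labels[: config.n] = 1
    spiked_rows = rng.choice(config.n_genes, size=config.g, replace=False)
    feature_sds = bvals[gene_idx].std(axis=1, ddof=1)  # pre-noise backbone sd
    n_pert = int(round(config.r * config.n))
    for row in spiked_rows:
        hit_cases = rng.choice(config.n, size=n_pert, replace=False)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values[row, hit_cases] += sign * config.d * feature_sds[row]
    feature_ids = [backbone.feature_ids[i] for i in gene_idx]
    matrix = FeatureMatrix(
        feature_ids=feature_ids,
        sample_ids=[f"s{j:05d}" for j in range(n_samples)],
        values=values,
    )
    truth = [feature_ids[i] for i in sorted(spiked_rows)]
    return matrix, labels, truth


def fdr_power_experiment(
    config: GenomeSimConfig,
    methods: list[str],
    seed: int | None = None,
    perm_budget: int = 20_000,
) -> pd.DataFrame:
    """Spike recovery at a BH FDR threshold, per method.

    For each replicate every method is run on every feature and thresholded
    at BH-adjusted ``fdr_level``; power is the mean fraction of spiked
    features recovered, ``fdp`` the mean false discovery proportion
    (FP / max(1, positives)).
    """
    if seed is not None:
        config = replace(config, seed=seed)
    power = {m: [] for m in methods}
    fdp = {m: [] for m in methods}
    for rep in range(config.reps):
        matrix, labels, truth = simulate_genomewide(config, rep)
        truth_mask = np.isin(np.asarray(matrix.feature_ids), truth)
        method_seeds = np.random.SeedSequence(
            ((config.seed or 0), 2, rep)
        ).generate_state(len(methods), dtype=np.uint32)
        for m, mseed in zip(methods, method_seeds):
            p = matrix_pvalues(
                matrix.values_array, labels, m,
                seed=int(mseed), perm_budget=perm_budget,
            )
            positive = adjust_pvalues(p, "bh") <= config.fdr_level
            tp = int((positive & truth_mask).sum())
            fp = int((positive & ~truth_mask).sum())
            power[m].append(tp / config.g)
            fdp[m].append(fp / max(1, int(positive.sum())))
    return pd.DataFrame(
        {
            "method": methods,
            "power": [float(np.mean(power[m])) for m in methods],
            "fdp": [float(np.mean(fdp[m])) for m in methods],
            "reps": config.reps,
            "n": config.n,
        }
    )
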