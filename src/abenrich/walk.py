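"""Rank-ordered enrichment walk for a single feature.

The test statistic targets *aberration enrichment*: a consistent excess of
extreme measurements among a subset of cases relative to controls.  Samples
are ranked by the measurement in the tested direction and a running score is
incremented by ``w_i / n1`` at every case and decremented by ``w_i / n0`` at
every control, where ``w_i`` is the absolute pooled z-score of the sample's
value floored at 0.5.  Under random assignment of the case labels to ranks
the score has mean zero and an exact, closed-form variance at every prefix
length; the statistic is the maximum variance-standardized score along the
walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Direction",
    "WEIGHT_FLOOR",
    "DegenerateFeatureError",
    "InsufficientSamplesError",
    "LabeledSampleSet",
    "WeightVector",
    "EnrichmentWalk",
    "compute_weights",
    "rank_samples",
    "enrichment_curve",
    "null_moments",
    "standardized_walk",
    "two_sided_statistic",
]

#: truncation floor applied to the absolute z-score weights
WEIGHT_FLOOR = 0.5


class Direction(str, Enum):
    """Which tail of the measurement is tested for case enrichment."""

    HIGH_IN_CASES = "high_in_cases"
    LOW_IN_CASES = "low_in_cases"

    @property
    def flipped(self) -> "Direction":
        return (
            Direction.LOW_IN_CASES
            if self is Direction.HIGH_IN_CASES
            else Direction.HIGH_IN_CASES
        )


class DegenerateFeatureError(ValueError):
    """Raised for features with zero variance (untestable; report p = 1)."""


class InsufficientSamplesError(ValueError):
    """Raised when there are too few samples for the requested operation."""


@dataclass(frozen=True)
class LabeledSampleSet:
    """One feature's values across samples with binary case/control labels.

    Parameters
    ----------
    values
        Real measurements, one per sample, in arbitrary units.
    labels
        Binary vector aligned with ``values``; 1 = case, 0 = control.
    """

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        labels = np.asarray(self.labels)
        if values.ndim != 1 or labels.ndim != 1:
            raise ValueError("values and labels must be 1-D vectors")
        if values.shape != labels.shape:
            raise ValueError(
                f"values (len {values.size}) and labels (len {labels.size}) "
                "must have equal length"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain missing or non-finite entries")
        uniq = np.unique(labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("labels must be binary (0 = control, 1 = case)")
        labels = labels.astype(np.int8)
        if labels.sum() < 1 or (labels == 0).sum() < 1:
            raise ValueError("need at least one case and one control")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n1(self) -> int:
        return int(self.labels.sum())

    @property
    def n0(self) -> int:
        return self.n - self.n1


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative sample weights (|pooled z-score| floored at 0.5)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if np.any(w < WEIGHT_FLOOR):
            raise ValueError(f"weights must be >= {WEIGHT_FLOOR}")
        object.__setattr__(self, "w", w)

    def prefix_stats(self, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Prefix sums ``W_k`` and ``sum w^2`` along ``order`` (k = 1..n)."""
        w_ord = self.w[order]
        return np.cumsum(w_ord), np.cumsum(w_ord * w_ord)


@dataclass(frozen=True)
class EnrichmentWalk:
    """The full standardized walk for one feature and direction.

    ``k_star`` is 1-based; ``z`` is NaN at positions where the null variance
    vanishes (those positions never enter the maximum).
    """

    direction: Direction
    order: np.ndarray  # rank -> sample index
    s: np.ndarray  # cumulative scores S_k
    var: np.ndarray  # exact null variances Var_k
    z: np.ndarray  # standardized scores, NaN where Var_k == 0
    usable: np.ndarray  # bool mask, Var_k > 0
    k_star: int
    t: float

    @property
    def n(self) -> int:
        return self.order.size


def compute_weights(values: np.ndarray) -> WeightVector:
    """Absolute pooled z-scores floored at :data:`WEIGHT_FLOOR`.

    The mean and standard deviation (``ddof=1``) pool cases and controls so
    that the weights do not depend on the labels and stay fixed across label
    permutations.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise InsufficientSamplesError("need at least 2 samples for weights")
    # range check rather than sd: summation error can make the sd of an
    # exactly constant vector a few ulp above zero
    if np.ptp(values) == 0.0:
        raise DegenerateFeatureError("feature has zero variance")
    sd = values.std(ddof=1)
    z = np.abs((values - values.mean()) / sd)
    return WeightVector(np.maximum(z, WEIGHT_FLOOR))


def rank_samples(values: np.ndarray, direction: Direction) -> np.ndarray:
    """Sample ordering for the walk (rank 1 = most extreme in `direction`).

    Ties are broken by original sample index (stable sort), so results are
    reproducible on discrete-valued features.
    """
    values = np.asarray(values, dtype=np.float64)
    if Direction(direction) is Direction.HIGH_IN_CASES:
        return np.argsort(-values, kind="stable")
    return np.argsort(values, kind="stable")


def enrichment_curve(
    order: np.ndarray, labels: np.ndarray, weights: WeightVector
) -> np.ndarray:
    """Cumulative scores ``S_k`` along ``order`` (k = 1..n)."""
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    w_ord = weights.w[order]
    is_case = labels[order].astype(bool)
    inc = np.where(is_case, w_ord / n1, -w_ord / n0)
    return np.cumsum(inc)


def null_moments(
    weights: WeightVector | np.ndarray, n1: int, n0: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and variance of ``S_k`` under random label assignment.

    With the n1 case labels assigned uniformly without replacement to the n
    ranks (weights fixed),

        E[S_k]  = 0
        Var_k   = (n * sum_{i<=k} w_(i)^2 - W_k^2) / (n1 * n0 * (n - 1))

    ``weights`` must already be in walk order.
    """
    w = weights.w if isinstance(weights, WeightVector) else np.asarray(weights)
    w = w.astype(np.float64)
    n = w.size
    if n != n1 + n0:
        raise ValueError("weight vector length must equal n1 + n0")
    if n < 3:
        raise InsufficientSamplesError("null moments require n >= 3")
    w_cum = np.cumsum(w)
    w2_cum = np.cumsum(w * w)
    var = (n * w2_cum - w_cum * w_cum) / (n1 * n0 * (n - 1))
    # Cauchy-Schwarz guarantees nonnegativity; clip fp cancellation residue
    np.clip(var, 0.0, None, out=var)
    return np.zeros(n), var


def _usable_mask(var: np.ndarray) -> np.ndarray:
    # relative threshold: Var_k = 0 exactly (all-equal-weight k = n) shows up
    # as cancellation residue many orders below the interior variances
    return var > var.max() * 1e-9


def standardized_walk(
    sample_set: LabeledSampleSet, direction: Direction
) -> EnrichmentWalk:
    """Full walk for one direction: S_k, Var_k, Z_k, and the max statistic.

    Positions with zero null variance are excluded from the maximum.
    """
    direction = Direction(direction)
    weights = compute_weights(sample_set.values)
    order = rank_samples(sample_set.values, direction)
    s = enrichment_curve(order, sample_set.labels, weights)
    _, var = null_moments(weights.w[order], sample_set.n1, sample_set.n0)
    usable = _usable_mask(var)
    z = np.full(sample_set.n, np.nan)
    z[usable] = s[usable] / np.sqrt(var[usable])
    if not usable.any():  # unreachable for n >= 3 with positive weights
        raise DegenerateFeatureError("no position with positive null variance")
    zm = np.where(usable, z, -np.inf)
    k_star = int(np.argmax(zm)) + 1
    return EnrichmentWalk(
        direction=direction,
        order=order,
        s=s,
        var=var,
        z=z,
        usable=usable,
        k_star=k_star,
        t=float(zm[k_star - 1]),
    )


def two_sided_statistic(
    sample_set: LabeledSampleSet,
) -> tuple[float, Direction, EnrichmentWalk]:
    """Run the walk in both directions and keep the larger maximum.

    The permutation null is built on this same two-sided statistic, so the
    resulting p-value needs no further direction correction.  Ties go to
    ``high_in_cases``.
    """
    walk_hi = standardized_walk(sample_set, Direction.HIGH_IN_CASES)
    walk_lo = standardized_walk(sample_set, Direction.LOW_IN_CASES)
    if walk_hi.t >= walk_lo.t:
        return walk_hi.t, Direction.HIGH_IN_CASES, walk_hi
    return walk_lo.t, Direction.LOW_IN_CASES, walk_lo
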