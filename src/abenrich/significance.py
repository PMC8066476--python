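"""Permutation significance, aberrant-subgroup estimation, matrix screening."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _perm
from .walk import (
    DegenerateFeatureError,
    Direction,
    EnrichmentWalk,
    LabeledSampleSet,
    standardized_walk,
    two_sided_statistic,
)

__all__ = [
    "AberrationTestResult",
    "permutation_pvalue",
    "exhaustive_pvalue",
    "estimate_r",
    "adjust_pvalues",
    "test_matrix",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

_EXHAUSTIVE_LIMIT = 10**6


@dataclass(frozen=True)
class AberrationTestResult:
    """Outcome of the aberration-enrichment test on one feature.

    ``p_value`` uses the add-one permutation estimator
    ``(1 + exceedances) / (1 + B_used)`` so it is never zero; exhaustive
    enumeration reports the exact unshifted fraction instead.  ``r_hat`` is
    the excess case fraction in the maximizing prefix,
    ``prefix_case_count/n1 - prefix_control_count/n0`` floored at 0 — an
    estimate of the proportion of cases carrying the aberration.
    ``boundary_value`` is the measurement at rank ``k_star``; the aberrant
    interval is everything beyond it (inclusive) in ``direction``.
    """

    statistic: float
    p_value: float
    b_used: int
    exceedances: int
    direction: Direction
    k_star: int
    prefix_case_count: int
    prefix_control_count: int
    r_hat: float
    boundary_value: float
    seed: int | None
    degenerate: bool = False
    exhaustive: bool = False


def _degenerate_result(seed: int | None) -> AberrationTestResult:
    return AberrationTestResult(
        statistic=np.nan,
        p_value=1.0,
        b_used=0,
        exceedances=0,
        direction=Direction.HIGH_IN_CASES,
        k_star=0,
        prefix_case_count=0,
        prefix_control_count=0,
        r_hat=0.0,
        boundary_value=np.nan,
        seed=seed,
        degenerate=True,
    )


def estimate_r(
    walk: EnrichmentWalk, sample_set: LabeledSampleSet
) -> tuple[float, int, int, float]:
    """Aberrant-subgroup summary from the maximizing prefix.

    Returns ``(r_hat, prefix_case_count, prefix_control_count,
    boundary_value)``.  The prefix is ranks ``1..k_star``; subtracting the
    control prefix fraction removes the background aberration rate seen in
    controls, and the estimate is floored at zero.
    """
    prefix = walk.order[: walk.k_star]
    cases = int(sample_set.labels[prefix].sum())
    controls = walk.k_star - cases
    r_hat = max(0.0, cases / sample_set.n1 - controls / sample_set.n0)
    boundary = float(sample_set.values[walk.order[walk.k_star - 1]])
    return r_hat, cases, controls, boundary


def _observed(
    sample_set: LabeledSampleSet, direction: Direction | str
) -> tuple[float, Direction, EnrichmentWalk, list[_perm.WalkPrep]]:
    if direction == "both":
        t_obs, best_dir, walk = two_sided_statistic(sample_set)
        preps = [
            _perm.prepare_walk(sample_set, Direction.HIGH_IN_CASES),
            _perm.prepare_walk(sample_set, Direction.LOW_IN_CASES),
        ]
    else:
        best_dir = Direction(direction)
        walk = standardized_walk(sample_set, best_dir)
        t_obs = walk.t
        preps = [_perm.prepare_walk(sample_set, best_dir)]
    return t_obs, best_dir, walk, preps


def permutation_pvalue(
    sample_set: LabeledSampleSet,
    b_max: int = 100_000,
    adaptive: bool = True,
    min_exceedances: int = 25,
    seed: int | None = None,
    direction: Direction | str = "both",
) -> AberrationTestResult:
    """Permutation p-value for the (by default two-sided) walk statistic.

    Case labels are reassigned uniformly at random among the ranks, weights
    and orderings fixed, and the same statistic recomputed;
    ``p = (1 + #{T_perm >= T_obs}) / (1 + B_used)``.  With ``adaptive=True``
    permutation stops early once ``min_exceedances`` permuted statistics have
    reached the observed one (the p-value is then already resolved to ~20%
    relative precision and cannot be small).
    """
    if b_max < 1:
        raise ValueError("b_max must be >= 1")
    try:
        t_obs, best_dir, walk, preps = _observed(sample_set, direction)
    except DegenerateFeatureError:
        return _degenerate_result(seed)
    exceed, used = _perm.count_exceedances(
        preps,
        t_obs,
        b_max,
        np.random.SeedSequence(seed),
        adaptive,
        min_exceedances,
    )
    r_hat, pc, pctl, boundary = estimate_r(walk, sample_set)
    return AberrationTestResult(
        statistic=t_obs,
        p_value=(1 + exceed) / (1 + used),
        b_used=used,
        exceedances=exceed,
        direction=best_dir,
        k_star=walk.k_star,
        prefix_case_count=pc,
        prefix_control_count=pctl,
        r_hat=r_hat,
        boundary_value=boundary,
        seed=seed,
    )


def exhaustive_pvalue(
    sample_set: LabeledSampleSet, direction: Direction | str = "both"
) -> AberrationTestResult:
    """Exact p-value by enumerating every case/control label arrangement.

    ``p = #{arrangements with T >= T_obs} / C(n, n1)`` (the observed
    arrangement is one of them, so p >= 1/C(n, n1)).
    """
    n, n1 = sample_set.n, sample_set.n1
    total = comb(n, n1)
    if total > _EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"C({n}, {n1}) = {total} arrangements exceed the exhaustive "
            f"enumeration bound of {_EXHAUSTIVE_LIMIT}"
        )
    try:
        t_obs, best_dir, walk, preps = _observed(sample_set, direction)
    except DegenerateFeatureError:
        return _degenerate_result(None)
    threshold = _perm.exceedance_threshold(t_obs)
    exceed = 0
    chunk: list[np.ndarray] = []
    for combo in combinations(range(n), n1):
        row = np.zeros(n, dtype=bool)
        row[list(combo)] = True
        chunk.append(row)
        if len(chunk) == 4096:
            t = _perm.batch_statistic(preps, np.array(chunk))
            exceed += int((t >= threshold).sum())
            chunk = []
    if chunk:
        t = _perm.batch_statistic(preps, np.array(chunk))
        exceed += int((t >= threshold).sum())
    r_hat, pc, pctl, boundary = estimate_r(walk, sample_set)
    return AberrationTestResult(
        statistic=t_obs,
        p_value=exceed / total,
        b_used=total,
        exceedances=exceed,
        direction=best_dir,
        k_star=walk.k_star,
        prefix_case_count=pc,
        prefix_control_count=pctl,
        r_hat=r_hat,
        boundary_value=boundary,
        seed=None,
        exhaustive=True,
    )


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjustment, input order preserved."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return multipletests(p, method=key)[1]


RESULT_COLUMNS = [
    "feature",
    "statistic",
    "p_value",
    "p_bh",
    "p_bonferroni",
    "direction",
    "k_star",
    "r_hat",
    "prefix_case_count",
    "prefix_control_count",
    "boundary_value",
    "b_used",
    "exceedances",
    "degenerate",
]


def test_matrix(
    matrix,
    labels,
    b_max: int = 100_000,
    adaptive: bool = True,
    min_exceedances: int = 25,
    direction: Direction | str = "both",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Screen every feature of a features x samples matrix.

    ``matrix`` may be a :class:`~abenrich.io.FeatureMatrix`, a pandas
    DataFrame (rows = features), or a 2-D array.  Per-feature random streams
    are spawned from the master ``seed`` keyed by feature index, so results
    do not depend on evaluation order.  Degenerate (constant) features are
    reported with p = 1 and flagged.
    """
    if hasattr(matrix, "values_array"):  # FeatureMatrix
        values = matrix.values_array
        feature_ids = list(matrix.feature_ids)
    elif isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=np.float64)
        feature_ids = list(matrix.index.astype(str))
    else:
        values = np.asarray(matrix, dtype=np.float64)
        feature_ids = [str(i) for i in range(values.shape[0])]
    labels = np.asarray(labels)
    if values.shape[1] != labels.size:
        raise ValueError(
            f"matrix has {values.shape[1]} samples but {labels.size} labels"
        )
    children = np.random.SeedSequence(seed).spawn(values.shape[0])
    rows = []
    for i, (fid, child) in enumerate(zip(feature_ids, children)):
        feat_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        try:
            sset = LabeledSampleSet(values[i], labels)
            res = permutation_pvalue(
                sset,
                b_max=b_max,
                adaptive=adaptive,
                min_exceedances=min_exceedances,
                seed=feat_seed,
                direction=direction,
            )
        except DegenerateFeatureError:
            res = _degenerate_result(feat_seed)
        if res.degenerate:
            logger.info("feature %s is degenerate (constant); p set to 1", fid)
        rows.append(
            {
                "feature": fid,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "direction": res.direction.value,
                "k_star": res.k_star,
                "r_hat": res.r_hat,
                "prefix_case_count": res.prefix_case_count,
                "prefix_control_count": res.prefix_control_count,
                "boundary_value": res.boundary_value,
                "b_used": res.b_used,
                "exceedances": res.exceedances,
                "degenerate": res.degenerate,
            }
        )
        if (i + 1) % 500 == 0:
            logger.info("screened %d / %d features", i + 1, len(feature_ids))
    table = pd.DataFrame(rows)
    table["p_bh"] = adjust_pvalues(table["p_value"], "bh")
    table["p_bonferroni"] = adjust_pvalues(table["p_value"], "bonferroni")
    return table[RESULT_COLUMNS]
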