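"""Shared machinery for permutation nulls.

The walk statistic is cheap per permutation (O(n) after precomputation):
weights depend only on the values, so a permutation reshuffles labels only
and the per-rank increments / standard deviations can be prepared once per
direction.  A numba kernel iterates permutations without materialising large
matrices; a vectorised numpy evaluator handles exhaustive enumeration and
doubles as an independent code path in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, uint64

from .walk import (
    Direction,
    LabeledSampleSet,
    compute_weights,
    null_moments,
    rank_samples,
    _usable_mask,
)

# statistic comparisons tolerate fp noise between code paths; counting a
# tied permuted statistic as an exceedance is the conservative side
_EXCEEDANCE_RTOL = 1e-9

_NEG = -1.0e300  # additive penalty that removes unusable positions from max


@dataclass(frozen=True)
class WalkPrep:
    """Per-direction arrays fixed across label permutations (rank order)."""

    order: np.ndarray  # rank -> sample index
    base: np.ndarray  # control increment  -w_(k)/n0
    diff: np.ndarray  # case minus control increment  w_(k)*(1/n1 + 1/n0)
    invsd: np.ndarray  # 1/sqrt(Var_k), 0 where unusable
    penalty: np.ndarray  # 0 where usable, -1e300 where not
    n1: int


def prepare_walk(sample_set: LabeledSampleSet, direction: Direction) -> WalkPrep:
    weights = compute_weights(sample_set.values)
    order = rank_samples(sample_set.values, direction)
    w_ord = weights.w[order]
    n1, n0 = sample_set.n1, sample_set.n0
    _, var = null_moments(w_ord, n1, n0)
    usable = _usable_mask(var)
    invsd = np.zeros_like(var)
    invsd[usable] = 1.0 / np.sqrt(var[usable])
    penalty = np.where(usable, 0.0, _NEG)
    return WalkPrep(
        order=np.ascontiguousarray(order, dtype=np.int64),
        base=np.ascontiguousarray(-w_ord / n0),
        diff=np.ascontiguousarray(w_ord * (1.0 / n1 + 1.0 / n0)),
        invsd=np.ascontiguousarray(invsd),
        penalty=np.ascontiguousarray(penalty),
        n1=n1,
    )


def batch_statistic(preps: list[WalkPrep], case_bool: np.ndarray) -> np.ndarray:
    """Max standardized score for each row of ``case_bool`` (sample space).

    ``preps`` holds one or two directions; the returned statistic is the max
    over the directions supplied.
    """
    case_bool = np.atleast_2d(case_bool)
    out = np.full(case_bool.shape[0], -np.inf)
    for prep in preps:
        inc = prep.base + prep.diff * case_bool[:, prep.order]
        z = np.cumsum(inc, axis=1) * prep.invsd + prep.penalty
        np.maximum(out, z.max(axis=1), out=out)
    return out


@njit(cache=False, fastmath=True)
def _perm_chunk(
    base_a, diff_a, invsd_a, pen_a,
    base_b, diff_b, invsd_b, pen_b,
    map_ba, two_sided, n1, threshold, n_perm, seed,
):  # pragma: no cover - exercised via python wrappers
    # splitmix64 scramble, then xorshift64 draws; modulo-free bounded ints
    state = uint64(seed) + uint64(0x9E3779B97F4A7C15)
    state = (state ^ (state >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    state = (state ^ (state >> uint64(27))) * uint64(0x94D049BB133111EB)
    state = state ^ (state >> uint64(31))
    if state == uint64(0):
        state = uint64(0x106689D45497FDB5)
    inv53 = 1.0 / 9007199254740992.0
    n = base_a.shape[0]
    idx = np.arange(n)
    case = np.zeros(n, dtype=np.float64)
    exceed = 0
    for _ in range(n_perm):
        # partial Fisher-Yates over direction-A ranks: idx[:n1] is a uniform
        # n1-subset of ranks (equivalently, of samples)
        for j in range(n1):
            state ^= state << uint64(13)
            state ^= state >> uint64(7)
            state ^= state << uint64(17)
            u = (state >> uint64(11)) * inv53
            k = j + int(u * (n - j))
            tmp = idx[j]
            idx[j] = idx[k]
            idx[k] = tmp
            case[idx[j]] = 1.0
        t = -np.inf
        s = 0.0
        for k in range(n):
            s += base_a[k] + diff_a[k] * case[k]
            z = s * invsd_a[k] + pen_a[k]
            if z > t:
                t = z
        if two_sided:
            s = 0.0
            for k in range(n):
                s += base_b[k] + diff_b[k] * case[map_ba[k]]
                z = s * invsd_b[k] + pen_b[k]
                if z > t:
                    t = z
        if t >= threshold:
            exceed += 1
        for j in range(n1):
            case[idx[j]] = 0.0
    return exceed


def exceedance_threshold(t_obs: float) -> float:
    return t_obs - _EXCEEDANCE_RTOL * max(1.0, abs(t_obs))


def chunk_schedule(b_max: int, start: int = 256, cap: int = 1 << 20) -> list[int]:
    """Geometric permutation batches: early nulls stop cheaply, large
    budgets amortise kernel-call overhead."""
    sizes: list[int] = []
    size = start
    remaining = int(b_max)
    while remaining > 0:
        take = min(size, remaining)
        sizes.append(take)
        remaining -= take
        size = min(size * 2, cap)
    return sizes


def count_exceedances(
    preps: list[WalkPrep],
    t_obs: float,
    b_max: int,
    seed_seq: np.random.SeedSequence,
    adaptive: bool,
    min_exceedances: int,
) -> tuple[int, int]:
    """Run up to ``b_max`` label permutations, returning (exceedances, B_used).

    If ``adaptive``, stops at the first chunk boundary where the exceedance
    count reaches ``min_exceedances``.
    """
    two_sided = len(preps) == 2
    a = preps[0]
    b = preps[1] if two_sided else preps[0]
    # rank of direction-B walk -> position in direction-A rank order
    inv_a = np.empty(a.order.size, dtype=np.int64)
    inv_a[a.order] = np.arange(a.order.size)
    map_ba = np.ascontiguousarray(inv_a[b.order])
    sizes = chunk_schedule(b_max)
    seeds = seed_seq.generate_state(len(sizes), dtype=np.uint64)
    threshold = exceedance_threshold(t_obs)
    exceed = 0
    used = 0
    for size, seed in zip(sizes, seeds):
        exceed += _perm_chunk(
            a.base, a.diff, a.invsd, a.penalty,
            b.base, b.diff, b.invsd, b.penalty,
            map_ba, two_sided, a.n1, threshold, size, seed,
        )
        used += size
        if adaptive and exceed >= min_exceedances:
            break
    return exceed, used
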