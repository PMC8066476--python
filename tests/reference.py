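"""Naive, independent reimplementation of the walk statistic for oracle use.

Deliberately slow and enumeration-based: the per-position null variance is
estimated from the full set of label arrangements (not the closed form), so
agreement with the package is a genuine cross-check of both the variance
formula and the statistic plumbing.
"""

from itertools import combinations
from statistics import mean, stdev

import numpy as np


def ref_weights(values):
    m = mean(values)
    sd = stdev(values)
    return [max(abs((x - m) / sd), 0.5) for x in values]


def ref_order(values, direction):
    idx = list(range(len(values)))
    if direction == "high_in_cases":
        return sorted(idx, key=lambda i: (-values[i], i))
    return sorted(idx, key=lambda i: (values[i], i))


def ref_curve(order, labels, w):
    n1 = sum(labels)
    n0 = len(labels) - n1
    s, out = 0.0, []
    for i in order:
        s += w[i] / n1 if labels[i] == 1 else -w[i] / n0
        out.append(s)
    return out


def ref_enum_variances(values, n1, direction):
    """Per-position variance of S_k over all label arrangements."""
    n = len(values)
    w = ref_weights(values)
    order = ref_order(values, direction)
    curves = []
    for combo in combinations(range(n), n1):
        labels = [1 if i in combo else 0 for i in range(n)]
        curves.append(ref_curve(order, labels, w))
    arr = np.array(curves)
    return arr.mean(axis=0), arr.var(axis=0)


def ref_statistic(values, labels, direction, var=None):
    """Max standardized score, standardized by *enumeration* variances."""
    if var is None:
        _, var = ref_enum_variances(values, sum(labels), direction)
    w = ref_weights(values)
    order = ref_order(values, direction)
    s = ref_curve(order, labels, w)
    vmax = max(var)
    best = -np.inf
    for k in range(len(values)):
        if var[k] > vmax * 1e-9:
            best = max(best, s[k] / np.sqrt(var[k]))
    return best


def ref_two_sided(values, labels, var_hi=None, var_lo=None):
    return max(
        ref_statistic(values, labels, "high_in_cases", var_hi),
        ref_statistic(values, labels, "low_in_cases", var_lo),
    )


def ref_exhaustive_p(values, labels, two_sided=True):
    """Exact p by full enumeration with enumeration-based standardization."""
    n, n1 = len(values), sum(labels)
    _, var_hi = ref_enum_variances(values, n1, "high_in_cases")
    _, var_lo = ref_enum_variances(values, n1, "low_in_cases")

    def stat(lab):
        if two_sided:
            return ref_two_sided(values, lab, var_hi, var_lo)
        return ref_statistic(values, lab, "high_in_cases", var_hi)

    t_obs = stat(list(labels))
    count = total = 0
    for combo in combinations(range(n), n1):
        lab = [1 if i in combo else 0 for i in range(n)]
        total += 1
        if stat(lab) >= t_obs - 1e-9 * max(1.0, abs(t_obs)):
            count += 1
    return count / total
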