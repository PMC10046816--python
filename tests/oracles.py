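"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different algorithmic route from the code
under test: segment intersection is decided by solving the parametric 2x2
system in exact rational arithmetic (`fractions.Fraction`), direction
changes by explicit run-length compression, and AUROC by brute-force pair
counting.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def segments_intersect_oracle(p1, p2, p3, p4) -> bool:
    """Exact closed-segment intersection via rational parametric solve.

    Segment A = p1 + s (p2 - p1), segment B = p3 + u (p4 - p3) with
    s, u in [0, 1].  All arithmetic is in Fractions, so the verdict is
    exact for any float input.  Touching counts; zero-length segments are
    points.
    """
    x1, y1 = map(Fraction, p1)
    x2, y2 = map(Fraction, p2)
    x3, y3 = map(Fraction, p3)
    x4, y4 = map(Fraction, p4)
    rx, ry = x2 - x1, y2 - y1
    sx, sy = x4 - x3, y4 - y3
    denom = rx * sy - ry * sx
    qpx, qpy = x3 - x1, y3 - y1

    a_point = rx == 0 and ry == 0
    b_point = sx == 0 and sy == 0

    if denom != 0:
        s = (qpx * sy - qpy * sx) / denom
        u = (qpx * ry - qpy * rx) / denom
        return 0 <= s <= 1 and 0 <= u <= 1

    # Parallel directions (or a degenerate segment).
    if a_point and b_point:
        return x1 == x3 and y1 == y3
    if a_point:
        on_line = (x1 - x3) * sy - (y1 - y3) * sx == 0
        return on_line and _within(x3, x4, x1) and _within(y3, y4, y1)
    if b_point:
        on_line = (x3 - x1) * ry - (y3 - y1) * rx == 0
        return on_line and _within(x1, x2, x3) and _within(y1, y2, y3)
    if qpx * ry - qpy * rx != 0:
        return False  # parallel but not collinear
    # Two collinear proper segments: project on A's dominant axis.
    if rx != 0:
        lo_a, hi_a = min(x1, x2), max(x1, x2)
        lo_b, hi_b = min(x3, x4), max(x3, x4)
    else:
        lo_a, hi_a = min(y1, y2), max(y1, y2)
        lo_b, hi_b = min(y3, y4), max(y3, y4)
    return max(lo_a, lo_b) <= min(hi_a, hi_b)


def _within(a, b, c) -> bool:
    return min(a, b) <= c <= max(a, b)


def direction_changes_oracle(y, carry_in: int = 0):
    """Run-length counting of vertical direction changes.

    Drop zero deltas, prepend the carry if any, and count adjacent sign
    changes in what remains; the last sign is the carry out.
    """
    deltas = [int(np.sign(b - a)) for a, b in zip(y, y[1:])]
    runs = [d for d in deltas if d != 0]
    if carry_in:
        runs = [carry_in] + runs
    count = sum(1 for a, b in zip(runs, runs[1:]) if a != b)
    carry_out = runs[-1] if runs else 0
    return count, carry_out


def auroc_pairs_oracle(labels, scores) -> float:
    """AUROC by brute-force counting of positive/negative score pairs."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def mann_whitney_exact_oracle(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group splits.

    Returns (U of sample a, p).  Tie-free data assumed.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_of(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + \
            0.5 * sum(1 for x in group_a for y in group_b if x == y)

    u_obs = u_of(a, b)
    n2 = len(b)
    mean_u = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_of(ga, gb) - mean_u) >= dev_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total
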