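"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive each quantity from first principles (exact
integer enumeration, definitional formulas, exhaustive agglomeration) and
share no code with the package.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np
from scipy import stats as _stats


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Works in integer numerators over the common denominator C(n, col1), so
    the tie comparison ("probability <= observed") is exact.
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    den = comb(n, col1)
    k_lo, k_hi = max(0, col1 - (n - row1)), min(row1, col1)
    numerators = {k: comb(row1, k) * comb(n - row1, col1 - k) for k in range(k_lo, k_hi + 1)}
    obs = numerators[a]
    return min(1.0, sum(v for v in numerators.values() if v <= obs) / den)


def bh_stepup(p_values) -> np.ndarray:
    """Definitional BH step-up: q_(i) = min_{j>=i} p_(j)*m/j, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for j in range(m - 1, -1, -1):
        val = (p[order[j]] * m) / (j + 1)
        running = min(running, val)
        q_sorted[j] = running
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def centroid_agglomeration(midsum2: list[int], cut_height: float) -> list[frozenset[int]]:
    """Exhaustive centroid-linkage agglomeration on 1-D midpoints.

    ``midsum2[i]`` is twice the midpoint of item i (an exact integer for
    integer coordinates).  Considers ALL cluster pairs each round, always
    merges the closest (tie-break: smaller leftmost member midpoint, then
    smaller rightmost), and stops when the minimum inter-centroid distance
    reaches ``cut_height``.  Returns the partition as member-index sets.
    """
    clusters: list[dict] = [
        {"sum2": s2, "n": 1, "members": frozenset([i]), "leftmost": s2, "rightmost": s2}
        for i, s2 in enumerate(midsum2)
    ]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ci = clusters[i]["sum2"] / (2 * clusters[i]["n"])
                cj = clusters[j]["sum2"] / (2 * clusters[j]["n"])
                pair_left = min(clusters[i]["leftmost"], clusters[j]["leftmost"])
                pair_right = min(clusters[i]["rightmost"], clusters[j]["rightmost"])
                key = (abs(cj - ci), pair_left, pair_right)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dist, _, _), i, j = best
        if dist >= cut_height:
            break
        a, b = clusters[i], clusters[j]
        merged = {
            "sum2": a["sum2"] + b["sum2"],
            "n": a["n"] + b["n"],
            "members": a["members"] | b["members"],
            "leftmost": min(a["leftmost"], b["leftmost"]),
            "rightmost": max(a["rightmost"], b["rightmost"]),
        }
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return [c["members"] for c in clusters]


def welch_t(x, y) -> tuple[float, float]:
    """Textbook Welch t statistic and two-sided p via Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * _stats.t.sf(abs(t), df)
    return t, p
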