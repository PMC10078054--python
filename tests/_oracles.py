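"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a route independent of the
implementation it checks: exhaustive enumeration, per-base dynamic
programming, or closed forms at tiny problem sizes.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def rank_sum_p_enumeration(x, y) -> float:
    """P(rank sum of x >= observed) by full enumeration of assignments."""
    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(idx)].sum() >= w_obs - 1e-12:
            hits += 1
    return hits / total


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by exact rational enumeration of all tables.

    Enumerates every 2 x n table with the observed margins, computes
    each probability as an exact Fraction, and sums those no more
    probable than the observed table.
    """
    table = [list(map(int, row)) for row in table]
    cols = [a + b for a, b in zip(table[0], table[1])]
    r1 = sum(table[0])
    total = sum(cols)
    denom = math.comb(total, r1)

    def prob(row1) -> Fraction:
        return Fraction(math.prod(math.comb(c, a) for c, a in zip(cols, row1)), denom)

    p_obs = prob(table[0])
    p = Fraction(0)
    for row1 in itertools.product(*[range(c + 1) for c in cols]):
        if sum(row1) != r1:
            continue
        pr = prob(row1)
        if pr <= p_obs:
            p += pr
    return float(p)


def bh_step_up(p) -> list[float]:
    """Textbook Benjamini-Hochberg step-up, written from the definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def ruzzo_tompa_segments(positions, counts, density) -> set[tuple[int, int]]:
    """All maximal-scoring segments for score = total - density * span.

    Per-base formulation: each base at a site position scores
    (count - density), every other base in between scores -density.
    Implements the Ruzzo-Tompa linear-time algorithm over the per-base
    score sequence and reports segments trimmed to site positions.
    """
    positions = list(map(int, positions))
    counts = list(map(float, counts))
    lo, hi = min(positions), max(positions)
    value_at = dict(zip(positions, counts))
    scores = [value_at.get(p, 0.0) - density for p in range(lo, hi + 1)]

    # Ruzzo & Tompa: maintain a list of disjoint candidate subsequences
    segs: list[list[float]] = []  # [L, R, startTotal, endTotal] with base indices [L, R)
    cum = 0.0
    eps = 1e-9
    for i, s in enumerate(scores):
        cum_next = cum + s
        if s > eps:
            seg = [i, i + 1, cum, cum_next]
            while True:
                # step 1: find rightmost j with startTotal_j < startTotal_seg
                j = None
                for k in range(len(segs) - 1, -1, -1):
                    if segs[k][2] < seg[2] - eps:
                        j = k
                        break
                if j is None or segs[j][3] >= seg[3] - eps:
                    segs.append(seg)
                    break
                # merge: extend segment j to cover through seg
                merged = [segs[j][0], seg[1], segs[j][2], seg[3]]
                segs = segs[:j]
                seg = merged
        cum = cum_next

    out = set()
    for L, R, *_ in segs:
        start, end = lo + L, lo + R - 1
        # trim to site positions (maximal segments start/end on positive bases)
        out.add((start, end))
    return out


def paraclu_cluster_set(positions, counts) -> set[tuple[int, int]]:
    """Union over all densities of the maximal-scoring segments.

    The density grid contains 0 and, for every run of consecutive sites,
    its density under each relevant span convention (inclusive span, and
    the base spans of prefix/suffix pieces reaching the neighbouring
    site), plus midpoints between consecutive grid values to cover the
    open intervals between critical densities.
    """
    positions = list(map(int, positions))
    counts = list(map(float, counts))
    n = len(positions)
    densities = {0.0}
    for i in range(n):
        run = 0.0
        for j in range(i, n):
            run += counts[j]
            densities.add(run / (positions[j] - positions[i] + 1))
            if i > 0:
                densities.add(run / (positions[j] - positions[i - 1]))
            if j < n - 1:
                densities.add(run / (positions[j + 1] - positions[i]))
    grid = sorted(densities)
    probes = list(grid)
    probes += [(a + b) / 2 for a, b in zip(grid, grid[1:])]
    out: set[tuple[int, int]] = set()
    for d in probes:
        out |= ruzzo_tompa_segments(positions, counts, d)
    return out


def zero_truncated_poisson_pmf(k: np.ndarray, lam: float) -> np.ndarray:
    from scipy.stats import poisson

    return poisson.pmf(k, lam) / (1 - math.exp(-lam))
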