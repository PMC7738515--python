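"""Independent first-principles reference implementations used by the tests.

Everything here is deliberately written from textbook formulas (explicit
loops, normal equations, pair counting) and imports nothing from the
package under test, so it can serve as an independent oracle.
"""

from __future__ import annotations

import math

import numpy as np


def average_ranks(x) -> list[float]:
    """Average-tie ranks, by explicit sorting and tie-group averaging."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman(x, y) -> float:
    """Rank-then-Pearson Spearman correlation."""
    return pearson(average_ranks(x), average_ranks(y))


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall tau_b by explicit pair counting."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif (dx > 0) == (dy > 0):
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2

    def tie_count(v):
        seen = {}
        for a in v:
            seen[a] = seen.get(a, 0) + 1
        return sum(c * (c - 1) // 2 for c in seen.values())

    n1, n2 = tie_count(x), tie_count(y)
    return (nc - nd) / math.sqrt((n0 - n1) * (n0 - n2))


def euclidean(x, y) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def distance(x, y, metric: str) -> float:
    if metric == "spearman":
        return 1.0 - spearman(x, y)
    if metric == "kendall":
        return 1.0 - kendall_tau_b(x, y)
    return euclidean(x, y)


def ols_line(x, y):
    """(intercept, slope) by solving the 2x2 normal equations directly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.array([[len(x), x.sum()], [x.sum(), (x**2).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return float(intercept), float(slope)


def pooled_t(a, b) -> float:
    """Classical pooled-variance two-sample t statistic, textbook form."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def fisher_z_test(m1: float, m2: float, n_eff: int):
    """(z, two-sided p) for comparing two correlations via atanh."""
    z = (math.atanh(m1) - math.atanh(m2)) / math.sqrt(2.0 / (n_eff - 3))
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return z, p


def average_linkage(d: np.ndarray):
    """Brute-force unweighted average linkage.

    Cluster distances are recomputed from scratch as the mean over member
    pairs of the original matrix at every step (no Lance-Williams
    update).  Node ids: leaves 0..n-1, merge k gets id n+k; ties on the
    minimum broken by the smallest (left, right) id pair.  Returns merge
    tuples (node, left, right, height).
    """
    n = d.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        ids = sorted(members)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                pairs = [(u, v) for u in members[i] for v in members[j]]
                dist = sum(d[u, v] for u, v in pairs) / len(pairs)
                if best is None:
                    best = (dist, i, j)
                    continue
                # tolerance tie: exact mathematical ties differ in the last
                # float bit depending on summation order
                tol = 1e-9 * max(1.0, abs(dist), abs(best[0]))
                if dist < best[0] - tol or (
                    abs(dist - best[0]) <= tol and (i, j) < best[1:3]
                ):
                    best = (dist, i, j)
        dist, i, j = best
        new = n + step
        merges.append((new, i, j, dist))
        members[new] = members.pop(i) | members.pop(j)
    return merges
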