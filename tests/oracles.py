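"""Independent brute-force oracles used across the test suite.

Every function here recomputes a statistic from its textbook definition
(naive loops, exhaustive enumeration, closed forms) without touching the
implementation paths in :mod:`urobiome`.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist


def shannon_naive(counts, base=2.0):
    total = float(sum(counts))
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p, base)
    return h


def bray_curtis_naive(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den if den else 0.0


def faith_pd_naive(tree, present: set) -> float:
    """Sum of branch lengths of every edge with >= 1 present descendant."""
    total = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} | ({node.name} if node.is_tip() else set())
        if leaves & present:
            total += node.length or 0.0
    return total


def unifrac_naive(tree, set_a: set, set_b: set) -> float:
    """Per-edge unique/shared classification, straight from the definition."""
    unique = shared = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} | ({node.name} if node.is_tip() else set())
        in_a, in_b = bool(leaves & set_a), bool(leaves & set_b)
        if in_a and in_b:
            shared += node.length or 0.0
        elif in_a or in_b:
            unique += node.length or 0.0
    total = unique + shared
    return unique / total if total else 0.0


def midrank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_naive(x, y):
    rx, ry = midrank(list(x)), midrank(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def bh_naive(pvalues):
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def fisher_exact_naive(table) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric family."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def log_prob(x):
        return (
            gammaln(row1 + 1) - gammaln(x + 1) - gammaln(row1 - x + 1)
            + gammaln(row2 + 1) - gammaln(col1 - x + 1) - gammaln(row2 - col1 + x + 1)
            - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
        )

    lo, hi = max(0, col1 - row2), min(row1, col1)
    probs = {x: math.exp(log_prob(x)) for x in range(lo, hi + 1)}
    cutoff = probs[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in probs.values() if p <= cutoff))


def chi2_independence_naive(table) -> tuple[float, float]:
    table = [[float(v) for v in row] for row in table]
    row_sums = [sum(r) for r in table]
    col_sums = [sum(c) for c in zip(*table)]
    n = sum(row_sums)
    stat = 0.0
    for i, r in enumerate(table):
        for j, o in enumerate(r):
            e = row_sums[i] * col_sums[j] / n
            stat += (o - e) ** 2 / e
    df = (len(table) - 1) * (len(table[0]) - 1)
    return stat, float(chi2_dist.sf(stat, df))


def mannwhitney_u_naive(x, y) -> float:
    """U statistic by pair counting with half-credit for ties."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mannwhitney_exact_p_naive(x, y) -> float:
    """Two-sided exact p by enumerating every group assignment."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mannwhitney_u_naive(x, y)
    n_total = 0
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        stats.append(mannwhitney_u_naive(g1, g2))
        n_total += 1
    stats = np.asarray(stats)
    p_le = float((stats <= u_obs + 1e-12).sum()) / n_total
    p_ge = float((stats >= u_obs - 1e-12).sum()) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def calinski_harabasz_naive(x, labels) -> float:
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n, _ = x.shape
    overall = x.mean(axis=0)
    groups = np.unique(labels)
    k = len(groups)
    between = sum(
        (labels == g).sum() * float(((x[labels == g].mean(axis=0) - overall) ** 2).sum())
        for g in groups
    )
    within = sum(
        float(((x[labels == g] - x[labels == g].mean(axis=0)) ** 2).sum()) for g in groups
    )
    return (between / (k - 1)) / (within / (n - k))


def silhouette_naive(distance, labels) -> float:
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            scores[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(
            d[i, labels == g].mean() for g in np.unique(labels) if g != labels[i]
        )
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def ward_d2_linkage_naive(distance) -> list[tuple[float, frozenset]]:
    """Brute-force Ward.D2 agglomeration by the Lance-Williams update on
    squared dissimilarities; returns merge heights with merged member sets."""
    d2 = np.asarray(distance, dtype=float) ** 2
    n = d2.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d2[i, j]
    merges = []
    next_id = n
    sizes = {i: 1 for i in range(n)}
    while len(clusters) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((math.sqrt(dij), clusters[i] | clusters[j]))
        si, sj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            sk = sizes[k]
            dist[(k, new) if k < new else (new, k)] = (
                (si + sk) * dik + (sj + sk) * djk - sk * dij
            ) / (si + sj + sk)
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = si + sj
        for k in (i, j):
            del clusters[k], sizes[k]
        dist = {
            pair: v for pair, v in dist.items() if i not in pair and j not in pair
        }
    return merges


def detection_prob_subsample(count: int, library: int, depth: int) -> float:
    """P(an ASV with `count` reads survives subsampling to `depth`)."""
    from scipy.stats import hypergeom

    return float(1.0 - hypergeom.pmf(0, library, count, depth))


def detection_prob_cohort(k_present: int, n_total: int, n_drawn: int) -> float:
    """P(an ASV present in k of N samples appears among n drawn samples)."""
    return float(
        1.0
        - math.exp(
            gammaln(n_total - k_present + 1)
            - gammaln(n_total - k_present - n_drawn + 1)
            - (gammaln(n_total + 1) - gammaln(n_total - n_drawn + 1))
        )
        if n_total - k_present >= n_drawn
        else 1.0
    )
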