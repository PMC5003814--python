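"""Independent brute-force oracles, kept free of the implementation paths
they check: plain-Python sums-of-squares ANOVA, the Benjamini-Hochberg
step-up formula applied literally, exhaustive pairwise Ward agglomeration
from cluster centroids, and sort-and-cumsum abundance curves."""

import numpy as np
from scipy.stats import f as f_dist


def anova_oracle(group_a, group_b):
    """Two-group one-way ANOVA from first principles (plain Python sums)."""
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    grand = sum(a + b) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
    dof = na + nb - 2
    fstat = ssb / (ssw / dof)
    return fstat, float(f_dist.sf(fstat, 1, dof))


def bh_oracle(pvals):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def ward_oracle(points):
    """Greedy Ward agglomeration evaluating every cluster pair per step.

    At each step the merge minimizing the within-cluster sum-of-squares
    increase |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2 is taken.
    Returns (heights, partitions): heights on the same scale as scipy's
    ward linkage (sqrt of twice the increase), partitions as sets of
    frozensets of original point indices after each merge.
    """
    x = np.asarray(points, dtype=float)
    n = len(x)
    clusters = {i: [i] for i in range(n)}
    active = list(range(n))
    heights = []
    partitions = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                ca = x[clusters[a]].mean(axis=0)
                cb = x[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                inc = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or inc < best[0]:
                    best = (inc, a, b)
        inc, a, b = best
        clusters[next_id] = clusters[a] + clusters[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        heights.append(np.sqrt(2.0 * inc))
        partitions.append({frozenset(clusters[c]) for c in active})
        next_id += 1
    return heights, partitions


def partitions_from_linkage(z, n):
    """Partition sequence implied by a scipy linkage matrix."""
    clusters = {i: frozenset([i]) for i in range(n)}
    active = set(range(n))
    parts = []
    for t, row in enumerate(z):
        a, b = int(row[0]), int(row[1])
        merged = clusters[a] | clusters[b]
        clusters[n + t] = merged
        active -= {a, b}
        active.add(n + t)
        parts.append({clusters[c] for c in active})
    return parts


def cumulative_oracle(intensities):
    """Sort descending, cumulative sum, normalize by the total."""
    vals = sorted((float(v) for v in intensities), reverse=True)
    total = sum(vals)
    out = []
    running = 0.0
    for v in vals:
        running += v
        out.append(running / total)
    return np.asarray(out)
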