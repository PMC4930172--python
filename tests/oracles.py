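"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive loops, explicit path
enumeration, direct formula evaluation.  None of it shares code with the
package paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_motifs(edge_triples, tf_list, sde, allow_self_target=True):
    """Exhaustive O(M*T*G) triple loop over all (miRNA, TF, gene) combinations.

    ``edge_triples`` is a set of (source, target, edge_type).
    """
    edges = set(edge_triples)
    mirnas = {s for s, t, et in edges if et in ("mirna_gene", "mirna_tf")}
    mirnas |= {t for s, t, et in edges if et == "tf_mirna"}
    tfs = set(tf_list)
    genes = {t for s, t, et in edges if et in ("mirna_gene", "tf_gene")} | tfs
    found = []
    for m in sorted(mirnas):
        for t in sorted(tfs):
            for g in sorted(genes):
                if g in mirnas:
                    continue
                if g == t and not allow_self_target:
                    continue
                if t not in sde or g not in sde:
                    continue
                has_mt = (m, t, "mirna_tf") in edges
                has_tm = (t, m, "tf_mirna") in edges
                has_mg = (m, g, "mirna_gene") in edges or (m, g, "mirna_tf") in edges
                has_tg = (t, g, "tf_gene") in edges
                if has_mt and has_tm and has_mg and has_tg:
                    found.append((m, t, g))
    return sorted(found)


def brute_force_betweenness(nodes, undirected_edges):
    """BC over ordered pairs by explicit enumeration of every shortest path."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in undirected_edges:
        if u == v:
            continue
        adj[u].add(v)
        adj[v].add(u)

    def shortest_paths(s, t):
        # BFS layered search, then backtrack every geodesic
        from collections import deque

        dist = {s: 0}
        q = deque([s])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    q.append(y)
        if t not in dist:
            return []
        paths = []

        def back(path):
            x = path[-1]
            if x == t:
                paths.append(list(path))
                return
            for y in adj[x]:
                if dist.get(y) == dist[x] + 1 and dist[y] <= dist[t]:
                    back(path + [y])

        back([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    bc = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = shortest_paths(s, t)
            if not paths:
                continue
            total = len(paths)
            for n in nodes:
                if n in (s, t):
                    continue
                through = sum(1 for p in paths if n in p[1:-1])
                bc[n] += through / total
    return bc


def naive_complete_linkage_heights(X):
    """O(n^3) agglomeration with city-block distance; returns sorted merge heights."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    heights = []

    def d(i, j):
        return float(np.abs(X[i] - X[j]).sum())

    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            h = max(d(i, j) for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


def naive_pooled_t(case, ctrl):
    """Two-sample pooled-variance t statistic, written out longhand."""
    case = np.asarray(case, float)
    ctrl = np.asarray(ctrl, float)
    n1, n2 = len(case), len(ctrl)
    m1, m2 = case.mean(), ctrl.mean()
    sp2 = (((case - m1) ** 2).sum() + ((ctrl - m2) ** 2).sum()) / (n1 + n2 - 2)
    return (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def naive_bh(p):
    """Direct evaluation of the step-up definition, one q at a time."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[k - 1]] / k for k in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def hypergeom_tail(x, N, K, n):
    """Exact upper-tail sum of the hypergeometric pmf via log-binomials."""
    from math import comb

    if x <= 0:
        return 1.0
    denom = comb(N, n)
    total = 0
    for i in range(x, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def trapezoid_auc(fpr, tpr):
    return float(np.trapezoid(tpr, fpr))
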