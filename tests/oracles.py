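"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible (explicit loops,
no vectorization, no shared helpers with the package) so that agreement with
the package is meaningful evidence of correctness.
"""

from __future__ import annotations

import numpy as np


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up, literal definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, p[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def connectedness_brute(corrected):
    """Per-taxon mean of strictly positive / strictly negative entries."""
    n = corrected.shape[0]
    pos, neg = [], []
    for i in range(n):
        ps = [corrected[i, j] for j in range(n) if j != i and corrected[i, j] > 0]
        ns = [corrected[i, j] for j in range(n) if j != i and corrected[i, j] < 0]
        pos.append(sum(ps) / len(ps) if ps else 0.0)
        neg.append(sum(ns) / len(ns) if ns else 0.0)
    return np.array(pos), np.array(neg)


def cohesion_brute(rel, conn_pos, conn_neg):
    """Per-sample abundance-weighted cohesion sums."""
    n_taxa, n_samples = rel.shape
    cp, cn = [], []
    for s in range(n_samples):
        cp.append(sum(rel[i, s] * conn_pos[i] for i in range(n_taxa)))
        cn.append(sum(rel[i, s] * conn_neg[i] for i in range(n_taxa)))
    return np.array(cp), np.array(cn)


def null_corrected_brute(rel, iterations, seed):
    """Observed Pearson matrix minus taxon-shuffle null mean (loop form)."""
    rng = np.random.default_rng(seed)
    n, m = rel.shape

    def pearson_matrix(x):
        c = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                xi = x[i] - x[i].mean()
                xj = x[j] - x[j].mean()
                d = np.sqrt((xi**2).sum() * (xj**2).sum())
                c[i, j] = (xi * xj).sum() / d if d > 0 else 0.0
        return c

    obs = pearson_matrix(rel)
    acc = np.zeros((n, n))
    for _ in range(iterations):
        shuffled = np.empty_like(rel)
        for i in range(n):
            shuffled[i] = rel[i, rng.permutation(m)]
        acc += pearson_matrix(shuffled)
    out = obs - acc / iterations
    for i in range(n):
        out[i, i] = 0.0
    return out


def wmis_brute(i, alive, b, s):
    """Literal wMIS: sum_j b_j s_ij / sum_j b_j over other live nodes."""
    num = 0.0
    den = 0.0
    for j in alive:
        if j == i:
            continue
        num += b[j] * s[i][j]
        den += b[j]
    return num / den if den > 0 else 0.0


def cascade_brute(alive, b, s):
    """Synchronous extinction cascade with explicit rounds."""
    alive = set(alive)
    while True:
        dead = {i for i in alive if wmis_brute(i, alive, b, s) <= 0}
        if not dead:
            return alive
        alive -= dead


def cascade_sequential(alive, b, s, order):
    """Sequential-removal cascade: one non-positive node at a time."""
    alive = set(alive)
    while True:
        for i in sorted(alive, key=order.index):
            if wmis_brute(i, alive, b, s) <= 0:
                alive.discard(i)
                break
        else:
            return alive


def topology_brute(adj):
    """Topological coefficient / neighborhood connectivity / clustering."""
    n = len(adj)
    neigh = [set(j for j in range(n) if adj[i][j]) for i in range(n)]
    deg = [len(x) for x in neigh]
    tc, nc, cc = [], [], []
    for i in range(n):
        nc.append(sum(deg[j] for j in neigh[i]) / deg[i] if deg[i] else 0.0)
        if deg[i] >= 2:
            vals = []
            for m in range(n):
                if m == i:
                    continue
                shared = len(neigh[i] & neigh[m])
                if shared > 0:
                    vals.append((shared + (1 if adj[i][m] else 0)) / deg[i])
            tc.append(sum(vals) / len(vals) if vals else 0.0)
        else:
            tc.append(0.0)
        if deg[i] >= 2:
            links = sum(
                1 for a in neigh[i] for bb in neigh[i] if a < bb and adj[a][bb]
            )
            cc.append(2.0 * links / (deg[i] * (deg[i] - 1)))
        else:
            cc.append(0.0)
    return np.array(tc), np.array(nc), np.array(cc)


def modularity_brute(adj_weights, partition):
    """Newman weighted modularity of a given partition (loop form)."""
    n = len(adj_weights)
    two_m = sum(adj_weights[i][j] for i in range(n) for j in range(n))
    k = [sum(adj_weights[i][j] for j in range(n)) for i in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if partition[i] == partition[j]:
                q += adj_weights[i][j] - k[i] * k[j] / two_m
    return q / two_m


def hub_z_brute(adj, modules):
    """Within-module degree z-scores."""
    n = len(adj)
    within = [
        sum(1 for j in range(n) if adj[i][j] and modules[j] == modules[i])
        for i in range(n)
    ]
    z = [0.0] * n
    for mod in set(modules):
        idx = [i for i in range(n) if modules[i] == mod]
        ks = [within[i] for i in idx]
        mean = sum(ks) / len(ks)
        sd = (sum((x - mean) ** 2 for x in ks) / len(ks)) ** 0.5
        if len(idx) > 1 and sd > 0:
            for i in idx:
                z[i] = (within[i] - mean) / sd
    return np.array(z)


def efficiency_brute(adj):
    """Global efficiency via Floyd-Warshall hop distances."""
    n = len(adj)
    if n < 2:
        return 0.0
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    total = sum(
        1.0 / d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < inf
    )
    return total / (n * (n - 1))


def vulnerability_brute(adj):
    """Per-node (E - E_-i) / E with the node deleted."""
    n = len(adj)
    e = efficiency_brute(adj)
    out = []
    for v in range(n):
        keep = [i for i in range(n) if i != v]
        sub = [[adj[i][j] for j in keep] for i in keep]
        out.append((e - efficiency_brute(sub)) / e)
    return np.array(out), e


def levins_overlap_brute(p_i, p_j):
    """Symmetrized Levins overlap by direct summation."""
    pi = [x / sum(p_i) for x in p_i]
    pj = [x / sum(p_j) for x in p_j]
    cross = sum(a * b for a, b in zip(pi, pj))
    o_ij = cross / sum(a * a for a in pi)
    o_ji = cross / sum(b * b for b in pj)
    return 0.5 * (o_ij + o_ji)
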