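"""Independent brute-force reference implementations.

Everything here works from a full all-pairs shortest-path matrix computed
with scipy's csgraph routines on the dense adjacency matrix — a deliberately
different route from the package's per-source BFS — and spells out the
module-separation semantics with plain loops. Used only to cross-check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path


def distance_matrix(g: nx.Graph):
    """Full hop-distance matrix (inf for unreachable) and node index."""
    nodes = sorted(g.nodes)
    idx = {x: i for i, x in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1
    dm = shortest_path(adj, method="D", unweighted=True)
    return dm, idx


def brute_separation(g, A, B, method="nearest"):
    """Module separation from the full distance matrix, loops only."""
    dm, idx = distance_matrix(g)
    A, B = sorted(set(A)), sorted(set(B))

    def within(S):
        vals = []
        if method == "nearest":
            for x in S:
                ds = [dm[idx[x], idx[y]] for y in S if y != x]
                ds = [d for d in ds if np.isfinite(d)]
                if ds:
                    vals.append(min(ds))
        else:
            for x, y in combinations(S, 2):
                d = dm[idx[x], idx[y]]
                if np.isfinite(d):
                    vals.append(d)
        return vals

    def between():
        vals = []
        if method == "nearest":
            for side, other in ((A, B), (B, A)):
                for x in side:
                    ds = [dm[idx[x], idx[y]] for y in other]
                    ds = [d for d in ds if np.isfinite(d)]
                    if ds:
                        vals.append(min(ds))
        else:
            for x in A:
                for y in B:
                    if x == y:
                        continue
                    d = dm[idx[x], idx[y]]
                    if np.isfinite(d):
                        vals.append(d)
        return vals

    d_aa = float(np.mean(within(A)))
    d_bb = float(np.mean(within(B)))
    d_ab = float(np.mean(between()))
    return d_ab - (d_aa + d_bb) / 2.0


def brute_rank(g, A, B, method="nearest"):
    """Exhaustive candidate scores [(gene, score)], descending, no caching."""
    A, B = set(A), set(B)
    base = brute_separation(g, A, B, method)
    items = []
    for x in sorted(A ^ B):
        items.append((x, base - brute_separation(g, A | {x}, B | {x}, method)))
    items.sort(key=lambda t: (-t[1], t[0]))
    return items


def brute_best_subset(g, A, B, k, method="nearest"):
    """Exhaustive (genes, s_ab_plus) minimum over all k-subsets."""
    A, B = set(A), set(B)
    best = None
    for X in combinations(sorted(A ^ B), k):
        s = brute_separation(g, A | set(X), B | set(X), method)
        if best is None or s < best[1]:
            best = (frozenset(X), s)
    return best


def brute_auc(scores):
    """Concordant-pair fraction with half credit for ties."""
    pos = [s for s, y in scores if y]
    neg = [s for s, y in scores if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_threshold(scores):
    """Enumerate every cutoff; maximise TPR − FPR, ties to higher cutoff."""
    pos = [s for s, y in scores if y]
    neg = [s for s, y in scores if not y]
    best_cut, best_j = None, -np.inf
    for cut in sorted({s for s, _ in scores}, reverse=True):
        tpr = sum(p >= cut for p in pos) / len(pos)
        fpr = sum(n >= cut for n in neg) / len(neg)
        if tpr - fpr > best_j:
            best_j, best_cut = tpr - fpr, cut
    return best_cut


def random_connected_graph(rng, n_max=30):
    """Small random connected graph with string node labels."""
    n = int(rng.integers(6, n_max + 1))
    while True:
        p = min(1.0, float(rng.uniform(1.2, 2.5)) / n * 2)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if nx.is_connected(g):
            break
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def random_gene_sets(rng, g, min_size=2, max_size=6, overlap=True):
    """Two random gene sets (possibly overlapping) on g."""
    nodes = sorted(g.nodes)
    ka = int(rng.integers(min_size, max_size + 1))
    kb = int(rng.integers(min_size, max_size + 1))
    A = set(rng.choice(nodes, size=ka, replace=False).tolist())
    pool = nodes if overlap else [x for x in nodes if x not in A]
    B = set(rng.choice(pool, size=min(kb, len(pool)), replace=False).tolist())
    return A, B
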