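"""Independent brute-force oracles used to verify the library's graph metrics.

Everything here is written from the bare definitions (loops, enumeration,
Floyd-Warshall) and deliberately avoids the library code paths and the
networkx algorithms they delegate to.
"""

from itertools import combinations

import numpy as np


def brute_pearson(X: np.ndarray) -> np.ndarray:
    """Element-by-element Pearson correlation between columns of X."""
    n, k = X.shape
    R = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            xi, xj = X[:, i].astype(float), X[:, j].astype(float)
            dxi, dxj = xi - xi.mean(), xj - xj.mean()
            denom = np.sqrt((dxi ** 2).sum() * (dxj ** 2).sum())
            if denom > 0:
                R[i, j] = (dxi * dxj).sum() / denom
    return R


def brute_clustering(adj: np.ndarray) -> float:
    """Mean local clustering by enumerating neighbor pairs; deg<2 nodes
    contribute 0."""
    n = adj.shape[0]
    local = []
    for u in range(n):
        nbrs = [v for v in range(n) if adj[u, v]]
        k = len(nbrs)
        if k < 2:
            local.append(0.0)
            continue
        closed = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        local.append(closed / (k * (k - 1) / 2))
    return float(np.mean(local))


def brute_aspl(adj: np.ndarray) -> float:
    """Hop ASPL over the largest connected component via Floyd-Warshall."""
    n = adj.shape[0]
    D = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :])
    # largest component = largest set of mutually reachable nodes
    comps = []
    left = set(range(n))
    while left:
        u = next(iter(left))
        comp = {v for v in left if np.isfinite(D[u, v])}
        comps.append(comp)
        left -= comp
    comp = max(comps, key=len)
    idx = sorted(comp)
    if len(idx) < 2:
        return np.nan
    total = sum(D[a, b] for a, b in combinations(idx, 2))
    return float(total / (len(idx) * (len(idx) - 1) / 2))


def brute_max_spanning_tree_weight(nodes, edges) -> float:
    """Maximal total weight over all spanning trees, by enumerating all
    (n-1)-subsets of the edge list and keeping those that span acyclically."""
    n = len(nodes)
    best = -np.inf
    for subset in combinations(edges, n - 1):
        parent = {u: u for u in nodes}

        def find(u):
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        ok = True
        for u, v, _ in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = max(best, sum(w for _, _, w in subset))
    return best


def iter_partitions(items):
    """All set partitions of ``items`` (restricted-growth-string recursion)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def brute_modularity(nodes, edges, assignment, weighted=True) -> float:
    """Q from the definition, independent of the library implementation."""
    m = 0.0
    e = {}
    d = {}
    for u, v, w in edges:
        w = w if weighted else 1.0
        m += w
        if assignment[u] == assignment[v]:
            e[assignment[u]] = e.get(assignment[u], 0.0) + w
        d[assignment[u]] = d.get(assignment[u], 0.0) + w
        d[assignment[v]] = d.get(assignment[v], 0.0) + w
    if m == 0:
        return 0.0
    return sum(
        e.get(c, 0.0) / m - (d.get(c, 0.0) / (2 * m)) ** 2
        for c in set(assignment.values())
    )


def brute_best_modularity(nodes, edges, weighted=True) -> float:
    """Optimal modularity by exhausting every partition of the node set."""
    best = -np.inf
    for part in iter_partitions(nodes):
        assignment = {u: i for i, grp in enumerate(part) for u in grp}
        best = max(best, brute_modularity(nodes, edges, assignment, weighted))
    return best


def random_graph_adj(rng, n, p) -> np.ndarray:
    """Symmetric 0/1 adjacency with independent edges."""
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T
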