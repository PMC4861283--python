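"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written from scratch against the
*definitions* (dense loops, exact integer arithmetic, brute-force
agglomeration) and never calls the implementation paths it validates.
"""

from __future__ import annotations

from math import comb

import numpy as np

# ---------------------------------------------------------------------------
# naive dense MCL

def dense_mcl_oracle(graph, inflation=2.0, expansion=2, self_loops=True,
                     prune_threshold=1e-5, max_iter=200, tol=1e-6):
    """Straightforward dense-matrix MCL; returns (clusters, unclustered).

    Same process definition as the library (expand, inflate, prune with
    column-max preservation, renormalise; attractor-system readout with
    lexicographic tie-break) but implemented with dense numpy arrays and
    plain loops.
    """
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        w = float(d.get("weight", 1.0))
        A[idx[u], idx[v]] = w
        A[idx[v], idx[u]] = w
    connected = [i for i in range(n) if (A[i] != 0).any()]
    unclustered = sorted(nodes[i] for i in range(n) if i not in set(connected))
    if not connected:
        return [], unclustered
    A = A[np.ix_(connected, connected)]
    m = len(connected)
    if self_loops:
        for j in range(m):
            A[j, j] = A[:, j].max()
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        prev = M.copy()
        P = np.linalg.matrix_power(M, expansion)
        P = P ** inflation
        for j in range(m):
            col = P[:, j]
            floor = min(col.max(), prune_threshold)
            col[col < floor] = 0.0
        M = P / P.sum(axis=0)
        if np.abs(M - prev).max() < tol:
            break

    attractors = [i for i in range(m) if M[i, i] > 0]
    att = set(attractors)
    # union attractor systems
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in attractors:
        for j in attractors:
            if i < j and (M[i, j] > 0 or M[j, i] > 0):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    assignment = {a: find(a) for a in attractors}
    for j in range(m):
        if j in assignment:
            continue
        pulls = [i for i in attractors if M[i, j] > 0]
        assignment[j] = find(min(pulls)) if pulls else j
    groups: dict = {}
    for j, root in assignment.items():
        groups.setdefault(root, []).append(j)
    clusters = [sorted(nodes[connected[j]] for j in grp)
                for grp in groups.values()]
    return clusters, unclustered


def partition_key(clusters):
    return frozenset(frozenset(c) for c in clusters)


# ---------------------------------------------------------------------------
# exact Fisher two-sided p by integer enumeration

def fisher_oracle(a: int, la: int, b: int, lb: int) -> float:
    """Two-sided Fisher p via exact integer hypergeometric enumeration.

    The tie slack (1 + 1e-7) is applied in exact rational arithmetic.
    """
    m = a + b
    lo, hi = max(0, m - lb), min(la, m)
    nums = [comb(la, k) * comb(lb, m - k) for k in range(lo, hi + 1)]
    denom = comb(la + lb, m)
    obs = nums[a - lo]
    total = sum(x for x in nums if x * 10**7 <= obs * (10**7 + 1))
    return total / denom


def fisher_oracle_family(la: int, lb: int, m: int) -> list:
    """p for every table with row margins (la, lb) and first-column m."""
    lo, hi = max(0, m - lb), min(la, m)
    nums = [comb(la, k) * comb(lb, m - k) for k in range(lo, hi + 1)]
    denom = comb(la + lb, m)
    order = sorted(range(len(nums)), key=lambda i: nums[i])
    sorted_nums = [nums[i] for i in order]
    prefix = []
    run = 0
    for x in sorted_nums:
        run += x
        prefix.append(run)
    out = []
    import bisect
    for a in range(lo, hi + 1):
        threshold = nums[a - lo] * (10**7 + 1)
        # count entries x with x * 1e7 <= threshold
        pos = bisect.bisect_right([x * 10**7 for x in sorted_nums], threshold)
        out.append(prefix[pos - 1] / denom)
    return out


# ---------------------------------------------------------------------------
# brute-force average-linkage agglomeration

def average_linkage_oracle(dist: np.ndarray):
    """O(n^3) agglomeration; returns the merge sequence.

    Each merge is (member frozenset A, member frozenset B, height).
    Ties in minimal distance break toward the pair with the smallest
    member indices (matching scipy's deterministic ordering on distinct
    distances; tests use generic distances without ties).
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        a, b = clusters.pop(i), clusters.pop(j)
        merges.append((a, b, h))
        new = a | b
        for k in list(clusters):
            key_i = (min(i, k), max(i, k))
            key_j = (min(j, k), max(j, k))
            dik, djk = d.pop(key_i), d.pop(key_j)
            d[(min(next_id, k), max(next_id, k))] = (
                len(a) * dik + len(b) * djk) / (len(a) + len(b))
        del d[(i, j)]
        clusters[next_id] = new
        next_id += 1
    return merges


# ---------------------------------------------------------------------------
# t-density integration (df = 6) for the correlation p-value

def corr_pvalue_by_integration(r: float, n: int = 8) -> float:
    """Two-sided correlation p by numerical integration of the t density."""
    from scipy.integrate import quad
    from math import gamma, sqrt, pi

    df = n - 2
    c = gamma((df + 1) / 2) / (gamma(df / 2) * sqrt(df * pi))

    def pdf(t):
        return c * (1 + t * t / df) ** (-(df + 1) / 2)

    a = abs(r)
    if a >= 1:
        return 0.0
    t0 = a * sqrt(df / (1 - a * a))
    tail, _ = quad(pdf, t0, np.inf, epsabs=1e-13, epsrel=1e-13)
    return 2.0 * tail


# ---------------------------------------------------------------------------
# random additive trees for NJ checks

def random_additive_tree(rng, n_taxa: int):
    """Random binary tree with uniform branch lengths; returns
    (labels, distance matrix) computed by path enumeration."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start with a star of 3, then attach remaining taxa to random edges
    # represent tree as adjacency dict of node -> {nbr: length}
    adj: dict = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def del_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    internal = ["i0"]
    for t in labels[:3]:
        add_edge("i0", t, rng.uniform(0.1, 1.0))
    for k, t in enumerate(labels[3:], start=1):
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid = f"i{k}"
        split = rng.uniform(0.2, 0.8) * w
        del_edge(u, v)
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(mid, t, rng.uniform(0.1, 1.0))
        internal.append(mid)
    # all-pairs leaf distances by DFS
    n = len(labels)
    dist = np.zeros((n, n))
    for i, a in enumerate(labels):
        seen = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        for j, b in enumerate(labels):
            dist[i, j] = seen[b]
    return labels, dist
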