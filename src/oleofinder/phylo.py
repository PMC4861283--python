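"""Neighbor-joining gene-family trees with duplication labeling.

The tree workflow mirrors classic distance phylogenetics of protein
families: pairwise distances from an alignment (p-distance or its
Poisson correction), Saitou-Nei neighbor joining, nonparametric
bootstrap over alignment columns, midpoint rooting, and the
species-overlap rule for events — an internal node of the rooted gene
tree is a *duplication* when its child subtrees share at least one
species, and a *speciation* otherwise.

NJ here is exact on additive matrices (topology and branch lengths are
recovered to numerical precision) and fully deterministic: ties on the
Q criterion break toward the lexicographically smallest taxon pair.
Negative branch lengths, which NJ can produce on non-additive input,
are kept (and can be clamped for display) so additivity checks stay
meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Node", "DistanceMatrix", "protein_distance", "neighbor_joining",
           "bootstrap_support", "label_duplications", "midpoint_root",
           "read_newick", "write_newick", "path_length_matrix",
           "bipartitions"]

_GAPS = frozenset("-.")
_SPECIES_TAG = re.compile(r"^([^_|]+)[_|]")


@dataclass
class Node:
    """A node of a (gene) tree.

    ``length`` is the branch to the parent (None at the root),
    ``support`` the bootstrap percentage of that branch, ``event`` one of
    ``leaf``/``speciation``/``duplication`` once labeled.
    """

    name: str | None = None
    length: float | None = None
    support: float | None = None
    event: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())


@dataclass
class DistanceMatrix:
    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("negative distances")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# distances

def protein_distance(
    records: Sequence[tuple[str, str]],
    model: str = "poisson",
) -> DistanceMatrix:
    """Pairwise distances from an aligned protein set.

    ``records`` are (name, aligned sequence) pairs of equal length.  Gap
    sites ('-' or '.') are deleted pairwise.  ``model="p"`` gives the raw
    mismatch proportion; ``"poisson"`` applies the -ln(1 - p) correction
    for multiple hits.
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    names = [n for n, _ in records]
    seqs = [s.upper() for _, s in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    L = {len(s) for s in seqs}
    if len(L) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s) for s in seqs])
    gap = np.isin(arr, list(_GAPS))
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            sites = int(ok.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable sites for pair ({names[i]}, {names[j]})")
            p = float((arr[i, ok] != arr[j, ok]).sum() / sites)
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair ({names[i]}, {names[j]}): p = 1")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=tuple(names), values=d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree represented with a trifurcating root (the
    final three-way join).  On an additive matrix the path-length matrix
    of the result reproduces the input exactly (up to float error).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(float).copy()
    nodes = [Node(name=lbl, event="leaf") for lbl in dm.labels]
    # representative label per active node for deterministic tie-breaks
    reps = [str(lbl) for lbl in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in cand if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        new = Node(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining actives
        knew = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            D[knew, ak] = D[ak, knew] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [a for a in active if a not in (i, j)] + [knew]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, l in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = l
    order = sorted(range(3), key=lambda t: reps[active[t]])
    return Node(children=[nodes[active[t]] for t in order])


def path_length_matrix(tree: Node, labels: Sequence | None = None) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (additivity oracle input)."""
    if labels is None:
        labels = sorted(tree.leaf_names())
    idx = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def below(node: Node) -> dict:
        if node.is_leaf:
            return {idx[node.name]: 0.0}
        maps = []
        for c in node.children:
            sub = below(c)
            maps.append({k: v + (c.length or 0.0) for k, v in sub.items()})
        for x in range(len(maps)):
            for y in range(x + 1, len(maps)):
                for li, di in maps[x].items():
                    for lj, dj in maps[y].items():
                        d[li, lj] = d[lj, li] = di + dj
        merged: dict = {}
        for mp in maps:
            merged.update(mp)
        return merged

    below(tree)
    return DistanceMatrix(labels=tuple(labels), values=d)


def bipartitions(tree: Node) -> set[frozenset]:
    """Canonical non-trivial leaf bipartitions (smaller side) of a tree."""
    all_leaves = tree.leaf_names()
    n = len(all_leaves)
    out = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if len(side) < 2 or len(side) > n - 2:
            continue
        other = all_leaves - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    records: Sequence[tuple[str, str]],
    n_reps: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> Node:
    """NJ tree with column-bootstrap support on internal branches.

    Alignment columns are resampled with replacement ``n_reps`` times;
    the support of an internal branch is the percentage of replicate
    trees containing the same leaf bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(protein_distance(records, model=model))
    counts: dict = {bp: 0 for bp in bipartitions(tree)}
    names = [n for n, _ in records]
    L = len(records[0][1])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = [
            (nm, "".join(seq[c] for c in cols)) for nm, seq in records
        ]
        try:
            rep_tree = neighbor_joining(protein_distance(resampled, model=model))
        except ValueError:
            continue  # saturated or degenerate replicate carries no vote
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    all_leaves = tree.leaf_names()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        canon = min(side, all_leaves - side,
                    key=lambda s: (len(s), tuple(sorted(s))))
        if canon in counts:
            node.support = 100.0 * counts[canon] / n_reps
    return tree


# ---------------------------------------------------------------------------
# rooting and duplication labeling

def _adjacency(tree: Node) -> tuple[dict, dict]:
    """Undirected adjacency of a tree; nodes keyed by id."""
    adj: dict = {}
    objs: dict = {}

    def walk(node: Node):
        objs[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            walk(c)
            w = c.length or 0.0
            adj[id(node)].append((id(c), w, c.support))
            adj.setdefault(id(c), []).append((id(node), w, c.support))

    walk(tree)
    return adj, objs


def midpoint_root(tree: Node) -> Node:
    """Re-root at the midpoint of the longest leaf-to-leaf path."""
    adj, objs = _adjacency(tree)
    leaves = [i for i, nbrs in adj.items() if objs[i].is_leaf]

    def far(start: int) -> dict:
        dist = {start: 0.0}
        prev = {start: None}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w, _ in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = None
    for a in leaves:
        dist, prev = far(a)
        b = max(leaves, key=lambda l: (dist[l], str(objs[l].name)))
        if best is None or dist[b] > best[0]:
            best = (dist[b], a, b, prev)
    total, a, b, prev = best
    # walk from b back to a, find the edge holding the midpoint
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    half = total / 2.0
    acc = 0.0
    for u, v in zip(path, path[1:]):
        w = next(wt for nb, wt, _ in adj[u] if nb == v)
        if acc + w >= half - 1e-12:
            off = half - acc  # distance from u toward v
            return _reroot_on_edge(adj, objs, u, v, off, w)
        acc += w
    # degenerate (zero-length tree): root above b
    return _reroot_on_edge(adj, objs, b, path[1],
                           0.0, next(wt for nb, wt, _ in adj[b]))


def _reroot_on_edge(adj, objs, u, v, off, w) -> Node:
    def build(node_id: int, parent_id, length, support) -> Node:
        src = objs[node_id]
        kids = [build(nb, node_id, wt, sup) for nb, wt, sup in adj[node_id]
                if nb != parent_id]
        return Node(name=src.name, length=length, support=support,
                    event=src.event if src.is_leaf else None, children=kids)

    left = build(u, v, off, None)
    right = build(v, u, w - off, None)
    return Node(children=[left, right])


def label_duplications(
    tree: Node,
    species_pattern: str | re.Pattern = _SPECIES_TAG,
) -> tuple[Node, int]:
    """Label internal nodes by the species-overlap rule.

    Leaf species are parsed from leaf names with ``species_pattern``
    (default: prefix before the first underscore or pipe).  An internal
    node is a duplication when any two of its children's species sets
    intersect.  Returns the labeled tree and the duplication count.
    ``tree`` must be rooted (apply :func:`midpoint_root` first if not).
    """
    rx = re.compile(species_pattern)
    n_dup = 0
    species_below: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            m = rx.match(str(node.name))
            if not m:
                raise ValueError(
                    f"cannot parse species tag from leaf {node.name!r}")
            node.event = "leaf"
            species_below[id(node)] = frozenset([m.group(1)])
            continue
        sets = [species_below[id(c)] for c in node.children]
        overlap = any(
            sets[i] & sets[j]
            for i in range(len(sets)) for j in range(i + 1, len(sets))
        )
        node.event = "duplication" if overlap else "speciation"
        if overlap:
            n_dup += 1
        species_below[id(node)] = frozenset().union(*sets)
    return tree, n_dup


# ---------------------------------------------------------------------------
# newick

def write_newick(tree: Node, decimals: int = 10) -> str:
    def render(node: Node) -> str:
        if node.is_leaf:
            label = node.name or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            if node.support is not None:
                label = f"({inner}){node.support:g}"
            else:
                label = f"({inner}){node.name or ''}"
        if node.length is not None:
            label += f":{node.length:.{decimals}g}"
        return label

    return render(tree) + ";"


def read_newick(text: str) -> Node:
    """Parse a newick string; internal numeric labels become supports."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str):
        raise ValueError(f"newick parse error at position {pos}: {msg}")

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    error("unexpected end inside group")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ":,();":
            pos += 1
        label = s[start:pos]
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}")
        if node.is_leaf:
            node.event = "leaf"
        return node

    root = parse_node()
    if pos != len(s):
        error("trailing characters")
    return root
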