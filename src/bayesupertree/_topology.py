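"""Canonical tree-topology primitives.

Topologies are immutable nested tuples so they can be hashed, compared and
deduplicated exactly.  Leaves are integers (indices into an external label
list).  A rooted binary topology is either a leaf ``int`` or a pair
``(left, right)`` with children in canonical order.  An unrooted binary
topology on >= 3 leaves is a triple ``(m, A, B)`` where ``m`` is the smallest
leaf index and ``A``, ``B`` are the two canonically ordered rooted subtrees
hanging off the internal node adjacent to ``m``.

Everything downstream (reconciliation scoring, MCMC moves, enumeration
oracles) is built on these forms, so canonical equality is string-free and
stable across processes.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator, Sequence


# ---------------------------------------------------------------------------
# canonical ordering
#
# struct_key / canon_rooted are memoized: MCMC proposals canonicalize the
# same subtrees millions of times.

@lru_cache(maxsize=1 << 17)
def struct_key(s):
    """Total order on rooted structs: leaves before internals, then recursive."""
    if isinstance(s, int):
        return (0, s)
    return (1, struct_key(s[0]), struct_key(s[1]))


@lru_cache(maxsize=1 << 17)
def canon_rooted(s):
    """Return the canonical form of a rooted struct (children sorted)."""
    if isinstance(s, int):
        return s
    a = canon_rooted(s[0])
    b = canon_rooted(s[1])
    if struct_key(a) <= struct_key(b):
        return (a, b)
    return (b, a)


def leaves_of(s) -> tuple:
    """Sorted tuple of leaf indices of a rooted or unrooted struct."""
    out = []

    def rec(t):
        if isinstance(t, int):
            out.append(t)
        else:
            for c in t:
                rec(c)

    if isinstance(s, tuple) and len(s) == 3:
        out.append(s[0])
        rec(s[1])
        rec(s[2])
    else:
        rec(s)
    return tuple(sorted(out))


def n_leaves(s) -> int:
    return len(leaves_of(s))


# ---------------------------------------------------------------------------
# rooted <-> unrooted

def unroot(rooted):
    """Canonical unrooted topology obtained by suppressing the root node.

    For two leaves returns the sorted pair; requires a binary rooted struct.
    """
    if isinstance(rooted, int):
        raise ValueError("cannot unroot a single leaf")
    labels = leaves_of(rooted)
    if len(labels) == 2:
        return (labels[0], labels[1])
    adj, leaf_label = _struct_adjacency(rooted, suppress_root=True)
    return _canon_unrooted_from_adj(adj, leaf_label)


def _struct_adjacency(rooted, suppress_root=False):
    """Adjacency map {node_id: [neighbor ids]} plus {node_id: leaf label}."""
    adj: dict[int, list[int]] = {}
    leaf_label: dict[int, int] = {}
    counter = [0]

    def new_node():
        i = counter[0]
        counter[0] += 1
        adj[i] = []
        return i

    def build(t):
        nid = new_node()
        if isinstance(t, int):
            leaf_label[nid] = t
        else:
            for c in t:
                cid = build(c)
                adj[nid].append(cid)
                adj[cid].append(nid)
        return nid

    root = build(rooted)
    if suppress_root:
        a, b = adj[root]
        adj[a] = [x for x in adj[a] if x != root]
        adj[b] = [x for x in adj[b] if x != root]
        adj[a].append(b)
        adj[b].append(a)
        del adj[root]
    return adj, leaf_label


def _canon_unrooted_from_adj(adj, leaf_label):
    inv = {lab: nid for nid, lab in leaf_label.items()}
    m = min(leaf_label.values())
    mnode = inv[m]
    hub = adj[mnode][0]

    def build(nid, parent):
        if nid in leaf_label:
            return leaf_label[nid]
        kids = [build(c, nid) for c in adj[nid] if c != parent]
        assert len(kids) == 2
        a, b = kids
        if struct_key(a) <= struct_key(b):
            return (a, b)
        return (b, a)

    subs = sorted((build(c, hub) for c in adj[hub] if c != mnode), key=struct_key)
    return (m, subs[0], subs[1])


class UnrootedIndex:
    """Deterministic node/edge indexing of a canonical unrooted topology.

    Nodes are numbered in DFS discovery order starting from the minimum leaf;
    edges are listed in discovery order.  Edge indices are the tie-break
    ordering used when reporting optimal gene-tree roots.
    """

    __slots__ = ("struct", "n_nodes", "leaf_label", "neighbors", "edges")

    def __init__(self, unrooted):
        self.struct = unrooted
        self.leaf_label: dict[int, int] = {}
        self.neighbors: list[list[int]] = []
        self.edges: list[tuple[int, int]] = []
        m, A, B = unrooted

        def new_node(label=None):
            nid = len(self.neighbors)
            self.neighbors.append([])
            if label is not None:
                self.leaf_label[nid] = label
            return nid

        def link(u, v):
            self.neighbors[u].append(v)
            self.neighbors[v].append(u)
            self.edges.append((u, v))

        def build(t, parent):
            if isinstance(t, int):
                nid = new_node(t)
            else:
                nid = new_node()
            link(parent, nid)
            if not isinstance(t, int):
                build(t[0], nid)
                build(t[1], nid)
            return nid

        mnode = new_node(m)
        hub = new_node()
        link(mnode, hub)
        build(A, hub)
        build(B, hub)
        self.n_nodes = len(self.neighbors)

    @property
    def n_leaves(self):
        return len(self.leaf_label)

    def root_at_edge(self, e: int):
        """Rooted canonical struct obtained by placing the root on edge e."""
        u, v = self.edges[e]
        return canon_rooted((self._subtree(u, v), self._subtree(v, u)))

    def _subtree(self, away, toward):
        """Struct of the subtree at node ``away`` looking away from ``toward``."""
        if away in self.leaf_label:
            return self.leaf_label[away]
        kids = [self._subtree(c, away) for c in self.neighbors[away] if c != toward]
        return (kids[0], kids[1])


# ---------------------------------------------------------------------------
# enumeration (used by oracles, partition functions, exhaustive searches)

def enumerate_rooted(labels: Sequence[int]) -> Iterator[tuple]:
    """All (2n-3)!! rooted binary topologies on the given leaf labels."""
    labels = sorted(labels)
    if not labels:
        return
    if len(labels) == 1:
        yield labels[0]
        return

    def insert_all(t, leaf):
        # yield every struct obtained by attaching `leaf` on an edge of t,
        # including the root stem
        yield canon_rooted((t, leaf))
        if not isinstance(t, int):
            for i, c in enumerate(t):
                other = t[1 - i]
                for sub in insert_all(c, leaf):
                    yield canon_rooted((sub, other))

    def rec(tree, rest):
        if not rest:
            yield tree
            return
        leaf, tail = rest[0], rest[1:]
        for t2 in insert_all(tree, leaf):
            yield from rec(t2, tail)

    yield from rec(labels[0], labels[1:])


def enumerate_unrooted(labels: Sequence[int]) -> Iterator[tuple]:
    """All (2n-5)!! unrooted binary topologies on >= 3 leaf labels."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves for an unrooted topology")
    seen = set()
    # unrooted topologies on n leaves == rooted topologies on n-1 leaves with
    # the last leaf attached at the root; enumerate rooted on labels[1:] and
    # hang labels[0] off the root
    for t in enumerate_rooted(labels[1:]):
        u = unroot(canon_rooted((t, labels[0])))
        if u not in seen:
            seen.add(u)
            yield u


def count_rooted(n: int) -> int:
    """(2n-3)!!, the number of rooted binary labeled topologies."""
    if n < 1:
        raise ValueError("n must be positive")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def random_rooted(labels: Sequence[int], rng) -> tuple:
    """Uniform random rooted binary topology via sequential edge insertion."""
    labels = sorted(labels)
    tree = labels[0]
    for k, leaf in enumerate(labels[1:], start=2):
        edges = 2 * (k - 1) - 1  # edges incl. root stem of a (k-1)-leaf tree
        target = int(rng.integers(edges))
        tree = _insert_at(tree, leaf, target)
    return canon_rooted(tree)


def _insert_at(t, leaf, idx):
    """Attach leaf on the idx-th edge (preorder, root stem first)."""
    done, out = _insert_rec(t, leaf, idx)
    assert done is True
    return out


def _insert_rec(t, leaf, idx):
    if idx == 0:
        return True, (t, leaf)
    idx -= 1
    if isinstance(t, int):
        return idx, None
    res, sub = _insert_rec(t[0], leaf, idx)
    if res is True:
        return True, (sub, t[1])
    res, sub = _insert_rec(t[1], leaf, res)
    if res is True:
        return True, (t[0], sub)
    return res, None


def random_unrooted(labels: Sequence[int], rng) -> tuple:
    labels = sorted(labels)
    return unroot(canon_rooted((random_rooted(labels[1:], rng), labels[0])))


# ---------------------------------------------------------------------------
# splits / clades

def rooted_clades(s) -> set[frozenset]:
    """All non-root, non-leaf clades (as frozensets of leaf indices)."""
    out = set()

    def rec(t):
        if isinstance(t, int):
            return frozenset((t,))
        cl = rec(t[0]) | rec(t[1])
        out.add(cl)
        return cl

    rec(s)
    out.discard(frozenset(leaves_of(s)))
    return out


def unrooted_splits(s) -> set[frozenset]:
    """Nontrivial splits of a topology, unrooted interpretation.

    Each split is represented by the side not containing the minimum leaf.
    Accepts rooted or unrooted structs.
    """
    if isinstance(s, tuple) and len(s) == 3:
        m, A, B = s
        rooted = canon_rooted(((A, B), m))
    else:
        rooted = s
    all_leaves = frozenset(leaves_of(rooted))
    mleaf = min(all_leaves)
    n = len(all_leaves)
    out = set()

    def rec(t):
        if isinstance(t, int):
            return frozenset((t,))
        cl = rec(t[0]) | rec(t[1])
        side = cl if mleaf not in cl else all_leaves - cl
        if 2 <= len(side) <= n - 2:
            out.add(side)
        return cl

    rec(rooted)
    return out


# ---------------------------------------------------------------------------
# tree moves (species-tree proposals, uncertainty generator)

def rooted_nni_moves(s) -> list[tuple]:
    """Rooted NNI rearrangements of a binary rooted topology, one entry per
    raw swap (constant count 2(n-2): each internal edge (p, v) admits two
    swaps exchanging a child of v with v's sibling).  Sampling uniformly from
    this fixed-size list gives a symmetric kernel; callers that need the
    distinct neighborhood should deduplicate."""
    out = []
    _nni_rec(s, out)
    return [canon_rooted(x) for x in out]


def _nni_rec(t, out):
    """Append every raw NNI variant of rooted struct t to out."""
    if isinstance(t, int):
        return
    a, b = t
    if not isinstance(a, int):
        a1, a2 = a
        out.append(((a1, b), a2))
        out.append(((a2, b), a1))
    if not isinstance(b, int):
        b1, b2 = b
        out.append(((b1, a), b2))
        out.append(((b2, a), b1))
    sub = []
    _nni_rec(a, sub)
    out.extend((v, b) for v in sub)
    sub = []
    _nni_rec(b, sub)
    out.extend((a, v) for v in sub)


def all_rootings(unrooted) -> list[tuple]:
    """Every rooted topology compatible with the given unrooted one."""
    idx = UnrootedIndex(unrooted)
    seen = []
    got = set()
    for e in range(len(idx.edges)):
        r = idx.root_at_edge(e)
        if r not in got:
            got.add(r)
            seen.append(r)
    return seen


def reroot_moves(rooted) -> list[tuple]:
    """All rerootings of the same unrooted topology, excluding the input."""
    if n_leaves(rooted) < 3:
        return []
    u = unroot(rooted)
    cur = canon_rooted(rooted)
    return [r for r in all_rootings(u) if r != cur]


def spr_moves(rooted) -> list[tuple]:
    """All distinct rooted-SPR rearrangements (prune a subtree, regraft on
    another edge, root stem included).  Returned without duplicates; the
    proposal kernel uses |spr_moves| counts for the Hastings ratio."""
    cur = canon_rooted(rooted)
    out = set()
    subtrees = _proper_subtrees(cur)
    for sub in subtrees:
        rest = _remove_subtree(cur, sub)
        if rest is None:
            continue
        for t2 in _attach_everywhere(rest, sub):
            c = canon_rooted(t2)
            if c != cur:
                out.add(c)
    return sorted(out, key=struct_key)


def _proper_subtrees(t):
    """All subtrees of t except t itself (as structs, may repeat shapes)."""
    out = []

    def rec(x, is_root):
        if not is_root:
            out.append(x)
        if not isinstance(x, int):
            rec(x[0], False)
            rec(x[1], False)

    rec(t, True)
    return out


def _remove_subtree(t, sub):
    """Remove the first occurrence of `sub`; suppress the resulting unary
    node.  Returns None if sub is a direct child of a 2-leaf tree root."""

    def rec(x):
        if isinstance(x, int):
            return None
        a, b = x
        if a == sub:
            return b
        if b == sub:
            return a
        ra = rec(a)
        if ra is not None:
            return (ra, b)
        rb = rec(b)
        if rb is not None:
            return (a, rb)
        return None

    return rec(t)


def _attach_everywhere(t, sub):
    """Yield structs attaching `sub` on every edge of t plus the root stem."""
    yield (t, sub)
    if not isinstance(t, int):
        a, b = t
        for v in _attach_everywhere(a, sub):
            yield (v, b)
        for v in _attach_everywhere(b, sub):
            yield (a, v)


def unrooted_nni_alternatives(unrooted, internal_edge_split: frozenset):
    """The two NNI alternatives of an unrooted topology around the internal
    edge whose split (side without min leaf) is `internal_edge_split`."""
    idx = UnrootedIndex(unrooted)
    # locate the edge with this split
    all_leaves = frozenset(idx.leaf_label.values())
    mleaf = min(all_leaves)
    for e, (u, v) in enumerate(idx.edges):
        if u in idx.leaf_label or v in idx.leaf_label:
            continue
        side = frozenset(_leafset_away(idx, v, u))
        if mleaf in side:
            side = all_leaves - side
        if side == internal_edge_split:
            return _nni_at_edge(idx, e)
    raise ValueError("no internal edge with the requested split")


def _leafset_away(idx, away, toward):
    out = []
    stack = [(away, toward)]
    while stack:
        node, par = stack.pop()
        if node in idx.leaf_label:
            out.append(idx.leaf_label[node])
        else:
            for nb in idx.neighbors[node]:
                if nb != par:
                    stack.append((nb, node))
    return out


def internal_edge_ids(idx: UnrootedIndex) -> list[int]:
    return [
        e
        for e, (u, v) in enumerate(idx.edges)
        if u not in idx.leaf_label and v not in idx.leaf_label
    ]


def _nni_at_edge(idx: UnrootedIndex, e: int):
    """Two unrooted NNI alternatives across internal edge e of idx."""
    u, v = idx.edges[e]
    usubs = [idx._subtree(c, u) for c in idx.neighbors[u] if c != v]
    vsubs = [idx._subtree(c, v) for c in idx.neighbors[v] if c != u]
    a, b = usubs
    c, d = vsubs
    # original arrangement is (a,b)|(c,d); the two alternatives swap across
    return [
        unroot(canon_rooted(((a, c), (b, d)))),
        unroot(canon_rooted(((a, d), (b, c)))),
    ]


def unrooted_nni_neighbors(unrooted) -> list[tuple]:
    """All unrooted NNI neighbors (2 per internal edge, deduplicated)."""
    idx = UnrootedIndex(unrooted)
    out = set()
    for e in internal_edge_ids(idx):
        for t in _nni_at_edge(idx, e):
            if t != unrooted:
                out.add(t)
    return sorted(out, key=lambda s: struct_key((s[0], (s[1], s[2]))))


# ---------------------------------------------------------------------------
# newick

def to_newick(struct, names, lengths=None) -> str:
    """Serialize a rooted struct (or canonical unrooted triple) to Newick."""

    def rec(t):
        if isinstance(t, int):
            return names[t]
        return "(" + ",".join(rec(c) for c in t) + ")"

    if isinstance(struct, tuple) and len(struct) == 3:
        m, A, B = struct
        return "(" + ",".join([names[m], rec(A), rec(B)]) + ");"
    return rec(struct) + ";"
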