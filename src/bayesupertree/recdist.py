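"""Gene-tree / species-tree disagreement measures.

Four distances between an unrooted gene-family tree G (possibly with several
leaves per species) and a rooted species tree S:

* ``d1`` duplications and ``d2`` losses of the most parsimonious
  duplication-loss reconciliation under the LCA mapping, minimized jointly
  over every rooting of G (optimal root ``r*``);
* ``d3`` deep coalescences (extra lineages), minimized over rootings
  (optimal root ``r**``, which may differ from ``r*``);
* ``d4`` the mulRF distance: symmetric difference of species-label-multiset
  bipartitions between unrooted G and the species tree extended with one
  multifurcation per multi-copy species.

The species tree is restricted to the induced subtree on the family's
species before any computation, so species unsampled by a family do not
inflate loss counts.

The all-rootings minimization runs in O(n) per (G, S) pair via a directed
edge dynamic program: every directed edge (t -> h) stores the LCA map and
the accumulated duplication/loss/coalescence contributions of the subtree at
h away from t, and each rooting combines two opposite directed edges plus a
root term.  A brute-force per-rooting oracle in the test-suite pins this
down on small trees.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _topology as top

try:  # JIT acceleration for the inner reconciliation loops
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@dataclass(frozen=True)
class DistanceVector:
    """(d1..d4) for one gene tree against one species tree."""

    dups: int
    losses: int
    deep_coal: int
    mulrf: int | None
    r_star: int
    r_star2: int

    def as_tuple(self, model: str = "DLIR") -> tuple:
        if model == "DLI":
            return (self.dups, self.losses, self.deep_coal)
        if model == "DLIR":
            if self.mulrf is None:
                raise ValueError("mulRF not computed")
            return (self.dups, self.losses, self.deep_coal, self.mulrf)
        raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# species tree indexing


@njit(cache=False)
def _lca_table_flat(parent, depth):
    n = parent.shape[0]
    lca = np.empty(n * n, np.int32)
    for u in range(n):
        lca[u * n + u] = u
        for v in range(u):
            a, b = u, v
            while a != b:
                if depth[a] >= depth[b]:
                    a = parent[a]
                else:
                    b = parent[b]
            lca[u * n + v] = a
            lca[v * n + u] = a
    return lca


class SpeciesIndex:
    """Rooted species-tree arrays: parents, depths and an LCA table."""

    __slots__ = ("struct", "n_leaves", "n_nodes", "parent", "depth",
                 "leaf_node", "lca", "lca_flat", "depth_arr", "_usplits")

    def __init__(self, struct):
        self.struct = top.canon_rooted(struct)
        parent: list[int] = []
        depth: list[int] = []
        leaf_node: dict[int, int] = {}

        def build(t, par, dep):
            nid = len(parent)
            parent.append(par)
            depth.append(dep)
            if isinstance(t, int):
                leaf_node[t] = nid
            else:
                build(t[0], nid, dep + 1)
                build(t[1], nid, dep + 1)
            return nid

        build(self.struct, -1, 0)
        self.parent = parent
        self.depth = depth
        self.leaf_node = leaf_node
        self.n_nodes = len(parent)
        self.n_leaves = len(leaf_node)
        n = self.n_nodes
        self.depth_arr = np.array(depth, np.int32)
        self.lca_flat = _lca_table_flat(np.array(parent, np.int32),
                                        self.depth_arr)
        self.lca = [[int(self.lca_flat[u * n + v]) for v in range(n)]
                    for u in range(n)]
        self._usplits = None

    def unrooted_species_splits(self):
        """Species-level nontrivial splits (unrooted), cached."""
        if self._usplits is None:
            if isinstance(self.struct, int) or self.n_leaves < 3:
                self._usplits = ()
            else:
                self._usplits = tuple(top.unrooted_splits(self.struct))
        return self._usplits


def restrict_struct(struct, keep):
    """Induced rooted topology on the species subset ``keep``.

    Unary nodes produced by pruning are suppressed; returns an int leaf if a
    single species remains, None if none.
    """
    keep = set(keep)

    def rec(t):
        if isinstance(t, int):
            return t if t in keep else None
        a = rec(t[0])
        b = rec(t[1])
        if a is None:
            return b
        if b is None:
            return a
        return (a, b)

    out = rec(struct)
    return None if out is None else top.canon_rooted(out)


# ---------------------------------------------------------------------------
# gene topology indexing


class GeneTopologyIndex:
    """Unrooted gene topology plus per-leaf species ids and split multiset.

    Also carries the flat integer arrays (neighbor tables, BFS schedule,
    per-leaf species ids) consumed by the JIT reconciliation kernel.
    """

    __slots__ = ("uidx", "leaf_species", "n_leaves", "species_present",
                 "copy_counts", "split_counter", "n_internal_edges",
                 "edges_arr", "nbr_node", "nbr_edge", "order", "parent",
                 "leaf_sp_fam")

    def __init__(self, unrooted_struct, leaf_species: Sequence[int]):
        self.uidx = top.UnrootedIndex(unrooted_struct)
        self.leaf_species = list(leaf_species)
        self.n_leaves = self.uidx.n_leaves
        self.copy_counts = Counter(self.leaf_species[lab]
                                   for lab in self.uidx.leaf_label.values())
        self.species_present = frozenset(self.copy_counts)
        self.split_counter, self.n_internal_edges = self._splits()
        self._build_arrays()

    def _build_arrays(self):
        uidx = self.uidx
        n = uidx.n_nodes
        self.edges_arr = np.array(uidx.edges, np.int32).reshape(-1, 2)
        self.nbr_node = np.full((n, 3), -1, np.int32)
        self.nbr_edge = np.full((n, 3), -1, np.int32)
        fill = [0] * n
        for e, (u, v) in enumerate(uidx.edges):
            self.nbr_node[u, fill[u]] = v
            self.nbr_edge[u, fill[u]] = e
            fill[u] += 1
            self.nbr_node[v, fill[v]] = u
            self.nbr_edge[v, fill[v]] = e
            fill[v] += 1
        parent = np.full(n, -1, np.int32)
        order = np.empty(n, np.int32)
        order[0] = 0
        seen = np.zeros(n, bool)
        seen[0] = True
        head = 0
        tail = 1
        while head < tail:
            node = order[head]
            head += 1
            for k in range(3):
                nb = self.nbr_node[node, k]
                if nb >= 0 and not seen[nb]:
                    seen[nb] = True
                    parent[nb] = node
                    order[tail] = nb
                    tail += 1
        self.order = order
        self.parent = parent
        self.leaf_sp_fam = np.full(n, -1, np.int32)
        for nid, lab in uidx.leaf_label.items():
            self.leaf_sp_fam[nid] = self.leaf_species[lab]

    def _splits(self):
        """Multiset of nontrivial species-multiset bipartitions (unrooted).

        Keys are canonical copy-count vectors over the family's sorted
        species (lexicographically smaller of side/complement).
        """
        uidx = self.uidx
        order = sorted(self.copy_counts)
        pos = {sp: i for i, sp in enumerate(order)}
        total = tuple(self.copy_counts[sp] for sp in order)
        n_total = sum(total)
        ctr: Counter = Counter()
        n_internal = 0
        for (u, v) in uidx.edges:
            if u in uidx.leaf_label or v in uidx.leaf_label:
                continue
            n_internal += 1
            vec = [0] * len(order)
            for lab in top._leafset_away(uidx, v, u):
                vec[pos[self.leaf_species[lab]]] += 1
            key = _canon_count_split(tuple(vec), total, n_total)
            if key is not None:
                ctr[key] += 1
        return ctr, n_internal


def _canon_count_split(vec: tuple, total: tuple, n_total: int):
    """Canonical key for a copy-count split vector; None if trivial."""
    ns = sum(vec)
    if ns <= 1 or n_total - ns <= 1:
        return None
    comp = tuple(t - v for t, v in zip(total, vec))
    return vec if vec <= comp else comp


def extended_species_splits(species_index: SpeciesIndex,
                            copy_counts: Mapping[int, int]) -> Counter:
    """Split multiset of the species tree extended per the gene multree.

    Every species with k > 1 gene copies is replaced by a k-furcation of
    copy leaves; since the extension is a star, the bipartition multiset
    does not depend on how copies are matched to gene leaves.
    """
    order = sorted(copy_counts)
    pos = {sp: i for i, sp in enumerate(order)}
    total = tuple(copy_counts[sp] for sp in order)
    n_total = sum(total)
    ctr: Counter = Counter()
    # species-level nontrivial splits of the restricted S (unrooted
    # interpretation), sides converted to copy-count vectors
    for side_species in species_index.unrooted_species_splits():
        vec = [0] * len(order)
        for sp in side_species:
            vec[pos[sp]] = copy_counts[sp]
        key = _canon_count_split(tuple(vec), total, n_total)
        if key is not None:
            ctr[key] += 1
    # multifurcation edges: one per multi-copy species (the edge between the
    # star center and the rest of the tree)
    for i, sp in enumerate(order):
        k = copy_counts[sp]
        if k > 1:
            vec = [0] * len(order)
            vec[i] = k
            key = _canon_count_split(tuple(vec), total, n_total)
            if key is not None:
                ctr[key] += 1
    return ctr


def mulrf(gene_struct_or_index, species_struct, leaf_species=None) -> int:
    """mulRF distance between an unrooted gene multree and a rooted species
    tree: symmetric difference of nontrivial species-multiset bipartitions
    after extending the (restricted) species tree with one multifurcation
    per multi-copy species.  Invariant to the rooting of either input."""
    if isinstance(gene_struct_or_index, GeneTopologyIndex):
        g = gene_struct_or_index
    else:
        g = GeneTopologyIndex(gene_struct_or_index, leaf_species)
    missing = g.species_present - set(top.leaves_of(species_struct))
    if missing:
        raise ValueError(f"species {sorted(missing)} absent from species tree")
    sidx = SpeciesIndex(restrict_struct(species_struct, g.species_present))
    return mulrf_from_counters(g.split_counter,
                               extended_species_splits(sidx, g.copy_counts))


def mulrf_from_counters(gene_splits, ext_splits) -> int:
    out = 0
    for k, v in gene_splits.items():
        out += abs(v - ext_splits.get(k, 0))
    for k, v in ext_splits.items():
        if k not in gene_splits:
            out += v
    return out


# ---------------------------------------------------------------------------
# rooted-tree reconciliation (reference API; the sampler uses the DP below)


def lca_map(gene_struct, species_index_or_struct, leaf_species):
    """LCA mapping from gene-tree nodes to species-tree nodes.

    Returns {gene node key: species node id} where internal gene nodes are
    keyed by their struct tuple and leaves by their int index.  The mapping
    satisfies M(leaf) = species leaf, M(g) = lca(M(g1), M(g2)).
    """
    sidx = (species_index_or_struct
            if isinstance(species_index_or_struct, SpeciesIndex)
            else SpeciesIndex(species_index_or_struct))
    out = {}

    def rec(t):
        if isinstance(t, int):
            sp = leaf_species[t]
            if sp not in sidx.leaf_node:
                raise ValueError(f"species {sp} absent from species tree")
            m = sidx.leaf_node[sp]
        else:
            m = sidx.lca[rec(t[0])][rec(t[1])]
        out[t] = m
        return m

    rec(gene_struct)
    return out


def dup_loss(gene_struct, species_index_or_struct, leaf_species):
    """(duplications, losses) of the minimal LCA reconciliation.

    A node g is a duplication iff its map equals a child's map; each child c
    contributes path-length(M(g) -> M(c)) losses, minus one when g is a
    speciation.
    """
    sidx = (species_index_or_struct
            if isinstance(species_index_or_struct, SpeciesIndex)
            else SpeciesIndex(species_index_or_struct))
    dups = 0
    losses = 0

    def rec(t):
        nonlocal dups, losses
        if isinstance(t, int):
            return sidx.leaf_node[leaf_species[t]]
        m1 = rec(t[0])
        m2 = rec(t[1])
        m = sidx.lca[m1][m2]
        is_dup = (m == m1) or (m == m2)
        dups += is_dup
        losses += (sidx.depth[m1] + sidx.depth[m2] - 2 * sidx.depth[m]
                   - (0 if is_dup else 2))
        return m

    rec(gene_struct)
    return dups, losses


def deep_coal(gene_struct, species_index_or_struct, leaf_species):
    """Minimal number of extra lineages (deep coalescences).

    Sum over non-root species nodes of (gene lineages crossing the branch
    above that node, minus one), under the LCA embedding.
    """
    sidx = (species_index_or_struct
            if isinstance(species_index_or_struct, SpeciesIndex)
            else SpeciesIndex(species_index_or_struct))
    total = 0

    def rec(t):
        nonlocal total
        if isinstance(t, int):
            return sidx.leaf_node[leaf_species[t]]
        m1 = rec(t[0])
        m2 = rec(t[1])
        m = sidx.lca[m1][m2]
        total += (sidx.depth[m1] - sidx.depth[m]) + (sidx.depth[m2] - sidx.depth[m])
        return m

    rec(gene_struct)
    # every non-root species branch carries at least one lineage when the
    # species tree is restricted to the family's species
    return total - (sidx.n_nodes - 1)


# ---------------------------------------------------------------------------
# all-rootings dynamic program


def all_rooting_costs(g: GeneTopologyIndex, sidx: SpeciesIndex):
    """Per-edge (dups, losses, deep_coal) arrays over all rootings of g.

    Edge order follows ``g.uidx.edges`` (the deterministic tie-break order).
    """
    uidx = g.uidx
    nbr = uidx.neighbors
    leaf_label = uidx.leaf_label
    lca = sidx.lca
    depth = sidx.depth
    leaf_node = sidx.leaf_node
    n_nodes = uidx.n_nodes

    # rooted orientation from node 0 (= minimum leaf) for scheduling
    parent = [-1] * n_nodes
    order = [0]
    seen = [False] * n_nodes
    seen[0] = True
    for node in order:
        for nb in nbr[node]:
            if not seen[nb]:
                seen[nb] = True
                parent[nb] = node
                order.append(nb)

    # Mdir[(t, h)]: species node of subtree at h away from t
    Mdir: dict[tuple[int, int], int] = {}
    # Sdir[(t, h)]: (dups, losses, -sum of internal map depths) accumulated
    Sdir: dict[tuple[int, int], tuple] = {}

    def contrib(h, t):
        """(map, dup, loss, negdepth) of internal node h oriented away from t."""
        a, b = (x for x in nbr[h] if x != t)
        ma = Mdir[(h, a)]
        mb = Mdir[(h, b)]
        m = lca[ma][mb]
        is_dup = (m == ma) or (m == mb)
        loss = depth[ma] + depth[mb] - 2 * depth[m] - (0 if is_dup else 2)
        return m, (1 if is_dup else 0), loss, -depth[m]

    # down pass (postorder)
    for v in reversed(order):
        t = parent[v]
        if t < 0:
            continue
        if v in leaf_label:
            Mdir[(t, v)] = leaf_node[g.leaf_species[leaf_label[v]]]
            Sdir[(t, v)] = (0, 0, 0)
        else:
            m, d, l, nd = contrib(v, t)
            a, b = (x for x in nbr[v] if x != t)
            sa = Sdir[(v, a)]
            sb = Sdir[(v, b)]
            Mdir[(t, v)] = m
            Sdir[(t, v)] = (d + sa[0] + sb[0], l + sa[1] + sb[1],
                            nd + sa[2] + sb[2])

    # up pass (preorder): (v, p) = subtree at p away from v
    for p in order:
        for v in nbr[p]:
            if parent[v] != p:
                continue
            if p in leaf_label:  # p is the root leaf (node 0)
                Mdir[(v, p)] = leaf_node[g.leaf_species[leaf_label[p]]]
                Sdir[(v, p)] = (0, 0, 0)
            else:
                m, d, l, nd = contrib(p, v)
                a, b = (x for x in nbr[p] if x != v)
                sa = Sdir[(p, a)]
                sb = Sdir[(p, b)]
                Mdir[(v, p)] = m
                Sdir[(v, p)] = (d + sa[0] + sb[0], l + sa[1] + sb[1],
                                nd + sa[2] + sb[2])

    leaf_depth_sum = sum(depth[leaf_node[g.leaf_species[lab]]]
                         for lab in leaf_label.values())
    n_nonroot_species = sidx.n_nodes - 1

    dups_arr = []
    loss_arr = []
    ils_arr = []
    for (u, v) in uidx.edges:
        ma = Mdir[(u, v)]
        mb = Mdir[(v, u)]
        m = lca[ma][mb]
        is_dup = (m == ma) or (m == mb)
        root_loss = depth[ma] + depth[mb] - 2 * depth[m] - (0 if is_dup else 2)
        sa = Sdir[(u, v)]
        sb = Sdir[(v, u)]
        dups_arr.append(sa[0] + sb[0] + (1 if is_dup else 0))
        loss_arr.append(sa[1] + sb[1] + root_loss)
        ils_arr.append(leaf_depth_sum + sa[2] + sb[2] - 2 * depth[m]
                       - n_nonroot_species)
    return dups_arr, loss_arr, ils_arr


@njit(cache=False)
def _min_roots_kernel(nbr_node, nbr_edge, edges, order, parent, leaf_sp_fam,
                      sp_node_of, lca, depth, n_sp_nodes):
    """All-rootings DP over directed edges; returns (d1, d2, d3, r*, r**)."""
    n_nodes = nbr_node.shape[0]
    E = edges.shape[0]
    M = np.empty(2 * E, np.int32)
    Sd = np.zeros(2 * E, np.int32)
    Sl = np.zeros(2 * E, np.int32)
    Sn = np.zeros(2 * E, np.int32)  # sum of internal map depths

    # directed id: 2e = subtree at edges[e,1] (away from edges[e,0]);
    # 2e+1 = subtree at edges[e,0]
    def did_of(t, h):
        for k in range(3):
            if nbr_node[h, k] == t:
                e = nbr_edge[h, k]
                if edges[e, 1] == h:
                    return 2 * e
                return 2 * e + 1
        return -1

    def fill(t, h):
        """Fill M/S for directed edge (t -> h)."""
        did = did_of(t, h)
        if leaf_sp_fam[h] >= 0:
            M[did] = sp_node_of[leaf_sp_fam[h]]
            Sd[did] = 0
            Sl[did] = 0
            Sn[did] = 0
            return
        a = -1
        b = -1
        for k in range(3):
            nb = nbr_node[h, k]
            if nb >= 0 and nb != t:
                if a < 0:
                    a = nb
                else:
                    b = nb
        da = did_of(h, a)
        db = did_of(h, b)
        ma = M[da]
        mb = M[db]
        m = lca[ma * n_sp_nodes + mb]
        is_dup = 1 if (m == ma or m == mb) else 0
        loss = depth[ma] + depth[mb] - 2 * depth[m] - (0 if is_dup else 2)
        M[did] = m
        Sd[did] = is_dup + Sd[da] + Sd[db]
        Sl[did] = loss + Sl[da] + Sl[db]
        Sn[did] = depth[m] + Sn[da] + Sn[db]

    # down pass: children before parents
    for idx in range(n_nodes - 1, -1, -1):
        v = order[idx]
        t = parent[v]
        if t >= 0:
            fill(t, v)
    # up pass: parents before children
    for idx in range(n_nodes):
        v = order[idx]
        for k in range(3):
            c = nbr_node[v, k]
            if c >= 0 and parent[c] == v:
                fill(c, v)

    c_leaf = 0
    for nid in range(n_nodes):
        if leaf_sp_fam[nid] >= 0:
            c_leaf += depth[sp_node_of[leaf_sp_fam[nid]]]

    best_dl = -1
    r1 = 0
    d1 = 0
    d2 = 0
    best_ils = -1
    r2 = 0
    for e in range(E):
        ma = M[2 * e]
        mb = M[2 * e + 1]
        m = lca[ma * n_sp_nodes + mb]
        is_dup = 1 if (m == ma or m == mb) else 0
        root_loss = depth[ma] + depth[mb] - 2 * depth[m] - (0 if is_dup else 2)
        dups_e = Sd[2 * e] + Sd[2 * e + 1] + is_dup
        loss_e = Sl[2 * e] + Sl[2 * e + 1] + root_loss
        ils_e = (c_leaf - Sn[2 * e] - Sn[2 * e + 1] - 2 * depth[m]
                 - (n_sp_nodes - 1))
        if best_dl < 0 or dups_e + loss_e < best_dl:
            best_dl = dups_e + loss_e
            r1 = e
            d1 = dups_e
            d2 = loss_e
        if best_ils < 0 or ils_e < best_ils:
            best_ils = ils_e
            r2 = e
    return d1, d2, best_ils, r1, r2


def _sp_node_array(g: GeneTopologyIndex, sidx: SpeciesIndex):
    n = max(g.species_present) + 1
    arr = np.full(n, -1, np.int32)
    for sp in g.species_present:
        arr[sp] = sidx.leaf_node[sp]
    return arr


def min_over_roots(g: GeneTopologyIndex, sidx: SpeciesIndex,
                   sp_node_of=None):
    """(d1, d2, d3, r_star, r_star2): duplication-loss costs at the rooting
    minimizing their sum, deep-coalescence cost at its own optimal rooting.
    Ties break to the smallest edge index."""
    if _HAVE_NUMBA:
        if sp_node_of is None:
            sp_node_of = _sp_node_array(g, sidx)
        return _min_roots_kernel(g.nbr_node, g.nbr_edge, g.edges_arr, g.order,
                                 g.parent, g.leaf_sp_fam, sp_node_of,
                                 sidx.lca_flat, sidx.depth_arr, sidx.n_nodes)
    dups, losses, ils = all_rooting_costs(g, sidx)
    best_dl = min(d + l for d, l in zip(dups, losses))
    r_star = next(i for i, (d, l) in enumerate(zip(dups, losses))
                  if d + l == best_dl)
    best_ils = min(ils)
    r_star2 = ils.index(best_ils)
    return dups[r_star], losses[r_star], best_ils, r_star, r_star2


# ---------------------------------------------------------------------------
# high-level distance vector


def distance_vector(gene_struct_or_index, species_struct, leaf_species=None,
                    model: str = "DLIR") -> DistanceVector:
    """Full distance vector of one gene topology against one species tree.

    ``gene_struct_or_index`` is a canonical unrooted struct (then
    ``leaf_species`` maps leaf index -> species id) or a prebuilt
    :class:`GeneTopologyIndex`.  The species tree is restricted to the
    family's species first.
    """
    if isinstance(gene_struct_or_index, GeneTopologyIndex):
        g = gene_struct_or_index
    else:
        g = GeneTopologyIndex(gene_struct_or_index, leaf_species)
    missing = g.species_present - set(_species_leaves(species_struct))
    if missing:
        raise ValueError(f"species {sorted(missing)} absent from species tree")
    restricted = restrict_struct(species_struct, g.species_present)
    sidx = SpeciesIndex(restricted)
    d1, d2, d3, r1, r2 = min_over_roots(g, sidx)
    d4 = None
    if model == "DLIR":
        ext = extended_species_splits(sidx, g.copy_counts)
        d4 = mulrf_from_counters(g.split_counter, ext)
    return DistanceVector(d1, d2, d3, d4, r1, r2)


def _species_leaves(struct):
    return top.leaves_of(struct)


def scaling_constants(g: GeneTopologyIndex, input_topologies,
                      reference_structs, model: str = "DLIR"):
    """Per-family distance scaling constants m_ij (fixed before sampling).

    m_dup = n_leaves - 1 (the maximum possible duplication count);
    m_loss and m_ils are the empirical maxima of those distances over the
    input topologies against the reference species trees, floored at 1;
    m_mulrf is the internal-edge-count upper bound.
    """
    n = g.n_leaves
    m_dup = max(1, n - 1)
    max_loss = 0
    max_ils = 0
    for ref in reference_structs:
        restricted = restrict_struct(ref, g.species_present)
        sidx = SpeciesIndex(restricted)
        for topo in input_topologies:
            gt = (topo if isinstance(topo, GeneTopologyIndex)
                  else GeneTopologyIndex(topo, g.leaf_species))
            _, l, i3, _, _ = min_over_roots(gt, sidx)
            max_loss = max(max_loss, l)
            max_ils = max(max_ils, i3)
    out = [m_dup, max(1, max_loss), max(1, max_ils)]
    if model == "DLIR":
        n_r = len(g.species_present)
        ext_internal = (max(0, n_r - 3)
                        + sum(1 for sp, k in g.copy_counts.items() if k > 1))
        out.append(max(1, g.n_internal_edges + ext_internal))
    return out


# ---------------------------------------------------------------------------
# cached scorer used by the samplers


class ReconScorer:
    """Distance-vector cache over (species tree, family, topology) keys.

    MCMC over species trees revisits the same (S, topology) pairs massively;
    distances are pure functions of the pair, so they are computed once.
    """

    def __init__(self, families_leaf_species, supports, model: str = "DLIR"):
        """``families_leaf_species``: per family, leaf index -> species id.
        ``supports``: per family, sequence of canonical unrooted structs."""
        self.model = model
        self.gidx: list[list[GeneTopologyIndex]] = []
        for ls, sup in zip(families_leaf_species, supports):
            self.gidx.append([GeneTopologyIndex(t, ls) for t in sup])
        # species contexts shared across families with the same species set
        self._subset_cache: dict = {}  # (S, subset) -> SpeciesIndex
        self._species_cache: dict = {}  # (S, fam) -> (sidx, ext, sp_node_of)
        self._dv_cache: dict = {}
        # per-family split-key machinery for fast extended-S counters
        self._fam_split_keys: list[dict] = []
        self._fam_star: list[Counter] = []
        self._fam_canon: list = []
        for g_list in self.gidx:
            g0 = g_list[0]
            order = sorted(g0.copy_counts)
            pos = {sp: i for i, sp in enumerate(order)}
            total = tuple(g0.copy_counts[sp] for sp in order)
            n_total = sum(total)
            star = Counter()
            for i, sp in enumerate(order):
                k = g0.copy_counts[sp]
                if k > 1:
                    vec = [0] * len(order)
                    vec[i] = k
                    key = _canon_count_split(tuple(vec), total, n_total)
                    if key is not None:
                        star[key] += 1
            self._fam_split_keys.append({})
            self._fam_star.append(star)
            self._fam_canon.append((pos, total, n_total, g0.copy_counts))

    def n_topologies(self, fam: int) -> int:
        return len(self.gidx[fam])

    def _ext_counter(self, fam: int, sidx: SpeciesIndex) -> Counter:
        """Extended-S split counter; species-split keys memoized per family
        (the same species splits recur across many species trees)."""
        pos, total, n_total, copy_counts = self._fam_canon[fam]
        keycache = self._fam_split_keys[fam]
        ctr = Counter(self._fam_star[fam])
        for side in sidx.unrooted_species_splits():
            key = keycache.get(side, -1)
            if key == -1:
                vec = [0] * len(total)
                for sp in side:
                    vec[pos[sp]] = copy_counts[sp]
                key = _canon_count_split(tuple(vec), total, n_total)
                keycache[side] = key
            if key is not None:
                ctr[key] += 1
        return ctr

    def _family_species_ctx(self, species_struct, fam: int):
        key = (species_struct, fam)
        ctx = self._species_cache.get(key)
        if ctx is None:
            g0 = self.gidx[fam][0]
            skey = (species_struct, g0.species_present)
            sidx = self._subset_cache.get(skey)
            if sidx is None:
                sidx = SpeciesIndex(
                    restrict_struct(species_struct, g0.species_present))
                self._subset_cache[skey] = sidx
            ext = (self._ext_counter(fam, sidx)
                   if self.model == "DLIR" else None)
            ctx = (sidx, ext, _sp_node_array(g0, sidx))
            self._species_cache[key] = ctx
        return ctx

    #: entries kept before the distance cache is dropped wholesale; a
    #: poorly mixing chain can otherwise accumulate gigabytes of keys
    MAX_CACHE = 1_000_000

    def distances(self, species_struct, fam: int, topo_idx: int) -> tuple:
        """(d1, d2, d3[, d4]) for family ``fam``'s topology ``topo_idx``."""
        key = (species_struct, fam, topo_idx)
        dv = self._dv_cache.get(key)
        if dv is None:
            if len(self._dv_cache) > self.MAX_CACHE:
                self._dv_cache.clear()
                self._species_cache.clear()
                self._subset_cache.clear()
            sidx, ext, spn = self._family_species_ctx(species_struct, fam)
            g = self.gidx[fam][topo_idx]
            d1, d2, d3, _, _ = min_over_roots(g, sidx, spn)
            if self.model == "DLIR":
                dv = (d1, d2, d3, mulrf_from_counters(g.split_counter, ext))
            else:
                dv = (d1, d2, d3)
            self._dv_cache[key] = dv
        return dv
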