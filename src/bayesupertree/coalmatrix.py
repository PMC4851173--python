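"""Summary-statistic coalescent species-tree baselines.

GLASS, STEAC, SD and MAC all reduce each gene tree to a matrix of distances
between species, merge the per-gene matrices into one, and cluster.  They
differ in three switches:

==========  ===============  ==============  ===============
method      within a gene    across genes    clustering
==========  ===============  ==============  ===============
GLASS       minimum          minimum         single linkage
SD          minimum          mean            UPGMA
STEAC       average          mean            UPGMA
MAC         average          minimum         single linkage
==========  ===============  ==============  ===============

"within a gene" handles several leaves of the same species in one tree
(paralogs / individuals); "across genes" reconciles contradicting distances
between gene families.  With ``lengths="unit"`` every branch counts 1, i.e.
path lengths in edges — the fallback when only topologies are available.

Agglomeration is hand-rolled with lexicographic tie-breaking so outputs are
deterministic; the test-suite cross-checks it against scipy's linkage on
tie-free inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

METHODS = {
    "GLASS": ("min", "min", "single_linkage"),
    "SD": ("min", "mean", "upgma"),
    "STEAC": ("avg", "mean", "upgma"),
    "MAC": ("avg", "min", "single_linkage"),
}


@dataclass
class SpeciesDistanceMatrix:
    species: tuple
    matrix: np.ndarray  # symmetric, nan where no gene covers the pair

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species),) * 2:
            raise ValueError("matrix shape mismatch")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
            raise ValueError("matrix not symmetric")
        self.matrix = m


# ---------------------------------------------------------------------------
# leaf-distance extraction (SimNode or dendropy trees)


def _leaf_distances(tree, unit: bool = False):
    """(labels, pairwise path-distance matrix) for a tree with lengths."""
    if isinstance(tree, dendropy.Tree):
        def children(n):
            return n.child_nodes()

        def length(n):
            return 1.0 if unit else (n.edge.length or 0.0)

        def label(n):
            return n.taxon.label

        root = tree.seed_node
    else:  # SimNode
        def children(n):
            return n.children

        def length(n):
            return 1.0 if unit else n.length

        def label(n):
            return n.label

        root = tree
    labels = []
    index = {}
    dist = {}

    def rec(n):
        """returns {leaf index: depth below n}"""
        if not children(n):
            i = index.setdefault(label(n), len(labels))
            if i == len(labels):
                labels.append(label(n))
            return {i: 0.0}
        below = {}
        groups = []
        for c in children(n):
            sub = {k: v + length(c) for k, v in rec(c).items()}
            groups.append(sub)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for x, dx in groups[gi].items():
                    for y, dy in groups[gj].items():
                        dist[(min(x, y), max(x, y))] = dx + dy
            below.update(groups[gi])
        below.update(groups[-1])
        return below

    rec(root)
    n = len(labels)
    m = np.zeros((n, n))
    for (x, y), d in dist.items():
        m[x, y] = m[y, x] = d
    if unit:
        # a bifurcating root is not a node of the unrooted tree: paths
        # crossing it count one edge fewer
        kids = children(root)
        if len(kids) == 2:
            left = set()

            def collect(nd):
                if not children(nd):
                    left.add(index[label(nd)])
                for c in children(nd):
                    collect(c)

            collect(kids[0])
            for x in left:
                for y in range(n):
                    if y not in left:
                        m[x, y] -= 1
                        m[y, x] = m[x, y]
    return labels, m


# ---------------------------------------------------------------------------
# per-gene species matrix


def gene_matrix(tree, leaf_map, within: str = "min",
                unit_lengths: bool = False) -> SpeciesDistanceMatrix:
    """Species-by-species matrix from one gene tree.

    Entry (X, Y) is the min (GLASS/SD) or average (STEAC/MAC) of path
    lengths over all leaf pairs (x in X, y in Y).
    """
    if within not in ("min", "avg"):
        raise ValueError("within must be 'min' or 'avg'")
    labels, m = _leaf_distances(tree, unit=unit_lengths)
    species = tuple(sorted(set(leaf_map[l] for l in labels)))
    sp_idx = {s: i for i, s in enumerate(species)}
    groups = {s: [] for s in species}
    for i, lab in enumerate(labels):
        groups[leaf_map[lab]].append(i)
    n = len(species)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            vals = [m[x, y] for x in groups[species[a]]
                    for y in groups[species[b]]]
            v = min(vals) if within == "min" else float(np.mean(vals))
            out[a, b] = out[b, a] = v
    return SpeciesDistanceMatrix(species, out)


def merge_matrices(matrices, across: str = "min") -> SpeciesDistanceMatrix:
    """Combine per-gene matrices: per-pair min (GLASS/MAC) or mean (SD/
    STEAC) over the genes where the pair is present.  A pair absent from
    every gene is an error (disconnected species)."""
    if across not in ("min", "mean"):
        raise ValueError("across must be 'min' or 'mean'")
    if not matrices:
        raise ValueError("no matrices to merge")
    species = tuple(sorted(set().union(*(m.species for m in matrices))))
    sp_idx = {s: i for i, s in enumerate(species)}
    n = len(species)
    acc = [[[] for _ in range(n)] for _ in range(n)]
    for m in matrices:
        for a, sa in enumerate(m.species):
            for b in range(a + 1, len(m.species)):
                i, j = sp_idx[sa], sp_idx[m.species[b]]
                acc[i][j].append(m.matrix[a, b])
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = acc[i][j]
            if not vals:
                raise ValueError(
                    f"species pair ({species[i]}, {species[j]}) not covered "
                    "by any gene")
            v = min(vals) if across == "min" else float(np.mean(vals))
            out[i, j] = out[j, i] = v
    return SpeciesDistanceMatrix(species, out)


# ---------------------------------------------------------------------------
# clustering


def build_species_tree(matrix: SpeciesDistanceMatrix,
                       method: str = "upgma") -> dendropy.Tree:
    """Rooted species tree by agglomerative clustering (UPGMA or single
    linkage).  Ties merge the lexicographically smallest cluster pair."""
    if method not in ("upgma", "single_linkage"):
        raise ValueError("method must be 'upgma' or 'single_linkage'")
    if np.any(np.isnan(matrix.matrix)):
        raise ValueError("matrix has missing entries")
    species = list(matrix.species)
    # cluster key = sorted tuple of member labels
    clusters = {(s,): None for s in species}
    newick = {(s,): s for s in species}
    sizes = {(s,): 1 for s in species}
    d = {}
    for i, a in enumerate(species):
        for j in range(i + 1, len(species)):
            key = tuple(sorted((a, species[j])))
            d[((a,), (species[j],))] = matrix.matrix[i, j]

    def getd(x, y):
        return d[(x, y)] if (x, y) in d else d[(y, x)]

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                v = getd(keys[i], keys[j])
                if best is None or v < best[0] - 1e-15:
                    best = (v, keys[i], keys[j])
        _, x, y = best
        merged = tuple(sorted(x + y))
        newick[merged] = f"({newick[x]},{newick[y]})"
        sizes[merged] = sizes[x] + sizes[y]
        del clusters[x], clusters[y]
        for z in list(clusters):
            if method == "upgma":
                v = (getd(x, z) * sizes[x] + getd(y, z) * sizes[y]) / (
                    sizes[x] + sizes[y])
            else:
                v = min(getd(x, z), getd(y, z))
            d[(merged, z)] = v
        clusters[merged] = None
    (final,) = clusters
    return dendropy.Tree.get(data=newick[final] + ";", schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# full pipelines


def run_method(trees, leaf_maps, method: str,
               lengths: str = "true") -> dendropy.Tree:
    """One of GLASS / STEAC / SD / MAC on a collection of gene trees.

    ``trees``: one tree (SimNode or dendropy) per family; ``leaf_maps``:
    matching leaf-label -> species mappings; ``lengths``: "true" uses the
    trees' branch lengths, "unit" sets every branch to 1.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; pick from {sorted(METHODS)}")
    if lengths not in ("true", "unit"):
        raise ValueError("lengths must be 'true' or 'unit'")
    within, across, clustering = METHODS[method]
    mats = [gene_matrix(t, lm, within, unit_lengths=(lengths == "unit"))
            for t, lm in zip(trees, leaf_maps)]
    merged = merge_matrices(mats, across)
    return build_species_tree(merged, clustering)
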