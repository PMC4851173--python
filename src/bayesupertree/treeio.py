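"""Tree I/O, leaf-to-species mapping, bipartitions, consensus and accuracy.

Input gene-tree collections are weighted lists of unrooted topologies, one
gene family per file: either a plain Newick list (optionally with a leading
tab-separated weight column; duplicated topologies are collapsed by
counting) or a Nexus TREES block.  Species assignment is by substring match
of species names inside leaf labels, as produced by most ortholog pipelines
(for example ``Dmel_CG1234`` contains the species name ``Dmel``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from . import _topology as top


class ParseError(ValueError):
    pass


class LeafMappingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class GeneFamily:
    """A gene family: ordered leaf labels plus a leaf -> species mapping.

    Several leaves may map to the same species (paralogs / multiple
    individuals); the species set may be a strict subset of the full
    species list.
    """

    family_id: int
    leaf_labels: tuple[str, ...]
    leaf_species: Mapping[str, str]

    def __post_init__(self):
        missing = [l for l in self.leaf_labels if l not in self.leaf_species]
        if missing:
            raise LeafMappingError(f"leaves without species mapping: {missing}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.leaf_species[l] for l in self.leaf_labels)))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


@dataclass
class GeneTreeDistribution:
    """Weighted collection of distinct unrooted gene-tree topologies.

    ``topologies`` are canonical unrooted structs over leaf indices into
    ``family.leaf_labels``; ``weights`` are the resampling weights (posterior
    frequencies from an upstream per-gene analysis), normalized to one.
    """

    family: GeneFamily
    topologies: tuple
    weights: np.ndarray
    raw_counts: tuple | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.topologies) != len(self.weights):
            raise ValueError("topologies/weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("negative weight")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {s}, not 1")
        if len(set(self.topologies)) != len(self.topologies):
            raise ValueError("duplicate topologies in distribution")

    def newick(self, i: int) -> str:
        return top.to_newick(self.topologies[i], self.family.leaf_labels)


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split: two disjoint leaf (multi)sets covering all leaves.

    Sides are stored canonically (lexicographically smaller side first) so
    equality and hashing are well defined.  In multree mode the sides are
    multisets of species labels, encoded as sorted (label, count) tuples.
    """

    side_a: tuple
    side_b: tuple

    @staticmethod
    def of(side_a: Iterable, side_b: Iterable) -> "Bipartition":
        a = tuple(sorted(side_a))
        b = tuple(sorted(side_b))
        if not a or not b:
            raise ValueError("bipartition side empty")
        if b < a:
            a, b = b, a
        return Bipartition(a, b)

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) == 1 or len(self.side_b) == 1


# ---------------------------------------------------------------------------
# parsing


_WEIGHT_RE = re.compile(r"^\s*([0-9.eE+-]+)\s+(\(.*)$")


def parse_trees(path, fmt: str = "newick-list"):
    """Read a weighted tree collection.

    Returns a list of ``(dendropy.Tree, weight)`` with distinct unrooted
    topologies and weights normalized to one.  Newick lists may carry an
    explicit leading weight column; otherwise duplicated topologies are
    collapsed by counting.  Raw (unnormalized) weights are attached to the
    returned list as the attribute ``raw_counts`` is not possible on a plain
    list, so use :func:`read_gene_family` when counts matter.
    """
    if fmt == "nexus":
        return _parse_nexus(path)
    if fmt != "newick-list":
        raise ValueError(f"unknown format {fmt!r}")
    entries = []
    with open(path) as fh:
        lines = fh.readlines()
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _WEIGHT_RE.match(line)
        if m:
            weight, newick = float(m.group(1)), m.group(2)
        else:
            weight, newick = 1.0, line
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ParseError(f"{path}: line {ln}: malformed Newick: {exc}") from exc
        entries.append((tree, weight))
    if not entries:
        raise ParseError(f"{path}: no trees found")
    return _collapse(entries)


def _parse_nexus(path):
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="nexus",
                                      preserve_underscores=True)
    except Exception as exc:
        raise ParseError(f"{path}: malformed Nexus: {exc}") from exc
    if not trees:
        raise ParseError(f"{path}: no trees found")
    entries = []
    for t in trees:
        w = t.weight if t.weight is not None else 1.0
        entries.append((t, float(w)))
    return _collapse(entries)


def _collapse(entries):
    """Merge duplicate unrooted topologies, normalize weights."""
    labels = sorted(l.taxon.label for l in entries[0][0].leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    seen: dict[tuple, int] = {}
    out: list[list] = []
    for tree, w in entries:
        key = dendropy_to_unrooted(tree, index)
        if key in seen:
            out[seen[key]][1] += w
        else:
            seen[key] = len(out)
            out.append([tree, w])
    total = sum(w for _, w in out)
    if total <= 0:
        raise ParseError("total tree weight is zero")
    return [(t, w / total) for t, w in out]


def read_gene_family(path, species_names: Sequence[str], family_id: int = 0,
                     fmt: str = "newick-list", case_insensitive: bool = False):
    """Read one gene family file into (GeneFamily, GeneTreeDistribution)."""
    pairs = parse_trees(path, fmt)
    labels = tuple(sorted(l.taxon.label for l in pairs[0][0].leaf_node_iter()))
    index = {lab: i for i, lab in enumerate(labels)}
    mapping = map_leaves_to_species(labels, species_names, case_insensitive)
    fam = GeneFamily(family_id, labels, mapping)
    topos, weights = [], []
    for tree, w in pairs:
        tlabels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        if tuple(tlabels) != labels:
            raise ParseError(f"{path}: trees with differing leaf sets")
        topos.append(dendropy_to_unrooted(tree, index))
        weights.append(w)
    return fam, GeneTreeDistribution(fam, tuple(topos), np.array(weights),
                                     raw_counts=tuple(weights))


def read_species_list(path) -> list[str]:
    with open(path) as fh:
        names = [ln.strip() for ln in fh if ln.strip()]
    if not names:
        raise ParseError(f"{path}: empty species list")
    if len(set(names)) != len(names):
        raise ParseError(f"{path}: duplicated species names")
    return names


def write_distribution(dist: GeneTreeDistribution, path):
    """Weighted Newick list, the same dialect the reader accepts."""
    with open(path, "w") as fh:
        for w, t in zip(dist.weights, dist.topologies):
            fh.write(f"{w:.10g}\t{top.to_newick(t, dist.family.leaf_labels)}\n")


# ---------------------------------------------------------------------------
# dendropy <-> canonical structs


def dendropy_to_struct(tree: dendropy.Tree, index: Mapping[str, int]):
    """Rooted canonical struct from a rooted binary dendropy tree."""

    def rec(node):
        if node.is_leaf():
            return index[node.taxon.label]
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("tree is not binary")
        return (rec(kids[0]), rec(kids[1]))

    return top.canon_rooted(rec(tree.seed_node))


def dendropy_to_unrooted(tree: dendropy.Tree, index: Mapping[str, int]):
    """Canonical unrooted struct; accepts bifurcating or trifurcating root."""
    kids = tree.seed_node.child_nodes()

    def rec(node):
        if node.is_leaf():
            return index[node.taxon.label]
        ch = node.child_nodes()
        if len(ch) != 2:
            raise ValueError("non-binary internal node")
        return (rec(ch[0]), rec(ch[1]))

    if len(kids) == 2:
        rooted = (rec(kids[0]), rec(kids[1]))
    elif len(kids) == 3:
        rooted = ((rec(kids[0]), rec(kids[1])), rec(kids[2]))
    else:
        raise ValueError("root must have 2 or 3 children")
    return top.unroot(top.canon_rooted(rooted))


def struct_to_dendropy(struct, names: Sequence[str], taxon_namespace=None):
    nwk = top.to_newick(struct, names)
    return dendropy.Tree.get(
        data=nwk, schema="newick", taxon_namespace=taxon_namespace,
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# species mapping


def map_leaves_to_species(leaf_labels: Sequence[str], species_names: Sequence[str],
                          case_insensitive: bool = False) -> dict[str, str]:
    """Map each leaf to the longest species name contained in its label.

    Raises on leaves matching no species, and on ties where two species
    names of equal length both occur in one label.
    """
    if not species_names:
        raise LeafMappingError("empty species list")
    if len(set(species_names)) != len(species_names):
        raise LeafMappingError("species names are not unique")
    out = {}
    for leaf in leaf_labels:
        hay = leaf.lower() if case_insensitive else leaf
        matches = []
        for sp in species_names:
            needle = sp.lower() if case_insensitive else sp
            if needle in hay:
                matches.append(sp)
        if not matches:
            raise LeafMappingError(f"leaf {leaf!r} matches no species name")
        best_len = max(len(m) for m in matches)
        best = [m for m in matches if len(m) == best_len]
        if len(best) > 1:
            raise LeafMappingError(
                f"leaf {leaf!r} matches species {best} equally well"
            )
        out[leaf] = best[0]
    return out


# ---------------------------------------------------------------------------
# bipartitions / splits


def _leafsets(tree_or_struct):
    """(all_labels frozenset, list of clade frozensets below each edge)."""
    if isinstance(tree_or_struct, ConsensusTree):
        return tree_or_struct.leaf_set, list(tree_or_struct.splits)
    if isinstance(tree_or_struct, dendropy.Tree):
        tree = tree_or_struct
        clades = []

        def rec(node):
            if node.is_leaf():
                return frozenset((node.taxon.label,))
            cl = frozenset().union(*(rec(c) for c in node.child_nodes()))
            clades.append(cl)
            return cl

        allset = rec(tree.seed_node)
        clades.pop()  # root clade is not an edge
        kids = tree.seed_node.child_nodes()
        if len(kids) == 2 and not kids[1].is_leaf():
            # a bifurcating root's two child edges are one unrooted edge
            second = frozenset(l.taxon.label
                               for l in kids[1].leaf_iter())
            clades.remove(second)
        return allset, clades
    struct = tree_or_struct
    if isinstance(struct, tuple) and len(struct) == 3:
        m, A, B = struct
        struct = top.canon_rooted(((A, B), m))
    allset = frozenset(top.leaves_of(struct))
    clades = []

    def rec2(t):
        if isinstance(t, int):
            return frozenset((t,))
        cl = rec2(t[0]) | rec2(t[1])
        clades.append(cl)
        return cl

    rec2(struct)
    clades.pop()
    if not isinstance(struct[1], int):
        clades.remove(frozenset(top.leaves_of(struct[1])))
    return allset, clades


def bipartitions(tree, nontrivial_only: bool = True, multree: bool = False,
                 leaf_map: Mapping[str, str] | None = None):
    """Set (plain mode) or multiset list (multree mode) of bipartitions.

    Unrooted interpretation.  In multree mode each side is a multiset of
    species labels obtained through ``leaf_map``; the result is a list since
    multisets may repeat.
    """
    allset, clades = _leafsets(tree)
    if len(allset) < 3:
        raise ValueError("need at least 3 leaves")
    out = []
    seen = set()
    for cl in clades:
        other = allset - cl
        if not other:
            continue
        if multree:
            if leaf_map is None:
                raise ValueError("multree mode requires leaf_map")
            from collections import Counter

            bp = Bipartition.of(
                Counter(leaf_map[l] for l in cl).items(),
                Counter(leaf_map[l] for l in other).items(),
            )
            # trivial = single leaf on one side
            if nontrivial_only and (len(cl) == 1 or len(other) == 1):
                continue
            out.append(bp)
        else:
            bp = Bipartition.of(cl, other)
            if nontrivial_only and bp.is_trivial:
                continue
            if bp not in seen:
                seen.add(bp)
                out.append(bp)
    return out if multree else set(out)


def split_set(tree) -> set[frozenset]:
    """Nontrivial unrooted splits, each as the frozenset side not containing
    the smallest label."""
    allset, clades = _leafsets(tree)
    ref = min(allset)
    n = len(allset)
    out = set()
    for cl in clades:
        side = cl if ref not in cl else allset - cl
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def split_accuracy(true_tree, estimate) -> float:
    """Fraction of the true tree's nontrivial unrooted splits present in the
    estimate.  1.0 iff the unrooted topologies agree (both resolved)."""
    ta, _ = _leafsets(true_tree)
    ea, _ = _leafsets(estimate)
    if ta != ea:
        raise ValueError("leaf sets differ between true tree and estimate")
    ts = split_set(true_tree)
    if not ts:
        raise ValueError("true tree has no nontrivial splits")
    es = split_set(estimate)
    return len(ts & es) / len(ts)


# ---------------------------------------------------------------------------
# consensus


def weighted_split_frequencies(samples) -> tuple[frozenset, dict]:
    """Cumulative weight of each nontrivial unrooted split over samples.

    ``samples`` is a sequence of (tree_or_struct, weight).
    Returns (common leaf set, {split: frequency}) with weights normalized.
    """
    if not samples:
        raise ValueError("empty sample")
    total = sum(w for _, w in samples)
    if total <= 0:
        raise ValueError("total sample weight is zero")
    freqs: dict[frozenset, float] = {}
    allset = None
    for tree, w in samples:
        ts, _ = _leafsets(tree)
        if allset is None:
            allset = ts
        elif ts != allset:
            raise ValueError("samples have differing leaf sets")
        for sp in split_set(tree):
            freqs[sp] = freqs.get(sp, 0.0) + w / total
    return allset, freqs


def _compatible(a: frozenset, b: frozenset, allset: frozenset) -> bool:
    if a <= b or b <= a:
        return True
    if not (a & b):
        return True
    return a | b == allset


def majority_consensus(samples, threshold: float = 0.5):
    """Majority-rule consensus over weighted tree samples.

    Keeps exactly the nontrivial splits with cumulative relative weight
    strictly greater than ``threshold`` (>= 0.5, which guarantees pairwise
    compatibility).  Returns (splits dict, newick string builder) as a
    ``ConsensusTree``.
    """
    if threshold < 0.5:
        raise ValueError("threshold must be >= 0.5")
    allset, freqs = weighted_split_frequencies(samples)
    eps = 1e-12
    kept = {
        sp: f for sp, f in freqs.items() if f > threshold + eps
    }
    return ConsensusTree(allset, kept)


@dataclass
class ConsensusTree:
    """A (possibly multifurcating) consensus, stored as its split set."""

    leaf_set: frozenset
    splits: dict  # split (side without min label) -> support

    def split_sides(self) -> set[frozenset]:
        return set(self.splits)

    def newick(self, support: bool = True) -> str:
        """Render as Newick, rooted (arbitrarily) at the smallest label.

        Splits become clades of that rooting; supports are written as
        internal node labels when requested.
        """
        ref = min(self.leaf_set)
        clades = sorted(self.splits, key=lambda s: (len(s), tuple(sorted(map(str, s)))))
        # each clade's parent = its smallest strict superset (or None = root)
        parent = {}
        for i, c in enumerate(clades):
            best = None
            for d in clades[i + 1:]:
                if c < d and (best is None or len(d) < len(best)):
                    best = d
            parent[c] = best

        def render(clade) -> str:
            kids = [c for c in clades if parent[c] == clade]
            covered = set().union(*kids) if kids else set()
            base = (clade if clade is not None else self.leaf_set - {ref})
            singles = sorted(base - covered, key=str)
            parts = [render(k) for k in sorted(kids, key=lambda s: (len(s), tuple(sorted(map(str, s)))))]
            parts += [str(s) for s in singles]
            inner = ",".join(parts)
            if clade is None:
                return f"({str(ref)},{inner});"
            if support:
                return f"({inner}){self.splits[clade]:.3f}"
            return f"({inner})"

        return render(None)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick(support=False), schema="newick",
            taxon_namespace=taxon_namespace, suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
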