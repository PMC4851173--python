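"""Nonparametric gene-tree uncertainty generator.

Bayesian phylogenetic programs return a posterior sample of topologies per
gene family; simulating that pipeline (sequences plus full tree inference)
is too slow for large studies.  This module emulates its outcome directly:
each true gene tree (with substitution-unit branch lengths) is turned into
a weighted distribution of topologies by repeated length-dependent NNI
perturbation, capturing the fact that short branches concentrate most of
the reconstruction uncertainty.

For each of ``n_draws`` draws the true topology is kept with probability
1 - min(pT, 1); otherwise every internal branch e is swapped independently
(one of its two NNI alternatives, chosen at random) with probability
p_e = min(1, pB * l_min / l_e), where l_min is the shortest internal branch
— so the shortest branch attains the cap pB and longer branches are
perturbed inversely proportionally to their length.  Distinct topologies
are collected with their frequencies as weights, truncated to the
``max_distinct`` most frequent, and the true topology is kept in the
support with at least one count (disable with ``force_true=False``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import _topology as top
from . import treeio
from .simulate import SimNode


@dataclass
class UncertaintyParams:
    """Perturbation parameters; dimensionless shape terms as in the study
    design (pT may exceed 1 before capping, meaning every draw perturbed)."""

    pT: float
    pB: float
    LT: float = float("nan")
    DT: float = float("nan")
    LB: float = float("nan")
    n_draws: int = 1000
    max_distinct: int = 160
    force_true: bool = True

    def __post_init__(self):
        if self.max_distinct < 1:
            raise ValueError("max_distinct must be >= 1")
        if self.pT < 0 or self.pB < 0:
            raise ValueError("probabilities must be non-negative")


def sample_uncertainty_params(rng, n_draws: int = 1000,
                              max_distinct: int = 160) -> UncertaintyParams:
    """Draw perturbation parameters from the study's laws:
    LT ~ U(2,5), DT ~ U(3,6), pT = 1.1 Beta(LT DT, DT);
    LB ~ U(1,5), pB = 1.5 Beta(LB, 1)."""
    LT = rng.uniform(2.0, 5.0)
    DT = rng.uniform(3.0, 6.0)
    pT = 1.1 * rng.beta(LT * DT, DT)
    LB = rng.uniform(1.0, 5.0)
    pB = 1.5 * rng.beta(LB, 1.0)
    return UncertaintyParams(pT, pB, LT, DT, LB, n_draws, max_distinct)


# ---------------------------------------------------------------------------
# mutable unrooted tree with persistent edges


class _MutableUnrooted:
    """Unrooted binary tree whose branches are persistent edge objects.

    An NNI across an internal branch re-attaches one neighboring branch
    from each endpoint; the branches themselves (and their lengths) keep
    their identity, so per-branch swap probabilities stay well defined
    through successive swaps within one draw.
    """

    def __init__(self, root: SimNode, label_index):
        self.leaf_label: dict[int, int] = {}
        self.ends: list[list[int]] = []  # edge id -> [node, node]
        self.lengths: list[float] = []
        self.incident: list[set] = []  # node id -> edge ids
        counter = [0]

        def new_node(label=None):
            nid = counter[0]
            counter[0] += 1
            self.incident.append(set())
            if label is not None:
                self.leaf_label[nid] = label
            return nid

        def link(u, v, length):
            eid = len(self.ends)
            self.ends.append([u, v])
            self.lengths.append(length)
            self.incident[u].add(eid)
            self.incident[v].add(eid)
            return eid

        def build(n: SimNode):
            nid = new_node(label_index[n.label] if not n.children else None)
            for c in n.children:
                cid = build(c)
                link(nid, cid, c.length)
            return nid

        rid = build(root)
        kids = sorted(self.incident[rid])
        if len(kids) != 2:
            raise ValueError("expected a binary rooted input tree")
        # suppress the root: merge its two incident edges into one
        e1, e2 = kids
        a = next(x for x in self.ends[e1] if x != rid)
        b = next(x for x in self.ends[e2] if x != rid)
        merged_len = self.lengths[e1] + self.lengths[e2]
        self.incident[a].discard(e1)
        self.incident[b].discard(e2)
        self.incident[rid] = set()
        self.ends[e1] = [a, b]
        self.lengths[e1] = merged_len
        self.incident[a].add(e1)
        self.incident[b].add(e1)
        self.ends[e2] = [-1, -1]  # retired
        self.internal_edges = sorted(
            eid for eid, (u, v) in enumerate(self.ends)
            if u >= 0 and u not in self.leaf_label and v not in self.leaf_label
        )
        self.internal_lengths = np.array(
            [self.lengths[e] for e in self.internal_edges])
        self._orig_ends = [list(e) for e in self.ends]
        self._orig_inc = [set(s) for s in self.incident]

    def reset(self):
        self.ends = [list(e) for e in self._orig_ends]
        self.incident = [set(s) for s in self._orig_inc]

    def _other(self, eid, node):
        u, v = self.ends[eid]
        return v if u == node else u

    def swap(self, internal_pos: int, which: int):
        """One of the two NNI alternatives across an internal branch."""
        eid = self.internal_edges[internal_pos]
        v, w = self.ends[eid]
        ev = sorted(x for x in self.incident[v] if x != eid)[0]
        ew = sorted(x for x in self.incident[w] if x != eid)[which]
        # move branch ev from v to w and ew from w to v
        self.incident[v].discard(ev)
        self.incident[w].discard(ew)
        self.ends[ev][self.ends[ev].index(v)] = w
        self.ends[ew][self.ends[ew].index(w)] = v
        self.incident[w].add(ev)
        self.incident[v].add(ew)

    def canon(self):
        adj = {n: [] for n in range(len(self.incident))
               if self.incident[n] or n in self.leaf_label}
        for eid, (u, v) in enumerate(self.ends):
            if u >= 0:
                adj[u].append(v)
                adj[v].append(u)
        adj = {n: nb for n, nb in adj.items() if nb}
        return top._canon_unrooted_from_adj(adj, self.leaf_label)


# ---------------------------------------------------------------------------


def perturb_distribution(true_tree: SimNode, leaf_species: dict,
                         params: UncertaintyParams, rng,
                         family_id: int = 0) -> treeio.GeneTreeDistribution:
    """Weighted topology distribution emulating gene-tree uncertainty.

    ``true_tree`` is a rooted binary tree with positive substitution-unit
    branch lengths; ``leaf_species`` maps its leaf labels to species names.
    """
    labels = tuple(sorted(l.label for l in true_tree.leaves()))
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    index = {lab: i for i, lab in enumerate(labels)}
    mut = _MutableUnrooted(true_tree, index)
    true_topo = mut.canon()
    fam = treeio.GeneFamily(family_id, labels,
                            {lab: leaf_species[lab] for lab in labels})

    n_internal = len(mut.internal_edges)
    counts: Counter = Counter()
    p_perturb = min(params.pT, 1.0)
    if n_internal == 0 or p_perturb <= 0.0 or params.pB <= 0.0:
        counts[true_topo] = params.n_draws
    else:
        lens = np.maximum(mut.internal_lengths, 1e-12)
        lmin = lens.min()
        p_edge = np.minimum(1.0, params.pB * lmin / lens)
        for _ in range(params.n_draws):
            if rng.random() >= p_perturb:
                counts[true_topo] += 1
                continue
            fire = rng.random(n_internal) < p_edge
            if not fire.any():
                counts[true_topo] += 1
                continue
            mut.reset()
            for e in np.flatnonzero(fire):
                mut.swap(int(e), int(rng.integers(2)))
            counts[mut.canon()] += 1

    # truncate to the most frequent topologies, deterministically
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], top.struct_key(
        (kv[0][0], (kv[0][1], kv[0][2])))))
    kept = ranked[:params.max_distinct]
    if params.force_true and all(t != true_topo for t, _ in kept):
        kept = kept[:params.max_distinct - 1] + [(true_topo, 1)]
    topos = tuple(t for t, _ in kept)
    raw = np.array([c for _, c in kept], dtype=float)
    return treeio.GeneTreeDistribution(fam, topos, raw / raw.sum(),
                                       raw_counts=tuple(int(c) for c in raw))
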