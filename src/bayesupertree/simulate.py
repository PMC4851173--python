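"""Three-tree simulator: species tree, birth-death locus trees, and
multispecies-coalescent gene trees with gamma rate heterogeneity.

A replicate is generated as a cascade: an ultrametric species tree (Kingman
coalescent or Yule), with branch durations in generations; per gene family a
locus tree grown along the species tree by a birth-death process of gene
duplication and loss (extinct loci pruned); and per locus tree a gene tree
from the multispecies coalescent with ``individuals`` gene copies sampled
per locus, pairwise coalescence rate 1/(2 Ne) per pair per generation, and
lineages failing to coalesce escaping into the parent branch.

Branch durations are in generations throughout; coalescent units are
generations / (2 Ne).  Substitution-unit branch lengths are produced by
multiplying each branch by the substitution rate and by three independent
gamma rate multipliers (species, locus and gene level), giving
non-clock-like trees whose short branches drive the gene-tree-uncertainty
generator.

Duplication nodes merge gene lineages like speciations do (the copy-number
bottleneck at the duplication event itself is not modeled).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _topology as top


# ---------------------------------------------------------------------------
# light mutable tree nodes (converted to Newick at the boundary)


class SimNode:
    __slots__ = ("children", "length", "label", "species", "locus", "age",
                 "event")

    def __init__(self, label=None, length=0.0):
        self.children = []
        self.length = float(length)
        self.label = label
        self.species = None
        self.locus = None
        self.age = 0.0
        self.event = None

    def add(self, child):
        self.children.append(child)
        return child

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, lengths=True, scale=1.0) -> str:
        def rec(n):
            if not n.children:
                core = n.label
            else:
                core = "(" + ",".join(rec(c) for c in n.children) + ")"
            if lengths:
                return f"{core}:{n.length * scale:.8g}"
            return core

        return rec(self) + ";"

    def total_length(self) -> float:
        tot = 0.0
        stack = [self]
        while stack:
            n = stack.pop()
            tot += n.length
            stack.extend(n.children)
        return tot

    def max_depth(self) -> float:
        if not self.children:
            return self.length
        return self.length + max(c.max_depth() for c in self.children)

    def iter_nodes(self):
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def scale(self, factor):
        for n in self.iter_nodes():
            n.length *= factor
        return self


def to_struct(root: SimNode, label_index) -> tuple:
    """Canonical rooted struct of a binary SimNode tree."""

    def rec(n):
        if not n.children:
            return label_index[n.label]
        a, b = n.children
        return (rec(a), rec(b))

    return top.canon_rooted(rec(root))


# ---------------------------------------------------------------------------
# species trees


def sim_species_tree(n: int, mode: str, height_generations: float, ne: float,
                     rng) -> SimNode:
    """Ultrametric rooted species tree with branch lengths in generations.

    ``mode`` is "coalescent" (Kingman; waiting times Exp with rate
    C(k,2)/(2 Ne)) or "yule" (pure birth).  The tree is rescaled so the
    root-to-tip height equals ``height_generations``.
    """
    if n < 3:
        raise ValueError("need at least 3 species")
    names = [f"s{i + 1:02d}" for i in range(n)]
    nodes = [SimNode(label=nm) for nm in names]
    for nd in nodes:
        nd.age = 0.0
    if mode == "coalescent":
        t = 0.0
        active = list(nodes)
        while len(active) > 1:
            k = len(active)
            rate = k * (k - 1) / 2.0 / (2.0 * ne)
            t += rng.exponential(1.0 / rate)
            i, j = sorted(rng.choice(k, size=2, replace=False))
            parent = SimNode()
            parent.age = t
            b = active.pop(j)
            a = active.pop(i)
            parent.add(a)
            parent.add(b)
            active.append(parent)
        root = active[0]
    elif mode == "yule":
        # forward in time: split a random lineage; realized as ages backwards
        t = 0.0
        active = [SimNode(label=None)]
        while len(active) < n:
            k = len(active)
            t += rng.exponential(1.0 / k)
            idx = int(rng.integers(k))
            split = active[idx]
            split.age = t
            c1, c2 = SimNode(), SimNode()
            active[idx] = c1
            active.append(c2)
            split.add(c1)
            split.add(c2)
            root = split if k == 1 else root
        t_end = t + rng.exponential(1.0 / n)
        for i, leaf in enumerate(active):
            leaf.label = names[i]
            leaf.age = t_end
        # convert forward times to ages above tips
        for nd in root.iter_nodes():
            nd.age = t_end - nd.age if nd.children else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    _ages_to_lengths(root)
    h = root.max_depth()
    root.scale(height_generations / h)
    _lengths_to_ages(root)
    for nd in root.iter_nodes():
        nd.species = nd
    return root


def _ages_to_lengths(root: SimNode):
    def rec(n, parent_age):
        n.length = max(0.0, parent_age - n.age)
        for c in n.children:
            rec(c, n.age)

    rec(root, root.age)
    root.length = 0.0


def _lengths_to_ages(root: SimNode):
    h = root.max_depth()

    def rec(n, depth):
        n.age = h - depth
        for c in n.children:
            rec(c, depth + c.length)

    rec(root, 0.0)


# ---------------------------------------------------------------------------
# locus trees (birth-death of paralogous loci inside the species tree)


def sim_locus_tree(species_root: SimNode, birth: float, death: float, rng,
                   max_leaves: int = 2000) -> SimNode | None:
    """Locus tree grown along the species tree; extinct loci pruned.

    Returns the pruned locus tree (unary pass-through nodes suppressed,
    durations preserved) or None if the whole family went extinct.
    Duplication nodes are annotated ``event='dup'`` with both children in
    the same species branch; speciations carry ``event='spec'``.
    """
    counter = {"leaves": 0}
    locus_ids = {}

    def evolve_branch(species_node, t_remaining, cur_age):
        """One locus lineage inside the branch above species_node; returns a
        SimNode subtree or None if extinct."""
        if counter["leaves"] > max_leaves:
            raise RuntimeError("locus tree exploded; lower the birth rate")
        t = 0.0
        while True:
            rate = birth + death
            dt = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if dt >= t_remaining - t:
                return at_species_node(species_node, cur_age - (t_remaining - t))
            t += dt
            if rng.random() < (birth / rate if rate > 0 else 0.0):
                node = SimNode()
                node.age = cur_age - t
                node.species = species_node
                node.event = "dup"
                kids = []
                for _ in range(2):
                    sub = evolve_branch(species_node, t_remaining - t, node.age)
                    if sub is not None:
                        kids.append(sub)
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                node.add(kids[0])
                node.add(kids[1])
                return node
            return None  # loss

    def at_species_node(species_node, age):
        if not species_node.children:
            lid = locus_ids.get(species_node.label, 0)
            locus_ids[species_node.label] = lid + 1
            leaf = SimNode(label=f"{species_node.label}_L{lid + 1}")
            leaf.age = 0.0
            leaf.species = species_node
            counter["leaves"] += 1
            return leaf
        node = SimNode()
        node.age = species_node.age
        node.species = species_node
        node.event = "spec"
        kids = []
        for child in species_node.children:
            sub = evolve_branch(child, child.length, species_node.age)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node.add(kids[0])
        node.add(kids[1])
        return node

    root = at_species_node(species_root, species_root.age)
    if root is None or not root.children:
        return root
    _set_lengths_from_ages(root)
    return root


def _set_lengths_from_ages(root: SimNode):
    def rec(n, parent_age):
        n.length = max(0.0, parent_age - n.age)
        for c in n.children:
            rec(c, n.age)

    rec(root, root.age)
    root.length = 0.0


# ---------------------------------------------------------------------------
# gene trees (multispecies coalescent inside the locus tree)


def sim_gene_tree(locus_root: SimNode, ne: float, individuals: int, rng) -> SimNode:
    """Multispecies-coalescent gene tree, branch lengths in generations.

    ``individuals`` gene copies are sampled per locus leaf; within each
    locus branch pairs coalesce at rate 1/(2 Ne); remaining lineages exit
    into the parent branch, and the final coalescent above the root is
    unconstrained.
    """
    if individuals < 1:
        raise ValueError("need at least one individual per species")

    def coalesce(lineages, age_lo, age_hi, locus_node):
        t = age_lo
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0 / (2.0 * ne)
            t += rng.exponential(1.0 / rate)
            if t >= age_hi:
                return lineages
            i, j = sorted(rng.choice(k, size=2, replace=False))
            node = SimNode()
            node.age = t
            node.locus = locus_node
            b = lineages.pop(j)
            a = lineages.pop(i)
            node.add(a)
            node.add(b)
            lineages.append(node)
        return lineages

    def rec(locus_node, age_top):
        """Active gene lineages at the top of the branch above locus_node."""
        if not locus_node.children:
            lin = []
            for ind in range(1, individuals + 1):
                leaf = SimNode(label=f"{locus_node.label}_i{ind}")
                leaf.age = 0.0
                leaf.locus = locus_node
                lin.append(leaf)
        else:
            lin = []
            for child in locus_node.children:
                lin.extend(rec(child, locus_node.age))
        return coalesce(lin, locus_node.age, age_top, locus_node)

    lineages = rec(locus_root, locus_root.age)
    final = coalesce(lineages, locus_root.age, math.inf, locus_root)
    root = final[0]
    _set_lengths_from_ages(root)
    return root


# ---------------------------------------------------------------------------
# rate heterogeneity


def apply_rate_heterogeneity(root: SimNode, gamma_shape: float, rng,
                             base_rate: float = 1.0) -> SimNode:
    """Multiply every branch by an independent Gamma(shape, 1/shape)
    multiplier (mean one) and by the base substitution rate, in place."""
    if gamma_shape <= 0:
        raise ValueError("gamma shape must be positive")
    for n in root.iter_nodes():
        mult = rng.gamma(gamma_shape, 1.0 / gamma_shape)
        n.length *= mult * base_rate
    return root


def hierarchical_rate_multipliers(gene_root: SimNode, species_mult, locus_mult,
                                  gene_shape: float, subst_rate: float, rng):
    """Substitution-unit lengths composing species x locus x gene gamma
    multipliers multiplicatively; each gene branch uses the multiplier of
    the locus (and species) branch containing its child end."""
    for n in gene_root.iter_nodes():
        hg = rng.gamma(gene_shape, 1.0 / gene_shape)
        hl = locus_mult.get(id(n.locus), 1.0) if n.locus is not None else 1.0
        sp = n.locus.species if n.locus is not None else None
        hs = species_mult.get(id(sp), 1.0) if sp is not None else 1.0
        n.length *= hg * hl * hs * subst_rate
    return gene_root


# ---------------------------------------------------------------------------
# replicate-level simulation (study conditions)


@dataclass
class SimParams:
    """Replicate-level parameter laws of the simulation study.

    Defaults are the full study ranges; pass narrower bounds for
    desk-scale runs.  All rates are per generation.
    """

    n_species_range: tuple = (10, 80)
    height_range: tuple = (100.0, 10000.0)
    edup_range: tuple = (1e-3, 4.0)
    n_families_range: tuple = (2, 50)
    individuals_range: tuple = (1, 10)
    ne_base: float = 2000.0
    ne_lognormal_sd: float = 0.25
    subst_rate: float = 0.001
    gamma_shape: float = 1.0
    loss_frac_max: float = 0.75
    coal_length_window: tuple = (0.05, 5.0)
    species_mode: str = "coalescent"


@dataclass
class FamilyTruth:
    gene_tree: SimNode  # substitution-unit branch lengths
    locus_tree: SimNode
    leaf_labels: tuple
    leaf_species: dict  # label -> species name
    birth: float
    death: float


@dataclass
class Replicate:
    species_tree: SimNode  # generations
    species_names: list
    ne: float
    individuals: int
    families: list
    params: dict  # provenance of every draw

    @property
    def species_struct(self):
        idx = {nm: i for i, nm in enumerate(self.species_names)}
        return to_struct(self.species_tree, idx)


def sim_replicate(params: SimParams, rng, min_family_leaves: int = 4) -> Replicate:
    """Draw one replicate: all parameters from their study distributions,
    then the species tree / locus trees / gene trees cascade.

    Families whose gene tree ends up with fewer than ``min_family_leaves``
    leaves (possible under heavy loss) are redrawn, so every family carries
    topological information.
    """
    n_species = int(rng.integers(params.n_species_range[0],
                                 params.n_species_range[1] + 1))
    height = rng.uniform(*params.height_range)
    edup = rng.uniform(*params.edup_range)
    n_families = int(rng.integers(params.n_families_range[0],
                                  params.n_families_range[1] + 1))
    individuals = int(rng.integers(params.individuals_range[0],
                                   params.individuals_range[1] + 1))
    ne = params.ne_base * rng.lognormal(0.0, params.ne_lognormal_sd)

    sp = sim_species_tree(n_species, params.species_mode, height, ne, rng)
    # keep the species-tree length (coalescent units) inside the design
    # window by rescaling the time axis, recording the factor
    sigma = sp.total_length()
    coal_len = sigma / (2.0 * ne)
    lo, hi = params.coal_length_window
    rescale = 1.0
    if coal_len < lo:
        rescale = lo / coal_len
    elif coal_len > hi:
        rescale = hi / coal_len
    if rescale != 1.0:
        sp.scale(rescale)
        _lengths_to_ages(sp)
        height *= rescale
        sigma *= rescale

    species_names = sorted(l.label for l in sp.leaves())
    species_mult = {id(n): rng.gamma(params.gamma_shape, 1.0 / params.gamma_shape)
                    for n in sp.iter_nodes()}

    families = []
    fam_draws = []
    attempts = 0
    while len(families) < n_families:
        attempts += 1
        if attempts > 50 * n_families:
            raise RuntimeError("too many extinct families; check rates")
        birth = rng.exponential(edup / sigma)
        death = rng.uniform(0.0, params.loss_frac_max * birth)
        locus = sim_locus_tree(sp, birth, death, rng)
        if locus is None or len(locus.leaves()) < 2:
            continue
        gene = sim_gene_tree(locus, ne, individuals, rng)
        if len(gene.leaves()) < min_family_leaves:
            continue
        locus_mult = {id(n): rng.gamma(params.gamma_shape,
                                       1.0 / params.gamma_shape)
                      for n in locus.iter_nodes()}
        hierarchical_rate_multipliers(gene, species_mult, locus_mult,
                                      params.gamma_shape, params.subst_rate,
                                      rng)
        labels = tuple(sorted(l.label for l in gene.leaves()))
        leaf_species = {lab: lab.split("_")[0] for lab in labels}
        families.append(FamilyTruth(gene, locus, labels, leaf_species,
                                    birth, death))
        fam_draws.append({"birth": birth, "death": death,
                          "n_leaves": len(labels)})

    prov = {
        "n_species": n_species, "height_generations": height,
        "edup": edup, "n_families": n_families, "individuals": individuals,
        "ne": ne, "sigma_generations": sigma,
        "coal_length": sigma / (2.0 * ne), "coal_rescale": rescale,
        "families": fam_draws,
    }
    return Replicate(sp, species_names, ne, individuals, families, prov)


def scaled_down_params() -> SimParams:
    """Desk-scale study conditions: 8-15 species, 5-10 families, 1-3
    individuals per species; every other law at its full-study value."""
    return SimParams(n_species_range=(8, 15), n_families_range=(5, 10),
                     individuals_range=(1, 3))


# ---------------------------------------------------------------------------
# output


def write_replicate(rep: Replicate, outdir):
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "species.nwk"), "w") as fh:
        fh.write(rep.species_tree.newick() + "\n")
    with open(os.path.join(outdir, "species_coal.nwk"), "w") as fh:
        fh.write(rep.species_tree.newick(scale=1.0 / (2.0 * rep.ne)) + "\n")
    with open(os.path.join(outdir, "species.txt"), "w") as fh:
        for nm in rep.species_names:
            fh.write(nm + "\n")
    for i, fam in enumerate(rep.families):
        with open(os.path.join(outdir, f"genefam_{i + 1:03d}.nwk"), "w") as fh:
            fh.write(fam.gene_tree.newick() + "\n")
    with open(os.path.join(outdir, "params.json"), "w") as fh:
        json.dump(rep.params, fh, indent=1, sort_keys=True)
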