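"""Independent brute-force reimplementations used only as test oracles.

These deliberately share no code with the package's reconciliation engine:
LCA mappings are computed by leaf-set intersection on freshly parsed
structures, rootings are enumerated explicitly, and mulRF compares
bipartition multisets assembled by direct traversal.
"""

from collections import Counter


def leafset(t):
    if isinstance(t, int):
        return frozenset((t,))
    return leafset(t[0]) | leafset(t[1])


def species_nodes(s_struct):
    """List of (node struct, leaf set) for every node of a rooted struct."""
    out = []

    def rec(t):
        ls = leafset(t)
        out.append((t, ls))
        if not isinstance(t, int):
            rec(t[0])
            rec(t[1])

    rec(s_struct)
    return out


def naive_lca(s_struct, species_set):
    """Smallest clade of the species tree containing species_set."""
    best = None
    for node, ls in species_nodes(s_struct):
        if species_set <= ls and (best is None or len(ls) < len(best[1])):
            best = (node, ls)
    return best[0]


def naive_depth(s_struct, node):
    def rec(t, d):
        if t == node:
            return d
        if isinstance(t, int):
            return None
        for c in t:
            r = rec(c, d + 1)
            if r is not None:
                return r
        return None

    return rec(s_struct, 0)


def gene_species_set(g_struct, leaf_species):
    if isinstance(g_struct, int):
        return frozenset((leaf_species[g_struct],))
    return (gene_species_set(g_struct[0], leaf_species)
            | gene_species_set(g_struct[1], leaf_species))


def naive_dup_loss(g_struct, s_struct, leaf_species):
    """Duplications and losses of the LCA reconciliation, recomputed from
    scratch with leaf-set LCAs and path depths."""
    dups = 0
    losses = 0

    def mapping(t):
        return naive_lca(s_struct, gene_species_set(t, leaf_species))

    def rec(t):
        nonlocal dups, losses
        if isinstance(t, int):
            return
        m = mapping(t)
        m1 = mapping(t[0])
        m2 = mapping(t[1])
        is_dup = m == m1 or m == m2
        dups += is_dup
        dm = naive_depth(s_struct, m)
        losses += (naive_depth(s_struct, m1) - dm
                   + naive_depth(s_struct, m2) - dm
                   - (0 if is_dup else 2))
        rec(t[0])
        rec(t[1])

    rec(g_struct)
    return dups, losses


def naive_deep_coal(g_struct, s_struct, leaf_species):
    """Extra lineages: for every non-root species node count the gene-tree
    edges whose child map lies at-or-below it and whose parent map lies
    strictly above, minus one."""
    def mapping(t):
        return naive_lca(s_struct, gene_species_set(t, leaf_species))

    gene_edges = []

    def rec(t, parent_map):
        m = mapping(t)
        if parent_map is not None:
            gene_edges.append((m, parent_map))
        if not isinstance(t, int):
            rec(t[0], m)
            rec(t[1], m)

    rec(g_struct, None)
    total = 0
    nodes = species_nodes(s_struct)
    root_ls = leafset(s_struct)
    for node, ls in nodes:
        if ls == root_ls:
            continue
        lineages = 0
        for child_m, parent_m in gene_edges:
            cls = leafset(child_m) if not isinstance(child_m, int) else frozenset((child_m,))
            pls = leafset(parent_m) if not isinstance(parent_m, int) else frozenset((parent_m,))
            if cls <= ls and pls > ls:
                lineages += 1
        total += max(0, lineages - 1)
    return total


def enumerate_rootings_costs(g_unrooted, s_struct, leaf_species, all_rootings):
    """Min DL (joint) and min deep-coalescence over explicit rootings."""
    best_dl = None
    best_ils = None
    for rooted in all_rootings(g_unrooted):
        d, l = naive_dup_loss(rooted, s_struct, leaf_species)
        i = naive_deep_coal(rooted, s_struct, leaf_species)
        if best_dl is None or d + l < best_dl[0] + best_dl[1]:
            best_dl = (d, l)
        if best_ils is None or i < best_ils:
            best_ils = i
    return best_dl[0], best_dl[1], best_ils


def naive_mulrf(g_unrooted, s_struct, leaf_species, splits_fn):
    """Symmetric difference of species-multiset bipartition multisets.

    ``splits_fn(unrooted_struct)`` must yield, for each internal edge, the
    leaf sets of one side (the oracle maps them to species multisets).
    """
    total = Counter(leaf_species)

    def canon(side_counter):
        other = total - side_counter
        if sum(side_counter.values()) <= 1 or sum(other.values()) <= 1:
            return None
        a = tuple(sorted(side_counter.items()))
        b = tuple(sorted(other.items()))
        return min(a, b)

    gene = Counter()
    for side in splits_fn(g_unrooted):
        key = canon(Counter(leaf_species[x] for x in side))
        if key is not None:
            gene[key] += 1
    # extended species tree: species with k copies -> k-leaf star.  A
    # pendant species edge is the same edge as that species' star edge, so
    # only internal species edges (>= 2 species on both sides) enter here;
    # pendant edges are covered by the star loop below.
    copies = Counter(leaf_species)
    ext = Counter()
    sp_sides = set()
    for node, ls in species_nodes(s_struct):
        if ls == leafset(s_struct):
            continue
        side = frozenset(ls)
        comp = leafset(s_struct) - side
        if len(side) < 2 or len(comp) < 2:
            continue
        sp_sides.add(min(side, comp, key=lambda s: tuple(sorted(s))))
    for side in sp_sides:
        key = canon(Counter({sp: copies[sp] for sp in side}))
        if key is not None:
            ext[key] += 1
    for sp, k in copies.items():
        if k > 1:
            key = canon(Counter({sp: k}))
            if key is not None:
                ext[key] += 1
    keys = set(gene) | set(ext)
    return sum(abs(gene.get(k, 0) - ext.get(k, 0)) for k in keys)
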