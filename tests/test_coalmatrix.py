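"""Distance-matrix baselines: matrices, merging, clustering, dispatch."""

import dendropy
import numpy as np
import pytest

from bayesupertree import coalmatrix as cm
from bayesupertree import simulate as sim
from bayesupertree import treeio


class TestGeneMatrix:
    def test_min_vs_avg_within(self):
        tr = dendropy.Tree.get(data="((x1:1,x2:3):0.0,y:1);",
                               schema="newick")
        lm = {"x1": "X", "x2": "X", "y": "Y"}
        assert cm.gene_matrix(tr, lm, "min").matrix[0, 1] == 2
        assert cm.gene_matrix(tr, lm, "avg").matrix[0, 1] == 3

    def test_single_copy_min_equals_avg(self, rng):
        sp = sim.sim_species_tree(5, "coalescent", 1000.0, 100.0, rng)
        loc = sim.sim_locus_tree(sp, 0.0, 0.0, rng)
        g = sim.sim_gene_tree(loc, 100.0, 1, rng)
        lm = {l.label: l.label.split("_")[0] for l in g.leaves()}
        a = cm.gene_matrix(g, lm, "min").matrix
        b = cm.gene_matrix(g, lm, "avg").matrix
        assert np.allclose(a, b)

    def test_unit_lengths_count_edges(self):
        tr = dendropy.Tree.get(data="((a:9,b:9):9,(c:9,d:9):9);",
                               schema="newick")
        lm = {x: x.upper() for x in "abcd"}
        m = cm.gene_matrix(tr, lm, "min", unit_lengths=True)
        i = {s: k for k, s in enumerate(m.species)}
        assert m.matrix[i["A"], i["B"]] == 2
        assert m.matrix[i["A"], i["C"]] == 3


class TestMerge:
    def test_min_and_mean(self):
        m1 = cm.SpeciesDistanceMatrix(("A", "B"),
                                      np.array([[0, 1], [1, 0]], float))
        m2 = cm.SpeciesDistanceMatrix(("A", "B"),
                                      np.array([[0, 3], [3, 0]], float))
        assert cm.merge_matrices([m1, m2], "min").matrix[0, 1] == 1
        assert cm.merge_matrices([m1, m2], "mean").matrix[0, 1] == 2

    def test_single_matrix_identity(self):
        m1 = cm.SpeciesDistanceMatrix(("A", "B"),
                                      np.array([[0, 2], [2, 0]], float))
        assert cm.merge_matrices([m1], "mean").matrix[0, 1] == 2

    def test_pair_in_one_gene_only(self):
        full = cm.SpeciesDistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 7], [2, 0, 6], [7, 6, 0]], float))
        partial = cm.SpeciesDistanceMatrix(
            ("A", "B"), np.array([[0, 4], [4, 0]], float))
        for rule in ("min", "mean"):
            merged = cm.merge_matrices([full, partial], rule)
            i = {s: k for k, s in enumerate(merged.species)}
            # pair (A, C) appears in one gene only: that gene's value
            assert merged.matrix[i["A"], i["C"]] == 7

    def test_uncovered_pair_errors(self):
        m1 = cm.SpeciesDistanceMatrix(("A", "B"),
                                      np.array([[0, 2], [2, 0]], float))
        m2 = cm.SpeciesDistanceMatrix(("C", "D"),
                                      np.array([[0, 5], [5, 0]], float))
        with pytest.raises(ValueError, match="not covered"):
            cm.merge_matrices([m1, m2], "mean")


class TestClustering:
    def test_three_species(self):
        m = cm.SpeciesDistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float))
        for meth in ("upgma", "single_linkage"):
            t = cm.build_species_tree(m, meth)
            assert "(A,B)" in t.as_string(schema="newick").replace("'", "")

    def test_matches_scipy_linkage_on_tiefree_input(self, rng):
        """Hand-rolled agglomeration equals scipy's average/single linkage
        whenever no ties occur."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = 6
            pts = rng.random((n, 3))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            mat = cm.SpeciesDistanceMatrix(
                tuple(f"t{i}" for i in range(n)), D)
            for meth, smeth in (("upgma", "average"),
                                ("single_linkage", "single")):
                mine = cm.build_species_tree(mat, meth)
                Z = linkage(squareform(D), method=smeth)
                members = {i: frozenset([f"t{i}"]) for i in range(n)}
                ref = set()
                for k, (a, b, _, _) in enumerate(Z):
                    mem = members[int(a)] | members[int(b)]
                    members[n + k] = mem
                    if 2 <= len(mem) <= n - 1:
                        ref.add(mem)
                mine_clades = set()

                def rec(node):
                    if node.is_leaf():
                        return frozenset([node.taxon.label])
                    s = frozenset().union(*(rec(c)
                                            for c in node.child_nodes()))
                    if 2 <= len(s) <= n - 1:
                        mine_clades.add(s)
                    return s

                rec(mine.seed_node)
                assert mine_clades == ref


class TestDispatch:
    def test_method_table(self):
        assert cm.METHODS["GLASS"] == ("min", "min", "single_linkage")
        assert cm.METHODS["SD"] == ("min", "mean", "upgma")
        assert cm.METHODS["STEAC"] == ("avg", "mean", "upgma")
        assert cm.METHODS["MAC"] == ("avg", "min", "single_linkage")

    def test_all_methods_recover_clean_tree(self, rng):
        """One clock-like, single-copy, ILS-free gene suffices for every
        method to recover the generating topology."""
        sp = sim.sim_species_tree(7, "coalescent", 100000.0, 10.0, rng)
        loc = sim.sim_locus_tree(sp, 0.0, 0.0, rng)
        g = sim.sim_gene_tree(loc, 10.0, 1, rng)
        lm = {l.label: l.label.split("_")[0] for l in g.leaves()}
        truth = dendropy.Tree.get(data=sp.newick(), schema="newick",
                                  preserve_underscores=True)
        for meth in cm.METHODS:
            est = cm.run_method([g], [lm], meth, "true")
            assert treeio.split_accuracy(truth, est) == 1.0

    def test_min_leq_mean_orderings(self, rng):
        """GLASS-style min entries never exceed STEAC-style averages at
        both the within-gene and across-gene stages."""
        sp = sim.sim_species_tree(5, "coalescent", 3000.0, 500.0, rng)
        mats_min, mats_avg = [], []
        for _ in range(3):
            loc = sim.sim_locus_tree(sp, 1e-4, 0.0, rng)
            g = sim.sim_gene_tree(loc, 500.0, 2, rng)
            lm = {l.label: l.label.split("_")[0] for l in g.leaves()}
            mats_min.append(cm.gene_matrix(g, lm, "min"))
            mats_avg.append(cm.gene_matrix(g, lm, "avg"))
        for a, b in zip(mats_min, mats_avg):
            assert (a.matrix <= b.matrix + 1e-12).all()
        merged_min = cm.merge_matrices(mats_min, "min")
        merged_mean = cm.merge_matrices(mats_min, "mean")
        assert (merged_min.matrix <= merged_mean.matrix + 1e-12).all()

    def test_gene_order_invariance(self, rng):
        sp = sim.sim_species_tree(6, "coalescent", 3000.0, 500.0, rng)
        trees, maps = [], []
        for _ in range(4):
            loc = sim.sim_locus_tree(sp, 1e-4, 0.0, rng)
            g = sim.sim_gene_tree(loc, 500.0, 1, rng)
            trees.append(g)
            maps.append({l.label: l.label.split("_")[0]
                         for l in g.leaves()})
        for meth in cm.METHODS:
            a = cm.run_method(trees, maps, meth, "true")
            b = cm.run_method(trees[::-1], maps[::-1], meth, "true")
            assert treeio.split_accuracy(a, b) == 1.0
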