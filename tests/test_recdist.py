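"""Reconciliation and mulRF distances against independent brute-force
oracles (see oracles.py — a from-scratch second implementation)."""

import numpy as np
import pytest

from bayesupertree import _topology as top
from bayesupertree import recdist as rd

import oracles
from conftest import random_multree_instance

A, B, C = 0, 1, 2


class TestRootedReconciliation:
    def test_congruent_single_copy(self):
        g = top.canon_rooted(((A, B), C))
        s = top.canon_rooted(((A, B), C))
        assert rd.dup_loss(g, s, [A, B, C]) == (0, 0)
        assert rd.deep_coal(g, s, [A, B, C]) == 0

    def test_three_taxon_discordance(self):
        g = top.canon_rooted(((A, B), C))
        s = top.canon_rooted(((A, C), B))
        assert rd.dup_loss(g, s, [A, B, C]) == (1, 3)
        assert rd.deep_coal(g, s, [A, B, C]) == 1

    def test_paralog_pair(self):
        # G=((a1,a2),b) vs S=(A,B): one duplication inside A, no losses,
        # no extra lineages
        g = top.canon_rooted(((0, 1), 2))
        s = top.canon_rooted((A, B))
        assert rd.dup_loss(g, s, [A, A, B]) == (1, 0)
        assert rd.deep_coal(g, s, [A, A, B]) == 0

    def test_lca_map_invariants(self):
        g = top.canon_rooted(((A, B), C))
        s = top.canon_rooted(((A, C), B))
        sidx = rd.SpeciesIndex(s)
        m = rd.lca_map(g, sidx, [A, B, C])
        assert m[(A, B)] == 0  # root of S (preorder id 0)
        g2 = top.canon_rooted(((0, 1), 2))
        s2 = rd.SpeciesIndex(top.canon_rooted((A, B)))
        m2 = rd.lca_map(g2, s2, [A, A, B])
        assert m2[(0, 1)] == s2.leaf_node[A]

    def test_unmapped_leaf_errors(self):
        g = top.canon_rooted(((A, B), C))
        with pytest.raises(ValueError):
            rd.lca_map(g, top.canon_rooted((A, B)), [A, B, C])

    def test_against_naive_oracle(self, rng):
        """dup_loss / deep_coal equal a from-scratch reimplementation."""
        for _ in range(60):
            s, g, ls = random_multree_instance(rng)
            restricted = rd.restrict_struct(s, set(ls))
            sidx = rd.SpeciesIndex(restricted)
            uidx = top.UnrootedIndex(g)
            rooted = uidx.root_at_edge(0)
            assert rd.dup_loss(rooted, sidx, ls) == oracles.naive_dup_loss(
                rooted, restricted, ls)
            assert rd.deep_coal(rooted, sidx, ls) == oracles.naive_deep_coal(
                rooted, restricted, ls)


class TestMinOverRoots:
    def test_congruent_tree_zero(self, rng):
        for n in (4, 6, 8):
            s = top.random_rooted(range(n), rng)
            gidx = rd.GeneTopologyIndex(top.unroot(s), list(range(n)))
            d1, d2, d3, r1, r2 = rd.min_over_roots(gidx, rd.SpeciesIndex(s))
            assert (d1, d2, d3) == (0, 0, 0)
            # the optimal root edge corresponds to S's own root split
            assert gidx.uidx.root_at_edge(r1) == s

    def test_three_leaf_rooting(self):
        g = top.unroot(top.canon_rooted(((A, B), C)))
        s = top.canon_rooted(((A, B), C))
        d1, d2, d3, _, _ = rd.min_over_roots(
            rd.GeneTopologyIndex(g, [A, B, C]), rd.SpeciesIndex(s))
        assert (d1, d2, d3) == (0, 0, 0)

    def test_matches_exhaustive_rooting_oracle(self, rng):
        """DP minima equal explicit enumeration over every rooting."""
        for _ in range(60):
            s, g, ls = random_multree_instance(rng)
            restricted = rd.restrict_struct(s, set(ls))
            sidx = rd.SpeciesIndex(restricted)
            d1, d2, d3, _, _ = rd.min_over_roots(
                rd.GeneTopologyIndex(g, ls), sidx)
            b1, b2, b3 = oracles.enumerate_rootings_costs(
                g, restricted, ls, top.all_rootings)
            assert (d1, d2, d3) == (b1, b2, b3)


class TestMulRF:
    def test_identical_single_copy_zero(self, rng):
        s = top.random_rooted(range(6), rng)
        dv = rd.distance_vector(top.unroot(s), s, list(range(6)), "DLIR")
        assert dv.mulrf == 0

    def test_three_leaf_unrooted_has_no_splits(self):
        # unrooted 3-leaf trees are stars: mulRF 0 regardless of rooting
        g = top.unroot(top.canon_rooted(((A, B), C)))
        dv = rd.distance_vector(g, top.canon_rooted(((A, C), B)),
                                [A, B, C], "DLIR")
        assert dv.mulrf == 0

    def test_paralog_example(self):
        # G=((a1,b),(a2,c)) vs S=((A,B),C): G split {A,B}|{A,C} vs
        # extended-S split {A,A}|{B,C} -> symmetric difference 2
        g = top.unroot(top.canon_rooted(((0, 2), (1, 3))))
        dv = rd.distance_vector(g, top.canon_rooted(((A, B), C)),
                                [A, A, B, C], "DLIR")
        assert dv.mulrf == 2

    def test_rerooting_invariance(self, rng):
        for _ in range(20):
            s, g, ls = random_multree_instance(rng, n_species_max=5)
            if len(set(ls)) < 3:
                continue
            restricted = rd.restrict_struct(s, set(ls))
            vals = set()
            for s2 in top.all_rootings(top.unroot(restricted)):
                dv = rd.distance_vector(g, s2, ls, "DLIR")
                vals.add(dv.mulrf)
            assert len(vals) == 1

    def test_against_naive_oracle(self, rng):
        def sides(gu):
            uidx = top.UnrootedIndex(gu)
            for e, (u, v) in enumerate(uidx.edges):
                if u in uidx.leaf_label or v in uidx.leaf_label:
                    continue
                yield top._leafset_away(uidx, v, u)

        for _ in range(60):
            s, g, ls = random_multree_instance(rng)
            restricted = rd.restrict_struct(s, set(ls))
            dv = rd.distance_vector(g, s, ls, "DLIR")
            assert dv.mulrf == oracles.naive_mulrf(g, restricted, ls, sides)

    def test_even_difference_when_counts_match(self, rng):
        """If both split multisets have equal cardinality the symmetric
        difference is even."""
        for _ in range(30):
            s, g, ls = random_multree_instance(rng)
            restricted = rd.restrict_struct(s, set(ls))
            gidx = rd.GeneTopologyIndex(g, ls)
            sidx = rd.SpeciesIndex(restricted)
            ext = rd.extended_species_splits(sidx, gidx.copy_counts)
            if sum(gidx.split_counter.values()) == sum(ext.values()):
                assert rd.mulrf_from_counters(gidx.split_counter, ext) % 2 == 0


class TestDistanceVector:
    def test_congruent_family_all_zero(self, rng):
        s = top.random_rooted(range(5), rng)
        dv = rd.distance_vector(top.unroot(s), s, list(range(5)), "DLIR")
        assert dv.as_tuple("DLIR") == (0, 0, 0, 0)
        dv = rd.distance_vector(top.unroot(s), s, list(range(5)), "DLI")
        assert dv.as_tuple("DLI") == (0, 0, 0)

    def test_missing_species_errors(self):
        g = top.unroot(top.canon_rooted(((0, 1), (2, 3))))
        with pytest.raises(ValueError):
            rd.distance_vector(g, top.canon_rooted((A, B)), [0, 1, 2, 3])

    def test_restriction_applied(self, rng):
        """Species absent from the family do not inflate losses."""
        s = top.random_rooted(range(8), rng)
        sub = top.random_rooted(range(4), rng)
        g = top.unroot(sub)
        dv = rd.distance_vector(g, s, list(range(4)), "DLI")
        restricted = rd.restrict_struct(s, {0, 1, 2, 3})
        dv2 = rd.distance_vector(g, restricted, list(range(4)), "DLI")
        assert dv.as_tuple("DLI") == dv2.as_tuple("DLI")

    def test_extra_gene_copy_never_decreases_dups(self, rng):
        for _ in range(15):
            s, g, ls = random_multree_instance(rng, leaves_max=6)
            dv = rd.distance_vector(g, s, ls, "DLI")
            # graft one more copy of species ls[0] onto the first edge
            L = len(ls)
            uidx = top.UnrootedIndex(g)
            rooted = uidx.root_at_edge(0)
            bigger = top.unroot(top.canon_rooted((rooted, L)))
            dv2 = rd.distance_vector(bigger, s, ls + [ls[0]], "DLI")
            assert dv2.dups >= dv.dups


class TestScalingConstants:
    def test_dup_constant_is_leafcount_minus_one(self, rng):
        g = top.random_unrooted(range(4), rng)
        gidx = rd.GeneTopologyIndex(g, [0, 1, 2, 3])
        m = rd.scaling_constants(gidx, [gidx],
                                 [top.random_rooted(range(4), rng)], "DLI")
        assert m[0] == 3

    def test_congruent_input_floors_at_one(self, rng):
        s = top.random_rooted(range(5), rng)
        gidx = rd.GeneTopologyIndex(top.unroot(s), list(range(5)))
        m = rd.scaling_constants(gidx, [gidx], [s], "DLI")
        assert m[1] == 1 and m[2] == 1

    def test_max_matches_bruteforce(self, rng):
        refs = [top.random_rooted(range(5), rng) for _ in range(10)]
        topos = [top.random_unrooted(range(5), rng) for _ in range(5)]
        ls = list(range(5))
        gidxs = [rd.GeneTopologyIndex(t, ls) for t in topos]
        m = rd.scaling_constants(gidxs[0], gidxs, refs, "DLI")
        best_loss = 0
        best_ils = 0
        for ref in refs:
            sidx = rd.SpeciesIndex(ref)
            for gi in gidxs:
                _, l, i, _, _ = rd.min_over_roots(gi, sidx)
                best_loss = max(best_loss, l)
                best_ils = max(best_ils, i)
        assert m[1] == max(1, best_loss)
        assert m[2] == max(1, best_ils)
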