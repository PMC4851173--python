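"""Three-tree simulator: shapes, expectations, coalescent closed form."""

import numpy as np
import pytest

from bayesupertree import _topology as top
from bayesupertree import simulate as sim


def tip_depths(root):
    out = []

    def rec(n, d):
        d += n.length
        if not n.children:
            out.append(d)
        for c in n.children:
            rec(c, d)

    rec(root, -root.length)
    return out


class TestSpeciesTree:
    @pytest.mark.parametrize("mode", ["coalescent", "yule"])
    def test_shape_and_height(self, mode, rng):
        sp = sim.sim_species_tree(6, mode, 5000.0, 2000.0, rng)
        assert len(sp.leaves()) == 6
        assert np.allclose(tip_depths(sp), 5000.0)
        internal = [n for n in sp.iter_nodes() if n.children]
        assert len(internal) == 5

    def test_minimum_size(self, rng):
        with pytest.raises(ValueError):
            sim.sim_species_tree(2, "coalescent", 100.0, 10.0, rng)


class TestLocusTree:
    def test_no_turnover_reproduces_species_tree(self, rng):
        sp = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0, rng)
        loc = sim.sim_locus_tree(sp, 0.0, 0.0, rng)
        assert sorted(l.label for l in loc.leaves()) == [
            f"s{i:02d}_L1" for i in range(1, 6)]

    def test_duplication_nodes_annotated(self, rng):
        sp = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0, rng)
        b = 2.0 / sp.total_length()
        found = 0
        for _ in range(50):
            loc = sim.sim_locus_tree(sp, b, 0.0, rng)
            for n in loc.iter_nodes():
                if n.event == "dup":
                    found += 1
                    assert len(n.children) == 2
                    assert n.species is not None
        assert found > 0

    def test_poisson_expectation_small_rate(self, rng):
        """With no loss and a small birth rate the mean duplication count
        approaches birth x species-tree length (branching corrections are
        second order)."""
        sp = sim.sim_species_tree(6, "coalescent", 5000.0, 2000.0, rng)
        b = 0.4 / sp.total_length()
        counts = [sum(1 for n in sim.sim_locus_tree(sp, b, 0.0, rng
                                                    ).iter_nodes()
                      if n.event == "dup") for _ in range(2500)]
        assert np.mean(counts) == pytest.approx(0.4, abs=0.1)


class TestGeneTree:
    def test_leaf_count_and_binarity(self, rng):
        sp = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0, rng)
        loc = sim.sim_locus_tree(sp, 0.0, 0.0, rng)
        g = sim.sim_gene_tree(loc, 1000.0, 3, rng)
        assert len(g.leaves()) == 15
        for n in g.iter_nodes():
            assert len(n.children) in (0, 2)
            if n is not g:
                assert n.length >= 0

    def test_single_leaf_case(self, rng):
        leaf = sim.SimNode("s01_L1")
        leaf.age = 0.0
        g = sim.sim_gene_tree(leaf, 100.0, 1, rng)
        assert len(g.leaves()) == 1

    @pytest.mark.parametrize("t_coal,n_draws", [(0.0, 12000), (1.0, 12000)])
    def test_three_taxon_discordance_closed_form(self, t_coal, n_draws):
        """Rooted gene-tree discordance equals (2/3) exp(-t) for an
        internal branch of t coalescent units."""
        ne = 1000.0
        root = _species_tree_3taxa(t_coal, ne)
        rng = np.random.default_rng(77)
        conc = top.canon_rooted(((0, 1), 2))
        disc = 0
        for _ in range(n_draws):
            loc = sim.sim_locus_tree(root, 0.0, 0.0, rng)
            g = sim.sim_gene_tree(loc, ne, 1, rng)
            labs = sorted(l.label for l in g.leaves())
            idx = {lab: i for i, lab in enumerate(labs)}
            disc += sim.to_struct(g, idx) != conc
        expected = 2 / 3 * np.exp(-t_coal)
        se = np.sqrt(expected * (1 - expected) / n_draws)
        assert abs(disc / n_draws - expected) < 4 * se

    def test_long_branch_no_discordance(self):
        ne = 1000.0
        root = _species_tree_3taxa(30.0, ne)
        rng = np.random.default_rng(3)
        conc = top.canon_rooted(((0, 1), 2))
        for _ in range(200):
            loc = sim.sim_locus_tree(root, 0.0, 0.0, rng)
            g = sim.sim_gene_tree(loc, ne, 1, rng)
            labs = sorted(l.label for l in g.leaves())
            idx = {lab: i for i, lab in enumerate(labs)}
            assert sim.to_struct(g, idx) == conc


def _species_tree_3taxa(t_coal, ne):
    A, B, C = (sim.SimNode(f"s{i:02d}") for i in (1, 2, 3))
    ab, root = sim.SimNode(), sim.SimNode()
    ab.add(A)
    ab.add(B)
    root.add(ab)
    root.add(C)
    ab.age = 5 * ne
    root.age = 5 * ne + t_coal * 2 * ne
    for x in (A, B, C):
        x.age = 0.0
    sim._set_lengths_from_ages(root)
    for n in root.iter_nodes():
        n.species = n
    return root


class TestRateHeterogeneity:
    def test_mean_one_preserves_expected_length(self, rng):
        sp = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0, rng)
        base = sp.total_length()
        totals = []
        for _ in range(400):
            import copy

            t = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0,
                                     np.random.default_rng(1))
            sim.apply_rate_heterogeneity(t, 1.0, rng, 1.0)
            totals.append(t.total_length())
        ref = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0,
                                   np.random.default_rng(1)).total_length()
        assert np.mean(totals) == pytest.approx(ref, rel=0.1)

    def test_large_shape_stays_clocklike(self, rng):
        sp = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0, rng)
        sim.apply_rate_heterogeneity(sp, 1e8, rng, 1.0)
        d = tip_depths(sp)
        assert np.ptp(d) / np.mean(d) < 1e-3

    def test_rejects_bad_shape(self, rng):
        sp = sim.sim_species_tree(5, "coalescent", 3000.0, 1000.0, rng)
        with pytest.raises(ValueError):
            sim.apply_rate_heterogeneity(sp, 0.0, rng)


class TestReplicate:
    def test_scaled_down_conditions(self, rng):
        params = sim.scaled_down_params()
        rep = sim.sim_replicate(params, rng)
        assert 8 <= len(rep.species_names) <= 15
        assert 5 <= len(rep.families) <= 10
        assert 1 <= rep.individuals <= 3
        lo, hi = params.coal_length_window
        assert lo - 1e-9 <= rep.params["coal_length"] <= hi + 1e-9
        for fam in rep.families:
            assert len(fam.leaf_labels) >= 4
            for lab in fam.leaf_labels:
                assert fam.leaf_species[lab] in rep.species_names

    def test_provenance_reproducible(self):
        params = sim.scaled_down_params()
        r1 = sim.sim_replicate(params, np.random.default_rng(5))
        r2 = sim.sim_replicate(params, np.random.default_rng(5))
        assert r1.params == r2.params
        assert r1.species_tree.newick() == r2.species_tree.newick()

    def test_no_duplication_means_single_copy(self, rng):
        params = sim.SimParams(n_species_range=(6, 6),
                               n_families_range=(3, 3),
                               individuals_range=(1, 1),
                               edup_range=(1e-9, 2e-9))
        rep = sim.sim_replicate(params, rng)
        for fam in rep.families:
            species = [fam.leaf_species[l] for l in fam.leaf_labels]
            assert len(species) == len(set(species))

    def test_write_replicate(self, tmp_path, rng):
        rep = sim.sim_replicate(sim.scaled_down_params(), rng)
        sim.write_replicate(rep, tmp_path)
        assert (tmp_path / "species.nwk").exists()
        assert (tmp_path / "species.txt").exists()
        assert (tmp_path / "params.json").exists()
        fams = list(tmp_path.glob("genefam_*.nwk"))
        assert len(fams) == len(rep.families)
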