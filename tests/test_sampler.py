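"""Sampler correctness on enumerable instances, proposals, annealing and
posterior summaries.  The heavyweight exactness runs live in
test_acceptance; these are fast versions of the same checks."""

import numpy as np
import pytest
from collections import Counter

from bayesupertree import _topology as top
from bayesupertree import model as mdl
from bayesupertree import recdist as rd
from bayesupertree import sampler as smp


def make_inputs(n_sp, supports_weights):
    fams = [smp.FamilyInput(list(range(n_sp)), tuple(sup), np.asarray(w))
            for sup, w in supports_weights]
    return smp.AnalysisInputs([f"s{i}" for i in range(n_sp)], fams)


class TestProposals:
    def test_nni_proposal_valid(self, rng):
        s = top.random_rooted(range(5), rng)
        for _ in range(20):
            y, lh = smp.propose_species_tree(s, rng, "nni")
            assert lh == 0.0
            assert top.leaves_of(y) == tuple(range(5))

    def test_reroot_preserves_unrooted_topology(self, rng):
        s = top.random_rooted(range(6), rng)
        for _ in range(10):
            y, _ = smp.propose_species_tree(s, rng, "reroot")
            assert top.unroot(y) == top.unroot(s)
            assert y != s

    def test_spr_hastings_ratio_consistent(self, rng):
        s = top.random_rooted(range(5), rng)
        y, lh = smp.propose_species_tree(s, rng, "spr")
        expected = (np.log(len(top.spr_moves(s)))
                    - np.log(len(top.spr_moves(y))))
        assert lh == pytest.approx(expected)

    def test_three_species_nni_reaches_other_resolutions(self, rng):
        s = top.canon_rooted(((0, 1), 2))
        seen = {smp.propose_species_tree(s, rng, "nni")[0]
                for _ in range(100)}
        assert seen == {top.canon_rooted(((0, 2), 1)),
                        top.canon_rooted(((1, 2), 0))}


class TestUniformTarget:
    def test_huge_lambda_gives_uniform_species_posterior(self, rng):
        """With penalties so weak the distance term vanishes the species
        posterior is uniform over the 15 rooted 4-taxon trees."""
        sup = [top.random_unrooted(range(4), rng)]
        inputs = make_inputs(4, [(sup, [1.0])])
        cfg = smp.SamplerConfig(iterations=15000, burn_in=0.2, thin=1,
                                seed=5, fix_lambda=1e9,
                                scale_constants=False, model="DLI")
        res = smp.run_chain(inputs, cfg)
        c = Counter(s.species for s in res.samples)
        freqs = np.array([c.get(t, 0) for t in top.enumerate_rooted(range(4))]
                         ) / len(res.samples)
        assert (freqs > 0).all()
        assert np.abs(freqs - 1 / 15).max() < 0.04


class TestExactPosterior:
    def test_joint_matches_enumeration(self, rng, make_support):
        """Sampled species-tree AND gene-tree marginals match the exact
        enumerated posterior on a 4-species instance with fixed lambda."""
        sup, w = make_support(rng, 3)
        lam = 3.0
        inputs = make_inputs(4, [(sup, w)])
        cfg = smp.SamplerConfig(iterations=40000, burn_in=0.25, thin=1,
                                seed=11, fix_lambda=lam,
                                scale_constants=False, model="DLI")
        res = smp.run_chain(inputs, cfg)
        post = {}
        for S in top.enumerate_rooted(range(4)):
            for i, (t, g) in enumerate(zip(sup, w)):
                dv = rd.distance_vector(t, S, [0, 1, 2, 3], "DLI")
                post[(S, i)] = g * np.exp(-sum(dv.as_tuple("DLI")) / lam)
        tot = sum(post.values())
        exS, exG = {}, {}
        for (S, i), v in post.items():
            exS[S] = exS.get(S, 0) + v / tot
            exG[i] = exG.get(i, 0) + v / tot
        n = len(res.samples)
        cS = Counter(s.species for s in res.samples)
        cG = Counter(s.gene_idx[0] for s in res.samples)
        for S, p in exS.items():
            assert abs(p - cS.get(S, 0) / n) < 0.02
        for i, p in exG.items():
            assert abs(p - cG.get(i, 0) / n) < 0.02

    def test_resampling_upweights_congruent_topology(self, rng):
        """Conditional on the species tree, a congruent topology is
        resampled above its input weight (monotone reweighting)."""
        s_true = top.canon_rooted(((0, 1), (2, 3)))
        good = top.unroot(s_true)
        bad = top.unroot(top.canon_rooted(((0, 2), (1, 3))))
        inputs = make_inputs(4, [([good, bad], [0.3, 0.7])])
        cfg = smp.SamplerConfig(iterations=1, seed=3, fix_lambda=0.8,
                                scale_constants=False, model="DLI",
                                init_species=s_true)
        eng = smp.ChainEngine(inputs, cfg)
        eng.state.species = s_true
        eng.state.distances = [eng._dist(s_true, 0, eng.state.gene_idx[0])]
        hits = 0
        n = 4000
        for _ in range(n):
            smp.resample_gene_tree(eng, 0)
            hits += eng.state.gene_idx[0] == 0
        assert hits / n > 0.3

    def test_point_mass_input_never_moves(self, rng):
        sup = [top.random_unrooted(range(4), rng)]
        inputs = make_inputs(4, [(sup, [1.0])])
        cfg = smp.SamplerConfig(iterations=500, seed=1, fix_lambda=1.0,
                                scale_constants=False, model="DLI")
        res = smp.run_chain(inputs, cfg)
        assert all(s.gene_idx == (0,) for s in res.samples)


class TestDeterminism:
    def test_same_seed_same_samples(self, rng, make_support):
        sup, w = make_support(rng, 2)
        inputs = make_inputs(4, [(sup, w)])
        cfg = smp.SamplerConfig(iterations=800, seed=42, model="DLIR")
        r1 = smp.run_chain(inputs, cfg)
        r2 = smp.run_chain(inputs, cfg)
        assert [s.species for s in r1.samples] == [s.species
                                                   for s in r2.samples]
        assert all(np.array_equal(a.lam, b.lam)
                   for a, b in zip(r1.samples, r2.samples))


class TestAnnealing:
    def test_congruent_families_recover_truth(self, rng):
        s_true = top.random_rooted(range(4), rng)
        g = top.unroot(s_true)
        inputs = make_inputs(4, [([g], [1.0]), ([g], [1.0])])
        cfg = smp.SamplerConfig(iterations=1500, seed=2, model="DL",
                                fix_lambda=1.0, scale_constants=False)
        s_ml, gidx, lam, lj = smp.anneal(inputs, cfg)
        assert top.unroot(s_ml) == g
        d = rd.distance_vector(g, s_ml, [0, 1, 2, 3], "DLI")
        assert d.dups + d.losses == 0

    def test_never_worse_than_best_visited(self, rng, make_support):
        """The returned state attains the best (unheated) score seen."""
        sup, w = make_support(rng, 2, n_leaves=5)
        inputs = make_inputs(5, [(sup, w), (sup, w)])
        cfg = smp.SamplerConfig(iterations=1200, seed=9, model="ILS",
                                fix_lambda=1.0, scale_constants=False)
        s_ml, gidx, lam, best_lj = smp.anneal(inputs, cfg)
        # recompute the returned state's score; must equal the reported best
        eng = smp.ChainEngine(inputs, cfg)
        eng.state.species = s_ml
        eng.state.gene_idx = list(gidx)
        eng.state.distances = [eng._dist(s_ml, i, gidx[i])
                               for i in range(eng.N)]
        assert eng.log_joint() == pytest.approx(best_lj)


class TestSummaries:
    def _samples(self, specs):
        out = []
        for i, (struct, lp) in enumerate(specs):
            out.append(smp.PosteriorSample(i, struct, (0,), np.ones((1, 1)),
                                           np.ones(1), lp))
        return out

    def test_single_topology(self):
        t = top.canon_rooted(((0, 1), (2, 3)))
        summ = smp.summarize(self._samples([(t, -1.0)] * 10))
        assert summ.map_tree == t
        assert summ.credible_set == [(t, 1.0)]
        assert set(summ.consensus.splits) == set(
            top.unrooted_splits(t))

    def test_credible_set_cumulative(self):
        a = top.canon_rooted(((0, 1), (2, 3)))
        b = top.canon_rooted(((0, 2), (1, 3)))
        c = top.canon_rooted(((0, 3), (1, 2)))
        samples = self._samples([(a, -1)] * 60 + [(b, -1)] * 30
                                + [(c, -1)] * 10)
        summ = smp.summarize(samples)
        assert [t for t, _ in summ.credible_set] == [a, b, c][:len(
            summ.credible_set)]
        assert sum(f for _, f in summ.credible_set) >= 0.95

    def test_tied_frequency_resolved_by_log_posterior(self):
        a = top.canon_rooted(((0, 1), (2, 3)))
        b = top.canon_rooted(((0, 2), (1, 3)))
        samples = self._samples([(a, -5.0)] * 5 + [(b, -1.0)] * 5)
        assert smp.summarize(samples).map_tree == b

    def test_conflicting_halves_star_consensus(self):
        a = top.canon_rooted(((0, 1), (2, 3)))
        b = top.canon_rooted(((0, 2), (1, 3)))
        summ = smp.summarize(self._samples([(a, -1)] * 5 + [(b, -1)] * 5))
        assert len(summ.consensus.splits) == 0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            smp.summarize([])


class TestEntropy:
    def test_distribution_entropy(self):
        assert smp.distribution_entropy([1.0]) == 0.0
        assert smp.distribution_entropy([0.5, 0.5]) == pytest.approx(
            np.log(2))
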