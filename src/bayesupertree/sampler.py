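"""Posterior sampling and ML search over species-tree space.

The sampler sweeps four update blocks per iteration — species tree, each
family's gene topology, each family's penalty vector, and the shared scale
vector — using Generalized Multiple-try Metropolis (GMTM): draw k candidates
from a proposal kernel, select one with probability proportional to a weight
function, build the k-candidate reverse shadow set (with the current state
substituted at the selected index) and accept with the weighted ratio.

Gene-tree updates use the input resampling weights as an independence
proposal, so the (externally computed) phylogenetic likelihood cancels and
only the distance-penalty terms enter the acceptance probability.

When exchange mode is on, species-tree and penalty updates append an
auxiliary-variable correction: auxiliary gene trees are drawn from the
distance model at the proposed state by a secondary MCMC over full topology
space, and their unscaled densities cancel the intractable partition
functions in the acceptance ratio.

Simulated annealing reuses the same machinery on the tempered target
P(S, Theta | D)^(1/kT) with a geometrically decreasing temperature; with a
single reconciliation cost, fixed penalties and point-mass gene-tree inputs
this reduces to gene-tree parsimony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from . import _topology as top
from . import model as mdl
from . import recdist
from . import treeio


# ---------------------------------------------------------------------------
# configuration and containers


@dataclass
class SamplerConfig:
    iterations: int = 20000
    burn_in: float = 0.5
    thin: int = 0  # 0 = auto, keep ~1000 samples
    k_tries: int = 4
    seed: int = 0
    move_weights: tuple = (0.7, 0.0, 0.3)  # NNI, SPR, reroot
    exchange: bool = False
    aux_len: int = 100
    model: str = "DLIR"
    # Mean of the fixed exponential hyper-hyperprior on lambda0.  With the
    # partition function neglected, the distance likelihood alone always
    # prefers permissive penalties; the joint mode sits near
    # lambda_ij ~ sqrt(delta_ij * lambda0_j) (delta = standardized distance),
    # so the single fixed prior factor on lambda0 must be strong enough to
    # hold the penalties at the scale of between-tree distance differences
    # (~0.1 after standardization to [0, 1]) against N*J likelihood factors.
    # The default 1e-5 places the equilibrium penalties at the few-percent
    # scale of the spread of standardized distances between candidate
    # species trees, where the posterior concentrates and the single-cost
    # parameterizations behave like (softened) gene tree parsimony; with a
    # mean near 1 the hierarchy turns uninformative and the species-tree
    # posterior flattens toward uniform.
    hyper_mean: float = 1e-5
    fix_lambda: object = None  # scalar or (N,J) array; disables lambda updates
    n_reference_trees: int = 10
    scale_constants: bool = True
    lam_step: float = 0.4
    anneal_start: float = 1.0
    anneal_end: float = 1e-3
    init_species: tuple | None = None

    def __post_init__(self):
        if self.k_tries < 2:
            raise ValueError("k_tries must be >= 2")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn_in must be in [0, 1)")
        if self.anneal_end >= self.anneal_start:
            raise ValueError("annealing must cool down")
        if self.model not in mdl.MODELS:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class PosteriorSample:
    iteration: int
    species: tuple
    gene_idx: tuple
    lam: np.ndarray
    lam0: np.ndarray
    log_post: float


@dataclass
class ChainResult:
    samples: list
    n_species: int
    species_names: list
    acceptance: dict
    config: SamplerConfig
    families: list  # AnalysisInputs.families


@dataclass
class FamilyInput:
    """One gene family prepared for sampling: species ids per leaf plus the
    weighted topology support."""

    leaf_species: list  # leaf index -> species id
    support: tuple  # canonical unrooted structs
    weights: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.weights = self.weights / self.weights.sum()
        self.cumw = np.cumsum(self.weights)


@dataclass
class AnalysisInputs:
    species_names: list
    families: list  # of FamilyInput

    @property
    def n_species(self):
        return len(self.species_names)


def inputs_from_distributions(species_names, dists) -> AnalysisInputs:
    """Build sampler inputs from (GeneFamily, GeneTreeDistribution) data."""
    sp_index = {s: i for i, s in enumerate(species_names)}
    fams = []
    for dist in dists:
        fam = dist.family
        ls = [sp_index[fam.leaf_species[lab]] for lab in fam.leaf_labels]
        fams.append(FamilyInput(ls, tuple(dist.topologies),
                                np.asarray(dist.weights, float),
                                tuple(fam.leaf_labels)))
    return AnalysisInputs(list(species_names), fams)


# ---------------------------------------------------------------------------
# species-tree proposal kernel


@lru_cache(maxsize=8192)
def _nni_moves_cached(struct):
    return tuple(top.rooted_nni_moves(struct))


@lru_cache(maxsize=8192)
def _reroot_moves_cached(struct):
    return tuple(top.reroot_moves(struct))


@lru_cache(maxsize=2048)
def _spr_moves_cached(struct):
    return tuple(top.spr_moves(struct))


MOVE_TYPES = ("nni", "spr", "reroot")


def propose_species_tree(struct, rng, move_type: str):
    """One proposal of the requested type.

    Returns (new struct, log Hastings ratio log[p(x|y)/p(y|x)]).  The NNI
    kernel (uniform over the fixed-size raw swap list) and the rerooting
    kernel (uniform over the other rootings of the same unrooted topology)
    are symmetric; SPR uses the neighborhood-size ratio.
    """
    if move_type == "nni":
        moves = _nni_moves_cached(struct)
        return moves[int(rng.integers(len(moves)))], 0.0
    if move_type == "reroot":
        moves = _reroot_moves_cached(struct)
        if not moves:
            return struct, 0.0
        return moves[int(rng.integers(len(moves)))], 0.0
    if move_type == "spr":
        moves = _spr_moves_cached(struct)
        y = moves[int(rng.integers(len(moves)))]
        return y, math.log(len(moves)) - math.log(len(_spr_moves_cached(y)))
    raise ValueError(f"unknown move type {move_type!r}")


# ---------------------------------------------------------------------------
# the engine


class ChainEngine:
    """Mutable sweep engine; exposed for fine-grained control in tests and
    for single-block updates such as gene-tree resampling."""

    def __init__(self, inputs: AnalysisInputs, config: SamplerConfig):
        self.inputs = inputs
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.n_species = inputs.n_species
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        self.J = mdl.model_dim(config.model)
        self.N = len(inputs.families)
        base = "DLIR" if config.model == "DLIR" else "DLI"
        self.base_model = base
        self.scorer = recdist.ReconScorer(
            [f.leaf_species for f in inputs.families],
            [f.support for f in inputs.families],
            base,
        )
        self.m = self._scaling_matrix()
        self.accept = {"species": [0, 0], "gene": [0, 0],
                       "lambda": [0, 0], "lambda0": [0, 0]}
        self.state = self._init_state()
        self.beta = 1.0  # inverse temperature (1/kT)

    # -- setup -------------------------------------------------------------

    def _scaling_matrix(self):
        cfg = self.cfg
        if not cfg.scale_constants:
            return np.ones((self.N, self.J))
        refs = [top.random_rooted(range(self.n_species), self.rng)
                for _ in range(cfg.n_reference_trees)]
        m = np.ones((self.N, self.J))
        for i, fam in enumerate(self.inputs.families):
            g0 = self.scorer.gidx[i][0]
            raw = recdist.scaling_constants(g0, self.scorer.gidx[i], refs,
                                            self.base_model)
            # raw = (m_dup, m_loss, m_ils[, m_mulrf]); collapse per model
            per_comp = []
            for comp in mdl.MODEL_COMPONENTS[self.cfg.model]:
                per_comp.append(float(sum(raw[k] for k in comp)))
            m[i] = per_comp
        return m

    def _init_state(self):
        cfg = self.cfg
        s0 = cfg.init_species or top.random_rooted(range(self.n_species),
                                                   self.rng)
        s0 = top.canon_rooted(s0)
        gene_idx = [int(np.searchsorted(f.cumw, self.rng.random()))
                    for f in self.inputs.families]
        if cfg.fix_lambda is not None:
            lam = np.broadcast_to(np.asarray(cfg.fix_lambda, float),
                                  (self.N, self.J)).copy()
            lam0 = np.ones(self.J)
        else:
            lam = np.full((self.N, self.J), cfg.hyper_mean)
            lam0 = np.full(self.J, cfg.hyper_mean)
        pen = mdl.PenaltyState(lam, lam0, self.m, cfg.hyper_mean)
        dists = [self._dist(s0, i, gene_idx[i]) for i in range(self.N)]
        self._inv = [tuple(1.0 / (self.m[i, j] * lam[i, j])
                           for j in range(self.J)) for i in range(self.N)]
        return mdl.ChainState(s0, gene_idx, pen, dists)

    # -- target pieces -----------------------------------------------------

    def _dist(self, s_struct, fam, topo_idx):
        dv = self.scorer.distances(s_struct, fam, topo_idx)
        if self.cfg.model == self.base_model:  # DLI / DLIR: identity
            return dv
        return mdl.project_distances(dv, self.cfg.model)

    def _phi(self, d, i):
        """log f_i for family i with current penalties."""
        out = 0.0
        for dj, ij in zip(d, self._inv[i]):
            out -= dj * ij
        return out

    def _phi_all(self, s_struct, gene_idx):
        out = 0.0
        for i in range(self.N):
            d = self._dist(s_struct, i, gene_idx[i])
            for dj, ij in zip(d, self._inv[i]):
                out -= dj * ij
        return out

    def log_joint(self):
        return mdl.log_joint(self.state, self.n_species)

    # -- GMTM select helper --------------------------------------------------

    def _gmtm_select(self, logw):
        """(index, log of normalized weight) for candidate selection."""
        mx = max(logw)
        if not math.isfinite(mx):
            return None, None
        w = [math.exp(v - mx) for v in logw]
        tot = sum(w)
        u = self.rng.random() * tot
        acc = 0.0
        j = len(w) - 1
        for idx, wi in enumerate(w):
            acc += wi
            if u < acc:
                j = idx
                break
        return j, float(logw[j]) - mx - math.log(tot)

    def _gmtm_logW_of(self, logw, idx):
        mx = max(logw)
        tot = sum(math.exp(v - mx) for v in logw)
        return float(logw[idx]) - mx - math.log(tot)

    # -- update blocks -------------------------------------------------------

    def update_species(self):
        cfg, st, rng = self.cfg, self.state, self.rng
        k = cfg.k_tries
        mt = MOVE_TYPES[int(np.searchsorted(np.cumsum(cfg.move_weights),
                                            rng.random() * sum(cfg.move_weights)))]
        cur_phi = sum(self._phi(d, i) for i, d in enumerate(st.distances))
        cands = []
        logh = []
        logw = []
        for _ in range(k):
            y, lh = propose_species_tree(st.species, rng, mt)
            cands.append(y)
            logh.append(lh)
            logw.append(self.beta * self._phi_all(y, st.gene_idx))
        j, logWy = self._gmtm_select(logw)
        self.accept["species"][1] += 1
        if j is None:
            return
        y = cands[j]
        if y == st.species:
            return
        # reverse shadows from y, slot j replaced by current state
        rev_logw = []
        for i in range(k):
            if i == j:
                rev_logw.append(self.beta * cur_phi)
            else:
                x_star, _ = propose_species_tree(y, rng, mt)
                rev_logw.append(self.beta * self._phi_all(x_star, st.gene_idx))
        logWx = self._gmtm_logW_of(rev_logw, j)
        log_acc = (logw[j] - self.beta * cur_phi + logh[j] + logWx - logWy)
        if cfg.exchange:
            log_acc += self._exchange_correction(st.species, y,
                                                 st.penalties.lam,
                                                 st.penalties.lam)
        if math.log(rng.random() + 1e-300) < log_acc:
            st.species = y
            st.distances = [self._dist(y, i, st.gene_idx[i])
                            for i in range(self.N)]
            self.accept["species"][0] += 1

    def update_gene(self, i):
        """Importance-resampling GMTM update of family i's topology.

        Candidates come from the input weights (independence proposal), so
        the phylogenetic-likelihood factor cancels and the weight function
        is the unscaled distance density.
        """
        cfg, st, rng = self.cfg, self.state, self.rng
        fam = self.inputs.families[i]
        n = len(fam.support)
        self.accept["gene"][1] += 1
        if n == 1:
            return
        k = cfg.k_tries
        u = rng.random(2 * k - 1)
        draws = np.searchsorted(fam.cumw, u)
        cand_idx = draws[:k]
        logw = [self.beta * self._phi(self._dist(st.species, i, int(c)), i)
                for c in cand_idx]
        j, logWy = self._gmtm_select(logw)
        if j is None:
            return
        y = int(cand_idx[j])
        cur = st.gene_idx[i]
        cur_phi = self.beta * self._phi(st.distances[i], i)
        rev_logw = []
        rpos = 0
        for t in range(k):
            if t == j:
                rev_logw.append(cur_phi)
            else:
                c = int(draws[k + rpos])
                rpos += 1
                rev_logw.append(
                    self.beta * self._phi(self._dist(st.species, i, c), i))
        logWx = self._gmtm_logW_of(rev_logw, j)
        log_acc = logw[j] - cur_phi + logWx - logWy
        if y == cur:
            return
        if math.log(rng.random() + 1e-300) < log_acc:
            st.gene_idx[i] = y
            st.distances[i] = self._dist(st.species, i, y)
            self.accept["gene"][0] += 1

    def update_lambda(self, i):
        """GMTM block update of family i's penalty vector (all J components
        jointly, multiplicative lognormal steps)."""
        cfg, st, rng = self.cfg, self.state, self.rng
        k = cfg.k_tries
        pen = st.penalties
        x = pen.lam[i]
        d = np.array(st.distances[i], float) / self.m[i]
        self.accept["lambda"][1] += 1

        def logtarget_rows(v):
            # -sum_j d_j/(m_j v_j) + sum_j [-v_j/lam0_j - log lam0_j]
            return self.beta * (-(d / v).sum(axis=1)
                                - (v / pen.lam0).sum(axis=1)
                                - np.log(pen.lam0).sum())

        cands = x[None, :] * np.exp(rng.normal(0.0, cfg.lam_step,
                                               size=(k, self.J)))
        logw = logtarget_rows(cands)
        j, logWy = self._gmtm_select(logw)
        if j is None:
            return
        y = cands[j]
        rev = y[None, :] * np.exp(rng.normal(0.0, cfg.lam_step,
                                             size=(k - 1, self.J)))
        cur_lt = float(logtarget_rows(x[None, :])[0])
        rev_logw = np.empty(k)
        rev_logw[j] = cur_lt
        mask = np.arange(k) != j
        rev_logw[mask] = logtarget_rows(rev)
        logWx = self._gmtm_logW_of(rev_logw, j)
        # multiplicative lognormal kernel: q(x|y)/q(y|x) = prod y_j / x_j
        logh = float(np.log(y).sum() - np.log(x).sum())
        log_acc = float(logw[j]) - cur_lt + logh + logWx - logWy
        if cfg.exchange:
            lam_star = pen.lam.copy()
            lam_star[i] = y
            log_acc += self._exchange_correction(st.species, st.species,
                                                 pen.lam, lam_star)
        if math.log(rng.random() + 1e-300) < log_acc:
            pen.lam[i] = y
            self._inv[i] = tuple(1.0 / (self.m[i, j2] * y[j2])
                                 for j2 in range(self.J))
            self.accept["lambda"][0] += 1

    def update_lambda0(self):
        """GMTM update of the shared scale vector lambda0 (weight function =
        unnormalized posterior, as in the plain algorithm)."""
        cfg, st, rng = self.cfg, self.state, self.rng
        k = cfg.k_tries
        pen = st.penalties
        x = pen.lam0
        lam_sum = pen.lam.sum(axis=0)  # (J,)
        self.accept["lambda0"][1] += 1

        def logtarget_rows(v):
            # sum_j [ -v_j/hyper_mean - S_j/v_j - N log v_j ] + const
            return self.beta * (-(v / cfg.hyper_mean).sum(axis=1)
                                - (lam_sum / v).sum(axis=1)
                                - self.N * np.log(v).sum(axis=1))

        cands = x[None, :] * np.exp(rng.normal(0.0, cfg.lam_step,
                                               size=(k, self.J)))
        logw = logtarget_rows(cands)
        j, logWy = self._gmtm_select(logw)
        if j is None:
            return
        y = cands[j]
        rev = y[None, :] * np.exp(rng.normal(0.0, cfg.lam_step,
                                             size=(k - 1, self.J)))
        cur_lt = float(logtarget_rows(x[None, :])[0])
        rev_logw = np.empty(k)
        rev_logw[j] = cur_lt
        rev_logw[np.arange(k) != j] = logtarget_rows(rev)
        logWx = self._gmtm_logW_of(rev_logw, j)
        logh = float(np.log(y).sum() - np.log(x).sum())
        log_acc = float(logw[j]) - cur_lt + logh + logWx - logWy
        if math.log(rng.random() + 1e-300) < log_acc:
            pen.lam0 = y
            self.accept["lambda0"][0] += 1

    # -- exchange ------------------------------------------------------------

    def _exchange_correction(self, s_x, s_y, lam_x, lam_y):
        """log f(A | lam_x, s_x) - log f(A | lam_y, s_y) with auxiliary gene
        trees A drawn from the distance model at the proposed state by a
        secondary NNI chain started at the current gene trees."""
        st = self.state
        out = 0.0
        for i in range(self.N):
            fam = self.inputs.families[i]
            a_struct = self._aux_sample(i, s_y, lam_y[i],
                                        fam.support[st.gene_idx[i]])
            dx = self._dist_struct(s_x, i, a_struct)
            dy = self._dist_struct(s_y, i, a_struct)
            out += self.beta * (
                -sum(dj / (mj * lj) for dj, lj, mj in zip(dx, lam_x[i], self.m[i]))
                + sum(dj / (mj * lj) for dj, lj, mj in zip(dy, lam_y[i], self.m[i]))
            )
        return out

    def _dist_struct(self, s_struct, fam, gene_struct):
        """Distance tuple for an arbitrary gene topology (exchange mode)."""
        key = (s_struct, fam, gene_struct)
        cache = self.scorer._dv_cache
        dv = cache.get(key)
        if dv is None:
            sidx, ext, _ = self.scorer._family_species_ctx(s_struct, fam)
            g = recdist.GeneTopologyIndex(
                gene_struct, self.inputs.families[fam].leaf_species)
            d1, d2, d3, _, _ = recdist.min_over_roots(g, sidx)
            if self.base_model == "DLIR":
                dv = (d1, d2, d3, recdist.mulrf_from_counters(g.split_counter,
                                                              ext))
            else:
                dv = (d1, d2, d3)
            cache[key] = dv
        return mdl.project_distances(dv, self.cfg.model)

    def _aux_sample(self, i, s_struct, lam_i, start_struct):
        """MH chain over full unrooted topology space targeting the unscaled
        distance density at (s_struct, lam_i); within this chain the
        partition function cancels."""
        rng = self.rng
        cur = start_struct
        cur_d = self._dist_struct(s_struct, i, cur)
        cur_phi = -sum(dj / (mj * lj)
                       for dj, lj, mj in zip(cur_d, lam_i, self.m[i]))
        for _ in range(self.cfg.aux_len):
            nbrs = top.unrooted_nni_neighbors(cur)
            if not nbrs:
                break
            y = nbrs[int(rng.integers(len(nbrs)))]
            y_d = self._dist_struct(s_struct, i, y)
            y_phi = -sum(dj / (mj * lj)
                         for dj, lj, mj in zip(y_d, lam_i, self.m[i]))
            # account for differing neighborhood sizes
            logh = math.log(len(nbrs)) - math.log(len(top.unrooted_nni_neighbors(y)))
            if math.log(rng.random() + 1e-300) < self.beta * (y_phi - cur_phi) + logh:
                cur, cur_phi = y, y_phi
        return cur

    # -- sweeps --------------------------------------------------------------

    def sweep(self):
        self.update_species()
        for i in range(self.N):
            self.update_gene(i)
        if self.cfg.fix_lambda is None:
            for i in range(self.N):
                self.update_lambda(i)
            self.update_lambda0()


# ---------------------------------------------------------------------------
# public entry points


def run_chain(inputs: AnalysisInputs, config: SamplerConfig) -> ChainResult:
    """Sample the posterior distribution of (S, G, lambda, lambda0)."""
    eng = ChainEngine(inputs, config)
    n_iter = config.iterations
    burn = int(n_iter * config.burn_in)
    thin = config.thin or max(1, (n_iter - burn) // 1000)
    samples = []
    for it in range(n_iter):
        eng.sweep()
        if it >= burn and (it - burn) % thin == 0:
            st = eng.state
            samples.append(PosteriorSample(
                it, st.species, tuple(st.gene_idx),
                st.penalties.lam.copy(), st.penalties.lam0.copy(),
                eng.log_joint()))
    return ChainResult(samples, eng.n_species, inputs.species_names,
                       eng.accept, config, inputs.families)


def anneal(inputs: AnalysisInputs, config: SamplerConfig):
    """Simulated-annealing point estimate (ML supertree under the chosen
    distances).  Returns (best species struct, best gene indices, best
    penalty matrix, best unheated log joint)."""
    eng = ChainEngine(inputs, config)
    n_iter = config.iterations
    # geometric cooling from anneal_start to anneal_end
    factor = (config.anneal_end / config.anneal_start) ** (1.0 / max(1, n_iter - 1))
    kt = config.anneal_start
    best = None
    for _ in range(n_iter):
        eng.beta = 1.0 / kt
        eng.sweep()
        lj = eng.log_joint()
        if best is None or lj > best[3]:
            st = eng.state
            best = (st.species, tuple(st.gene_idx), st.penalties.lam.copy(), lj)
        kt *= factor
    return best


def resample_gene_tree(engine: ChainEngine, i: int):
    """One importance-resampling GMTM update of family i's gene topology
    (candidates from the input weights; likelihood terms cancel).  Mutates
    and returns the engine's state."""
    engine.update_gene(i)
    return engine.state


# ---------------------------------------------------------------------------
# posterior summaries


@dataclass
class PosteriorSummary:
    map_tree: tuple
    map_frequency: float
    consensus: treeio.ConsensusTree
    credible_set: list  # [(struct, freq)] smallest set with cum freq >= level
    credible_level: float
    split_support: dict  # unrooted split -> posterior frequency
    topology_freqs: dict  # rooted struct -> frequency


def summarize(samples: Sequence[PosteriorSample],
              credible_level: float = 0.95,
              consensus_threshold: float = 0.5) -> PosteriorSummary:
    """MAP tree, majority-rule consensus, credible set and split supports."""
    if not samples:
        raise ValueError("empty posterior sample")
    counts: dict = {}
    logp: dict = {}
    for s in samples:
        counts[s.species] = counts.get(s.species, 0) + 1
        logp.setdefault(s.species, []).append(s.log_post)
    n = len(samples)
    freqs = {t: c / n for t, c in counts.items()}
    # MAP = most frequent rooted topology; ties -> higher mean log posterior,
    # then canonical order for determinism
    order = sorted(freqs, key=lambda t: (-freqs[t],
                                         -float(np.mean(logp[t])),
                                         top.struct_key(t)))
    cred = []
    cum = 0.0
    for t in order:
        cred.append((t, freqs[t]))
        cum += freqs[t]
        if cum >= credible_level - 1e-12:
            break
    weighted = [(s.species, 1.0) for s in samples]
    _, split_freqs = treeio.weighted_split_frequencies(weighted)
    consensus = treeio.majority_consensus(weighted, consensus_threshold)
    return PosteriorSummary(order[0], freqs[order[0]], consensus, cred,
                            credible_level, split_freqs, freqs)


def gene_tree_posterior(result: ChainResult, i: int):
    """(indices, frequencies) of family i's sampled topologies."""
    counts: dict = {}
    for s in result.samples:
        counts[s.gene_idx[i]] = counts.get(s.gene_idx[i], 0) + 1
    n = len(result.samples)
    idx = sorted(counts)
    return idx, np.array([counts[t] / n for t in idx])


def distribution_entropy(weights) -> float:
    w = np.asarray(weights, float)
    w = w[w > 0]
    return float(-(w * np.log(w)).sum())


# ---------------------------------------------------------------------------
# trace output


def write_trace(result: ChainResult, path):
    """Tab-separated trace: iteration, log posterior, lambda0, per-family
    lambdas — loadable by generic MCMC trace inspectors."""
    J = result.samples[0].lam0.shape[0] if result.samples else 0
    N = result.samples[0].lam.shape[0] if result.samples else 0
    with open(path, "w") as fh:
        cols = ["iteration", "log_posterior"]
        cols += [f"lambda0_{j}" for j in range(J)]
        cols += [f"lambda_{i}_{j}" for i in range(N) for j in range(J)]
        fh.write("\t".join(cols) + "\n")
        for s in result.samples:
            row = [str(s.iteration), f"{s.log_post:.6f}"]
            row += [f"{v:.6g}" for v in s.lam0]
            row += [f"{v:.6g}" for v in s.lam.ravel()]
            fh.write("\t".join(row) + "\n")


def write_tree_samples(result: ChainResult, path):
    names = result.species_names
    with open(path, "w") as fh:
        for s in result.samples:
            fh.write(top.to_newick(s.species, names) + "\n")
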