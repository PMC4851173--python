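"""End-to-end evaluation harness for the simulation study.

Each replicate runs the full pipeline: three-tree simulation, nonparametric
gene-tree uncertainty, species-tree inference by every requested method,
and the three performance measures — split accuracy against the true
unrooted species tree, exact true-tree recovery, and (for the Bayesian
posterior) whether the true unrooted topology lies in the 95% credible set.

Methods:

* ``bayes_dlir`` / ``bayes_dli`` — the hierarchical Bayesian sampler;
  consensus and MAP point estimates are both recorded.
* ``gtp_dl`` / ``gtp_ils`` — simulated annealing under a single cost
  (duplications+losses, or deep coalescences), i.e. gene tree parsimony on
  the weighted input distributions.
* ``glass`` / ``sd`` / ``steac`` / ``mac`` with suffix ``_true`` (true gene
  trees, true branch lengths) or ``_topo`` (most frequent input topology,
  unit branch lengths).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _topology as top
from . import coalmatrix
from . import sampler as smp
from . import simulate as sim
from . import treeio
from . import uncertainty as unc

BAYES_METHODS = ("bayes_dlir", "bayes_dli")
GTP_METHODS = ("gtp_dl", "gtp_ils")
DM_METHODS = tuple(f"{m.lower()}_{src}" for m in coalmatrix.METHODS
                   for src in ("true", "topo"))
DEFAULT_METHODS = ("bayes_dlir", "gtp_dl", "gtp_ils") + DM_METHODS


@dataclass
class EvalRecord:
    replicate: int
    method: str
    estimator: str  # consensus / map / point
    accuracy: float
    recovered: bool
    coverage: object  # bool for Bayesian methods, None otherwise
    n_species: int
    n_families: int
    coal_length: float
    edup: float
    individuals: int
    min_branch_coal: float


@dataclass
class BenchmarkConfig:
    n_replicates: int = 20
    sim_params: sim.SimParams = field(default_factory=sim.scaled_down_params)
    methods: tuple = DEFAULT_METHODS
    chain_iterations: int = 20000
    gtp_iterations: int = 4000
    k_tries: int = 4
    uncertainty_draws: int = 1000
    seed: int = 0


# ---------------------------------------------------------------------------
# split helpers (everything compared on species-name splits, unrooted)


def _splits_of_struct(struct, names):
    return {frozenset(names[i] for i in s) for s in top.unrooted_splits(struct)}


def _splits_of_consensus(ct: treeio.ConsensusTree, names):
    return {frozenset(names[i] for i in s) for s in ct.splits}


def _splits_of_dendropy(tree):
    return {frozenset(s) for s in treeio.split_set(tree)}


def accuracy_from_splits(true_splits: set, est_splits: set) -> float:
    if not true_splits:
        raise ValueError("true tree has no nontrivial splits")
    return len(true_splits & est_splits) / len(true_splits)


# ---------------------------------------------------------------------------


def perturb_replicate(rep: sim.Replicate, rng, n_draws: int = 1000):
    """Apply the uncertainty generator to every family of a replicate;
    returns (list of GeneTreeDistribution, list of UncertaintyParams)."""
    dists = []
    all_params = []
    for i, fam in enumerate(rep.families):
        params = unc.sample_uncertainty_params(rng, n_draws=n_draws)
        dists.append(unc.perturb_distribution(fam.gene_tree, fam.leaf_species,
                                              params, rng, family_id=i))
        all_params.append(params)
    return dists, all_params


def evaluate_replicate(true_struct, names, estimates: dict,
                       replicate_id: int = 0, covariates: dict | None = None):
    """Score a dict of estimates against the true species tree.

    ``estimates``: method -> dict with keys ``splits`` (set of name
    frozensets), optional ``estimator`` and ``coverage``.
    """
    true_splits = _splits_of_struct(true_struct, names)
    cov = covariates or {}
    out = []
    for method in sorted(estimates):
        e = estimates[method]
        acc = accuracy_from_splits(true_splits, e["splits"])
        out.append(EvalRecord(
            replicate_id, method, e.get("estimator", "point"), acc,
            acc == 1.0, e.get("coverage"),
            cov.get("n_species", len(names)), cov.get("n_families", 0),
            cov.get("coal_length", float("nan")), cov.get("edup", float("nan")),
            cov.get("individuals", 0), cov.get("min_branch_coal", float("nan")),
        ))
    return out


def _min_internal_branch_coal(rep: sim.Replicate) -> float:
    vals = []
    for n in rep.species_tree.iter_nodes():
        if n.children and n is not rep.species_tree:
            vals.append(n.length / (2.0 * rep.ne))
    return min(vals) if vals else float("nan")


def run_replicate(rep: sim.Replicate, methods, rng, config: BenchmarkConfig,
                  replicate_id: int = 0):
    """All requested methods on one replicate; returns EvalRecords."""
    names = rep.species_names
    true_struct = rep.species_struct
    true_unrooted = top.unroot(true_struct)
    dists, _ = perturb_replicate(rep, rng, config.uncertainty_draws)
    inputs = smp.inputs_from_distributions(names, dists)
    estimates = {}

    for method in methods:
        seed = int(rng.integers(2 ** 31))
        try:
            if method in BAYES_METHODS:
                model = "DLIR" if method.endswith("dlir") else "DLI"
                cfg = smp.SamplerConfig(iterations=config.chain_iterations,
                                        seed=seed, model=model,
                                        k_tries=config.k_tries)
                res = smp.run_chain(inputs, cfg)
                summ = smp.summarize(res.samples)
                estimates[method + "_cons"] = {
                    "splits": _splits_of_consensus(summ.consensus, names),
                    "estimator": "consensus",
                    "coverage": _in_unrooted_credible(res.samples,
                                                      true_unrooted),
                }
                estimates[method + "_map"] = {
                    "splits": _splits_of_struct(summ.map_tree, names),
                    "estimator": "map",
                    "coverage": _in_unrooted_credible(res.samples,
                                                      true_unrooted),
                }
            elif method in GTP_METHODS:
                model = "DL" if method.endswith("dl") else "ILS"
                cfg = smp.SamplerConfig(iterations=config.gtp_iterations,
                                        seed=seed, model=model,
                                        fix_lambda=1.0, scale_constants=False,
                                        k_tries=config.k_tries)
                s_ml, _, _, _ = smp.anneal(inputs, cfg)
                estimates[method] = {
                    "splits": _splits_of_struct(s_ml, names)}
            else:
                base, src = method.rsplit("_", 1)
                if src == "true":
                    trees = [f.gene_tree for f in rep.families]
                    maps = [f.leaf_species for f in rep.families]
                    est = coalmatrix.run_method(trees, maps, base.upper(),
                                                "true")
                else:
                    trees, maps = [], []
                    for d in dists:
                        best = int(np.argmax(d.weights))
                        nwk = top.to_newick(d.topologies[best],
                                            d.family.leaf_labels)
                        trees.append(treeio.struct_to_dendropy(
                            d.topologies[best], d.family.leaf_labels))
                        maps.append(dict(d.family.leaf_species))
                    est = coalmatrix.run_method(trees, maps, base.upper(),
                                                "unit")
                estimates[method] = {"splits": _splits_of_dendropy(est)}
        except Exception as exc:  # record failures, keep the benchmark going
            estimates[method] = {"splits": set(), "estimator": f"failed:{exc}"}

    cov = {
        "n_species": len(names), "n_families": len(rep.families),
        "coal_length": rep.params["coal_length"], "edup": rep.params["edup"],
        "individuals": rep.individuals,
        "min_branch_coal": _min_internal_branch_coal(rep),
    }
    return evaluate_replicate(true_struct, names, estimates, replicate_id, cov)


def _in_unrooted_credible(samples, true_unrooted, level: float = 0.95) -> bool:
    counts: dict = {}
    for s in samples:
        u = top.unroot(s.species)
        counts[u] = counts.get(u, 0) + 1
    n = len(samples)
    order = sorted(counts, key=lambda t: (-counts[t],
                                          top.struct_key((t[0], (t[1], t[2])))))
    cum = 0.0
    for t in order:
        cum += counts[t] / n
        if t == true_unrooted:
            return True
        if cum >= level - 1e-12:
            return False
    return False


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """The scaled-down simulation study: simulate, perturb, infer, score.

    Per-replicate seeds are spawned from the master seed and logged in the
    output so single replicates can be re-run exactly.
    """
    master = np.random.default_rng(config.seed)
    rows = []
    for r in range(config.n_replicates):
        rep_seed = int(master.integers(2 ** 31))
        rng = np.random.default_rng(rep_seed)
        rep = sim.sim_replicate(config.sim_params, rng)
        t0 = time.time()
        recs = run_replicate(rep, config.methods, rng, config, replicate_id=r)
        for rec in recs:
            row = rec.__dict__.copy()
            row["replicate_seed"] = rep_seed
            row["wall_seconds"] = round(time.time() - t0, 2)
            rows.append(row)
    return pd.DataFrame(rows)


def median_accuracy(df: pd.DataFrame, method: str,
                    estimator: str | None = None) -> float:
    sel = df[df.method == method]
    if estimator is not None:
        sel = sel[sel.estimator == estimator]
    return float(sel.accuracy.median())
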