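"""The hierarchical probability model.

The species tree S is a hyperparameter with a uniform prior over all rooted
binary labeled topologies.  Given S, each gene family i draws its topology
G_i from a multivariate exponential penalty distribution

    P(G_i | S, lambda_i.) = exp(-sum_j d_j(G_i, S) / (m_ij lambda_ij)) / Z_i

where d_j are the disagreement measures (duplications, losses, deep
coalescences and, in the DLIR parameterization, mulRF), m_ij are fixed
scaling constants standardizing each distance to [0, 1], and Z_i is the
partition function over all topologies on the family's leaves.  Each penalty
lambda_ij has an exponential hyperprior with genome-wide mean lambda_0j,
itself exponential with a fixed mean.

All densities are composed in log space.  The partition function is
neglected by default (point estimates of S are insensitive to it); exchange
mode restores it, and a brute-force enumerator provides the exact value on
small families for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _topology as top
from . import recdist

MODELS = ("DLI", "DLIR", "DL", "ILS")
#: distance-vector component indices used by each parameterization;
#: DL merges duplications+losses into one cost (gene-tree-parsimony mode)
MODEL_COMPONENTS = {
    "DLI": ((0,), (1,), (2,)),
    "DLIR": ((0,), (1,), (2,), (3,)),
    "DL": ((0, 1),),
    "ILS": ((2,),),
}


def model_dim(model: str) -> int:
    return len(MODEL_COMPONENTS[model])


def project_distances(dv: tuple, model: str) -> tuple:
    """Collapse a (d1,d2,d3[,d4]) tuple onto the model's J components."""
    return tuple(sum(dv[k] for k in comp) for comp in MODEL_COMPONENTS[model])


@dataclass
class PenaltyState:
    """Penalty matrix lambda_ij (> 0), shared scales lambda_0j (> 0), fixed
    standardization constants m_ij and the fixed hyper-hyper mean."""

    lam: np.ndarray  # (N families, J distances)
    lam0: np.ndarray  # (J,)
    m: np.ndarray  # (N, J)
    hyper_mean: float = 1.0

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.lam0 = np.asarray(self.lam0, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.lam <= 0) or np.any(self.lam0 <= 0) or np.any(self.m <= 0):
            raise ValueError("penalties and scales must be strictly positive")
        if self.lam.shape != self.m.shape or self.lam.shape[1] != self.lam0.shape[0]:
            raise ValueError("inconsistent penalty dimensions")
        if self.hyper_mean <= 0:
            raise ValueError("hyper_mean must be positive")

    def copy(self) -> "PenaltyState":
        return PenaltyState(self.lam.copy(), self.lam0.copy(), self.m,
                            self.hyper_mean)


def unscaled_log_density(d, lam_i, m_i) -> float:
    """log f_i(G, S, lambda_i.) = -sum_j d_j / (m_ij lambda_ij)."""
    total = 0.0
    for dj, lj, mj in zip(d, lam_i, m_i):
        if lj <= 0 or mj <= 0:
            raise ValueError("lambda and m must be strictly positive")
        total += dj / (mj * lj)
    return -total


def log_prior_lambda(lam_ij: float, lam0j: float) -> float:
    """Exponential hyperprior: log[exp(-lambda_ij/lambda_0j)/lambda_0j]."""
    if lam_ij < 0 or lam0j <= 0:
        raise ValueError("non-positive penalty parameter")
    return -lam_ij / lam0j - math.log(lam0j)


def log_prior_lambda0(lam0j: float, hyper_mean: float) -> float:
    """Exponential hyper-hyperprior with the given fixed mean."""
    if lam0j < 0 or hyper_mean <= 0:
        raise ValueError("non-positive scale parameter")
    return -lam0j / hyper_mean - math.log(hyper_mean)


def log_species_prior(n_species: int) -> float:
    """Uniform over the (2n-3)!! rooted binary labeled topologies."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    return -math.log(top.count_rooted(n_species))


@dataclass
class ChainState:
    """Full MCMC state: species tree, per-family gene topology indices,
    penalties, and the cached per-family distance tuples."""

    species: tuple  # canonical rooted struct over species ids
    gene_idx: list  # per family: index into its topology support
    penalties: PenaltyState
    distances: list  # per family: projected distance tuple (J components)

    def copy(self) -> "ChainState":
        return ChainState(self.species, list(self.gene_idx),
                          self.penalties.copy(), list(self.distances))


def log_joint(state: ChainState, n_species: int) -> float:
    """Unnormalized log posterior, partition function and the (canceling)
    phylogenetic-likelihood term omitted."""
    p = state.penalties
    out = log_species_prior(n_species)
    for i, d in enumerate(state.distances):
        out += unscaled_log_density(d, p.lam[i], p.m[i])
    for i in range(p.lam.shape[0]):
        for j in range(p.lam.shape[1]):
            out += log_prior_lambda(p.lam[i, j], p.lam0[j])
    for j in range(p.lam0.shape[0]):
        out += log_prior_lambda0(p.lam0[j], p.hyper_mean)
    if not np.isfinite(out):
        raise ValueError("non-finite log posterior")
    return out


def partition_function_bruteforce(leaf_species, species_struct, lam_i, m_i,
                                  model: str = "DLIR",
                                  max_leaves: int = 8) -> float:
    """Z_i(S, lambda_i.) by enumerating every unrooted topology on the
    family's leaf multiset.  Only feasible for small families."""
    L = len(leaf_species)
    if L > max_leaves:
        raise ValueError(
            f"{L} leaves: enumeration infeasible, use exchange mode instead")
    if L < 3:
        return 1.0
    base = "DLIR" if model == "DLIR" else "DLI"
    z = 0.0
    for gu in top.enumerate_unrooted(range(L)):
        dv = recdist.distance_vector(gu, species_struct, leaf_species, base)
        d = project_distances(dv.as_tuple(base), model)
        z += math.exp(unscaled_log_density(d, lam_i, m_i))
    return z
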