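# Methods

## The model

`bayesupertree` estimates a rooted species-tree topology S from weighted
collections of unrooted gene-family tree topologies — typically the
posterior samples of per-gene Bayesian phylogenetic analyses.  Gene
families may contain paralogs and several individuals per species; leaves
are assigned to species automatically by longest-substring match of the
species name inside the leaf label.

The model is a hierarchical Bayesian generalization of the
maximum-likelihood supertree idea: the probability of a gene-family
topology G_i given the species tree decays exponentially in a *vector* of
disagreement measures,

    P(G_i | S, lambda_i.)  =  exp( - sum_j d_j(G_i, S) / (m_ij lambda_ij) ) / Z_i(S, lambda_i.)

with, in the DLIR parameterization, four distances d_j:

* **duplications** and **losses** of the most parsimonious
  duplication–loss reconciliation under the LCA mapping, minimized jointly
  over all rootings of the (unrooted) gene tree;
* **deep coalescences** (extra lineages), minimized over rootings at its
  own optimal root, which need not coincide with the duplication–loss one;
* **mulRF**, a Robinson–Foulds-type distance between the gene multree and
  the species tree extended with one multifurcation per multi-copy
  species, compared unrooted as multisets of species-label-multiset
  bipartitions.

The DLI parameterization drops mulRF.  The species tree is restricted to
each family's species before any distance is computed, so species a family
never sampled cannot inflate loss counts.  m_ij are fixed per-family
standardization constants mapping each distance to [0, 1]: the maximum
possible duplication count (n_i - 1), an internal-edge-count bound for
mulRF, and empirical maxima over the input topologies against a set of
random reference species trees for losses and deep coalescences (floored
at 1; 10 reference trees by default — the constants only set a scale and
are insensitive to this count).

Each penalty lambda_ij has an exponential hyperprior with genome-wide mean
lambda_0j shared across families, and lambda_0j is itself exponential with
a fixed mean (below).  The species-tree prior is uniform over the
(2n-3)!! rooted binary labeled topologies.  The phylogenetic likelihood
P(D_i | G_i) never has to be computed: the input weights are used as the
proposal distribution for gene-tree updates, so the likelihood factor
cancels from the acceptance ratio (importance resampling).

### The fixed hyper-hyper mean

The partition function Z_i is neglected by default (see below).  Without
it the distance factor alone always prefers larger (more permissive)
penalties: the conditional mode is lambda_ij ~ sqrt(delta_ij lambda_0j)
with delta the standardized distance, and lambda_0j in turn tracks the
mean penalty, so the only thing restraining the hierarchy is the single
fixed prior factor on lambda_0 — against N x J likelihood factors.  The
hierarchy is therefore only *informative* (the stated design goal: prefer
small distances overall) if its fixed mean is far below one.  Because the
standardization maps distances to [0, 1] using worst-case (random-tree)
maxima, the spread of standardized distances between candidate species
trees is one to two orders of magnitude smaller than their absolute level,
and the penalties must sit near that spread for the posterior over species
trees to discriminate at all.  The default mean is 1e-5, which places the
equilibrium penalties at the few-percent scale: posteriors concentrate,
the sampler's point estimates behave like a softened multivariate gene
tree parsimony, and the posterior sharpens gene-tree distributions rather
than flattening them.  With means near 1 the penalties drift to the
absolute distance level and the species-tree posterior becomes numerically
uniform.  The value is configurable (`SamplerConfig.hyper_mean`).

## Sampling

All blocks are updated by Generalized Multiple-try Metropolis (k = 4
tries): draw k candidates from the proposal kernel, select one with
probability proportional to a weight function (the unnormalized target),
draw the k-candidate reverse shadow set with the current state substituted
at the selected index, and accept with the weighted ratio.  One sweep
updates, in order: the species tree, each family's gene topology, each
family's penalty vector (all J components jointly, multiplicative
lognormal steps), and the shared scale vector.

Species-tree proposals mix rooted NNI (uniform over the fixed-size raw
swap list — a symmetric kernel) and rerooting (uniform over the other
rootings of the same unrooted topology — also symmetric) with weights
0.7 / 0.3.  Rooted SPR is implemented with a neighborhood-size Hastings
correction but is off by default: enumerating SPR neighborhoods dominates
sweep cost at these tree sizes and NNI + rerooting is already irreducible
over rooted topologies.

Defaults: 20000 sweeps, 50% burn-in, thinning chosen so roughly 1000
samples are kept.  Posterior summaries: MAP rooted topology (ties broken
by higher mean log posterior), 50% majority-rule consensus over the
unrooted samples, the smallest credible set reaching 95%, and per-split
supports.

### The partition function and the exchange algorithm

Z_i(S, lambda_i.) sums the unscaled density over every topology on the
family's leaves; it changes with S and lambda and is intractable beyond a
few leaves.  Neglecting it is the package default, mirroring the original
study's reported setting.  Exchange mode restores it: each species-tree or
penalty proposal is accompanied by auxiliary gene trees drawn from the
distance model at the proposed state (by a secondary NNI chain over full
topology space, 100 sweeps by default, started at the current gene trees),
whose unscaled densities cancel the partition-function ratio in the
acceptance probability.  A brute-force enumerator
(`model.partition_function_bruteforce`, families of up to 8 leaves)
provides exact values for validation; the test-suite checks the exchange
sampler against the exactly normalized posterior on 4-leaf instances.

### Annealing / gene tree parsimony

The ML mode reuses the sweep machinery on the tempered target
P(S, Theta | D)^(1/kT) with kT decreasing geometrically from 1.0 to 1e-3
(the study never states a schedule; this one is the package's choice), and
returns the best-scoring state visited.  With a single cost (DL or ILS),
fixed penalties, unit scaling and point-mass gene-tree inputs this is
exactly weighted gene tree parsimony; the test-suite verifies it attains
the exhaustive-search optimum on 5-species instances.

## The simulator

A replicate is a three-level cascade, all durations in generations:

1. **Species tree** — Kingman coalescent (pairwise rate 1/(2 Ne)) or Yule,
   rescaled to the drawn root height.  Coalescent units are
   generations / (2 Ne).  The replicate-level parameter laws are:
   species count ~ U(10, 80); height ~ U(100, 10000) generations;
   expected duplications E_dup ~ U(1e-3, 4); families N ~ U(2, 50);
   Ne = 2000 LogNormal(0, 0.25); individuals per species ~ U(1, 10)
   (shared by all families); substitution rate 0.001 per generation;
   Gamma(1, 1) branch-rate multipliers at all three levels.  The species
   tree is rescaled in time so its total length in coalescent units stays
   inside the design window [0.05, 5], and the factor is recorded in the
   provenance block.
2. **Locus trees** — a birth–death process of gene duplication (rate
   beta ~ Exponential(mean E_dup / sigma), sigma the total species-tree
   length in generations) and loss (rate ~ U(0, 0.75 beta)), per family,
   grown along the species tree; extinct loci are pruned.
3. **Gene trees** — the multispecies coalescent inside the locus tree,
   with `individuals` gene copies per locus leaf and unconstrained
   coalescence above the root.  Duplication nodes merge lineages the way
   speciations do; the single-haplotype bottleneck at the duplication
   event itself is not modeled.

Substitution-unit branch lengths compose the three gamma multipliers
multiplicatively (species x locus x gene); a gene branch uses the
multiplier of the locus and species branches containing its child end.
These lengths exist only to drive the uncertainty generator — no inference
step reads branch lengths.

Families whose gene tree ends with fewer than four leaves (possible under
heavy loss) are redrawn so every family carries topological information.

The simulator is validated against the closed-form three-taxon discordance
probability (2/3) e^(-t) over a grid of internal branch lengths.

## Gene-tree uncertainty

Each true gene tree is converted into a weighted topology distribution by
length-dependent NNI perturbation: a draw keeps the true topology with
probability 1 - min(pT, 1); otherwise every internal branch e is swapped
(one of its two NNI alternatives at random) with probability
p_e = min(1, pB l_min / l_e), so the shortest branch attains the cap pB
and longer branches are perturbed inversely proportionally to length.
The parameter laws are pT = 1.1 Beta(LT DT, DT) with LT ~ U(2, 5),
DT ~ U(3, 6), and pB = 1.5 Beta(LB, 1) with LB ~ U(1, 5); pT > 1 simply
means every draw is perturbed.  1000 draws are taken per family, the
distinct topologies are truncated to the 160 most frequent, and the true
topology is force-included with at least one count (disable with
`force_true=False`).

The per-branch law is a reconstruction — the source pseudocode is not
available — normalized so the shortest branch attains the cap.  At
realistic family sizes (hundreds of leaves) it corrupts mildly: the most
frequent topology is usually the true one.  At desk-scale family sizes
(8–30 leaves) the same laws are much more corrupting, because a far larger
fraction of internal branches is comparable to the shortest one, so a
wrong topology is frequently the most sampled one.  Scaled-down
benchmark numbers therefore operate under substantially heavier input
noise than full-scale ones, and should not be read as estimates of
full-scale accuracy.

## Distance-matrix baselines

GLASS, SD, STEAC and MAC reduce each gene tree to a species-by-species
distance matrix (minimum or average path length over leaf pairs), merge
matrices across genes (minimum or mean), and cluster (single linkage or
UPGMA); the dispatch table is in `coalmatrix.METHODS`.  Unit-length mode
sets every branch to 1 (path lengths in edges, with a bifurcating root not
counted as a node), the fallback when only topologies are available.
Agglomeration is hand-rolled with lexicographic tie-breaking for
deterministic outputs and is cross-checked against scipy's linkage on
tie-free inputs.

## Numerical choices and degenerate inputs

* All densities are composed in log space; GMTM weights are normalized by
  log-sum-exp, so annealing at low temperature cannot underflow.
* Topologies are canonical nested tuples; deduplication and hashing are
  exact, with no string round-trips.
* Reconciliation minimization over rootings runs as an O(n)
  directed-edge dynamic program (JIT-compiled when numba is available,
  pure Python otherwise) and is pinned against an independent brute-force
  oracle in the tests.
* Optimal-root ties break to the smallest edge index of a deterministic
  edge ordering; consensus and credible-set ties break canonically.
* Families with a single species present get all-zero distances (no
  topological information) and simply do not influence the species tree.
* Every stochastic entry point takes a seed; equal seeds give
  byte-identical outputs (no iteration over string-keyed sets anywhere on
  an output path).

## What the synthetic data does and does not show

The generator reproduces the statistical structure of the study design:
lineage sorting controlled by branch lengths in coalescent units,
family-specific duplication/loss rates, multiple individuals, non-clock
branch lengths, and input distributions with the true topology present but
not necessarily most frequent.  It does not simulate sequences, alignment
error, model misspecification in the per-gene analyses, gene conversion or
horizontal transfer.  Passing benchmarks on these data show the estimator
recovers species trees under duplication/loss plus coalescent discordance
with realistic input noise — not that it is robust to alignment-level
artifacts.

## Known limitations

* The neglected partition function makes the penalty posteriors
  prior-dominated (see the hyper-hyper discussion above); exchange mode is
  exact but roughly an order of magnitude slower.
* Desk-scale problem sizes are used throughout the shipped benchmarks: 20
  replicates, 8–15 species, 5–10 families, 1–3 individuals, 20000 sweeps
  per chain.  Full-study ranges are configurable but take hours.
* The mulRF component is computed after restricting the species tree to
  the family's species; families spanning two species carry mulRF signal
  only through multi-copy star splits.
* Rooted SPR proposals are available but not part of the default kernel.
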