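# bayesupertree

Hierarchical Bayesian supertree inference of a **rooted species tree**
from posterior distributions of **unrooted gene-family tree topologies**.

Genome-wide data sets disagree with any single species tree because of
gene duplication and loss, incomplete lineage sorting, and plain
reconstruction error.  Most species-tree methods model one of these
processes and require orthologous, single-copy genes.  `bayesupertree`
instead treats every source of conflict through a multivariate penalty:
the probability of a gene-family topology G_i given the species tree S is

    P(G_i | S, λ_i·) ∝ exp( − Σ_j d_j(G_i, S) / (m_ij λ_ij) )

where the d_j are the minimum **duplications**, **losses** and **deep
coalescences** of the LCA reconciliation (each minimized over all rootings
of the unrooted gene tree) plus, in the DLIR parameterization, the
**mulRF** distance between the gene multree and the extended species
tree.  The m_ij standardize each distance to [0, 1]; the penalties λ_ij
are family-specific with genome-wide exponential hyperpriors, so gene
families inform each other about how much disagreement to tolerate.
Gene families may contain paralogs and multiple individuals per species —
no ortholog calling is needed, and leaves are mapped to species
automatically by substring match of the species names in the leaf labels.

Inference is MCMC (multiple-try Metropolis over species trees, gene
trees, and penalties), where the input tree weights act as an importance
proposal so the per-gene phylogenetic likelihood cancels.  The output is
a posterior sample of rooted species-tree topologies (MAP tree,
majority-rule consensus, credible sets, split supports) together with
sharpened posterior distributions of the gene trees themselves.  A
simulated-annealing mode returns an ML point estimate and, with a single
cost, reproduces weighted gene tree parsimony exactly.

The package also ships everything needed to study the method without
external data: a three-tree simulator (species tree → birth–death locus
trees → multispecies-coalescent gene trees, with gamma rate
heterogeneity), a nonparametric gene-tree-uncertainty generator, the four
distance-matrix baselines (GLASS, STEAC, SD, MAC), and an evaluation
harness.  See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a small truth, emulate per-gene phylogenetic uncertainty, and
infer the species tree:

```sh
bayesupertree simulate --n-species 8 --n-families 4 --seed 42 -o truth
for i in 1 2 3 4; do
  bayesupertree perturb truth/genefam_00$i.nwk -s truth/species.txt \
      --seed $i -o fam$i.trees
done
bayesupertree run fam?.trees -s truth/species.txt -n 4000 --seed 7 -o posterior
```

The perturbation step prints the drawn uncertainty parameters and support
sizes, e.g.

```
19 distinct topologies -> fam1.trees (pT=0.807, pB=1.492, seed=1)
151 distinct topologies -> fam2.trees (pT=0.584, pB=1.224, seed=2)
```

meaning family 2's "posterior" spreads over 151 topologies, each weighted
by its sampling frequency.  The run command ends with

```
MAP tree (p=0.997): ((s02,(s04,(s01,(s06,s08)))),(s03,(s05,s07)));
```

the most frequent rooted topology in the posterior sample and its
posterior probability.  `posterior/` also contains the 50% majority-rule
consensus with split supports

```
(s01,(s06,s08)1.000,((((s05,s07)1.000,s03)1.000,s02)1.000,s04)1.000);
```

the credible set (`credible_set.tsv`), the sampled trees, and a
tab-separated `trace.tsv` of the continuous parameters for convergence
diagnostics.  Against the generating tree in `truth/species.nwk` this
estimate recovers 4 of the 5 nontrivial splits (split accuracy 0.8) —
with only four heavily perturbed families, one short branch stays
unresolved, which is exactly what the posterior supports report.

Other subcommands: `ml` (simulated-annealing point estimate; `--model DL`
or `ILS` gives gene tree parsimony), `distmatrix` (GLASS/STEAC/SD/MAC),
`distances` (per-family distance vectors against a fixed species tree),
and `evaluate` (the simulation benchmark; tidy TSV output).

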