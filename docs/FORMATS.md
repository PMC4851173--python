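# File formats

## Inputs

**Gene-tree distribution (one file per gene family).**  A plain-text list
of Newick topologies, one per line, optionally preceded by a weight and a
tab:

    0.62	((Dmel_G1,Dsim_G1),(Dyak_G1,Dyak_G2));
    0.38	((Dmel_G1,Dyak_G1),(Dsim_G1,Dyak_G2));

Without a weight column, duplicated topologies are collapsed by counting
(a MrBayes-style `.t` dump concatenated into one list works).  Weights are
normalized to sum to one on load; branch lengths are accepted and ignored
(the model is topology-only).  Nexus TREES blocks (with translate tables)
are accepted for files ending in `.nex`/`.nexus`; tree weights are taken
from `[&W ...]` comments when present.  Blank lines and `#` comments are
skipped.  All trees in one file must share one leaf set.

**Species list.**  Plain text, one species name per line.  Names must be
unique.  Each gene-tree leaf label must contain exactly one species name
as a substring (longest match wins; equal-length double matches are an
error).

**Rooted species tree** (for `distances`): a single Newick tree whose leaf
labels are the species names.

## Outputs

`run` writes into its output directory:

* `trace.tsv` — tab-separated, header row; columns `iteration`,
  `log_posterior`, `lambda0_<j>`, `lambda_<family>_<j>`.  Loadable by
  generic MCMC trace inspectors.
* `species_samples.nwk` — one sampled rooted species topology per line.
* `map_tree.nwk`, `consensus.nwk` (split supports as internal labels),
  `credible_set.tsv` (frequency, tree).
* `config.txt` — every option and the seed that produced the run.

`simulate` writes `species.nwk` (generations), `species_coal.nwk`
(coalescent units), `species.txt`, `genefam_XXX.nwk` (true gene trees,
substitution-unit lengths) and `params.json` (provenance of every
parameter draw).  `perturb` emits the weighted Newick list format above.
`distmatrix` writes one Newick species tree per method.  `distances`
writes a TSV with columns `family`, `topology`, `weight`, `d_dup`,
`d_loss`, `d_ils`, `d_mulrf`, `r_star`, `r_star2` (optimal-root edge
indices).  `evaluate` writes a tidy TSV with one row per (replicate,
method, estimator) and the replicate covariates and seeds.
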