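# Methods

## Problem setting

Single-cell resolved cell–cell interaction (CCI) analysis starts from a
cell–cell interaction matrix (CCIM): rows are ordered (sender, receiver)
pairs of single cells, columns are ligand–receptor pairs drawn from a prior
knowledge database, and entries are interaction scores. The analysis goal is
to cluster cell pairs by their interaction profiles *and* to name, for each
cluster, the small set of ligand–receptor interactions that characterizes
it — in one model, rather than by clustering first and testing for
differential interactions afterwards.

## CCIM construction

Given an expression matrix `E` (cells × genes, nonnegative, normalization
assumed upstream) and a database of pairs `(ligand_k, receptor_k)`, the
score of feature `k` for the directed pair `(s, r)` is

    score(s, r, k) = E[s, ligand_k] · E[r, receptor_k]

the single-cell convention used by NICHES-style tools. Directionality
matters: `(A, B)` and `(B, A)` are distinct rows. Self-pairs `(A, A)` are
included by default and can be excluded. Multi-subunit complexes are not
modeled; each feature is one ligand gene and one receptor gene. A
configurable kernel hook allows alternative score functions.

Two preprocessing steps precede training:

* **Activity filter.** A feature is *active* when its fraction of nonzero
  scores is at least `min_nonzero_fraction` (default 0.05) and its variance
  is positive. CCIMs are extremely sparse — most ligand–receptor pairs never
  co-occur in a cell pair — and constant columns carry no signal and break
  z-scoring.
* **Standardization.** Each retained column is z-scored (population SD,
  `ddof` configurable). Componentwise boosting compares features by
  correlation with a response, which presupposes columns on a common scale.

## Model

* **Encoder.** A single linear layer `Z = X Bᵀ` with no bias or
  nonlinearity; `B` is `d × p` and starts at exactly zero. Every latent
  dimension is therefore a sparse signed linear combination of named
  ligand–receptor features — the interpretable core of the model.
* **Split-softmax.** Per row, `s = [max(z, 0), max(−z, 0)]` (length `2d`)
  followed by a numerically stabilized softmax. Each of the `2d` outputs is
  a soft cluster; a latent dimension contributes one positive-sign and one
  negative-sign cluster, so groups of cell pairs encoded with opposite signs
  in the same dimension are split rather than conflated, and negative
  activations are not squashed toward zero as a plain softmax would.
  Cluster numbering is fixed as `[pos(1..d), neg(1..d)]`:
  cluster `c ≤ d` is dimension `c` positive, cluster `c > d` is dimension
  `c − d` negative (`interpret.cluster_to_dimension` maps between the two).
  Temperature is fixed at 1.
* **Decoder.** Maps the `2d` cluster probabilities back to the `p` features.
  The default is a single linear layer: reconstruction is then a learned
  cluster-profile matrix, which keeps the backward pass that drives feature
  selection well conditioned and is the configuration under which planted
  structure is recovered reliably. Hidden layers (tanh/relu) are available
  through `decoder_hidden` for more expressive reconstructions.
* **Loss.** Mean squared error over all `n·p` entries of the standardized
  score matrix.

## Optimization

Training alternates, every epoch on the full batch:

1. **Pseudo-responses.** One coherent backward pass through decoder and
   split-softmax yields `u_l = −∂L/∂z_l` for every latent dimension, at the
   current parameters. At the split kink `z = 0` the subgradient convention
   takes both sign parts as active; with a one-sided convention the all-zero
   initialization would be a stationary dead point.
2. **Componentwise boosting sweep.** For each dimension `l` in order: center
   `u_l`; under the disentanglement constraint residualize it (least
   squares, with intercept, pseudo-inverse for rank deficiency) against the
   *current* activations of the other dimensions; rescale to unit SD; then
   fit a univariate least-squares coefficient
   `β̂_j = x_jᵀu/(x_jᵀx_j + ε)` for every candidate feature and update only
   the best one: `B[l, j*] += ν β̂`, with `j*` maximizing `|x_jᵀu|`
   (equivalent to the RSS criterion on standardized columns; ties go to the
   lowest index for determinism). Activations of dimension `l` are
   recomputed before dimension `l+1` is processed. The unit-SD rescaling
   does not affect which feature is selected; it makes the step size ν act
   on a scale-free response (the mean-MSE gradient magnitudes are
   `O(1/(n p))` and would otherwise yield vanishing increments). Weights are
   never pruned once set; sparsity comes from the zero start and the
   one-feature-per-sweep updates, so after `t` epochs a row has at most
   `t · updates_per_epoch` nonzeros.
3. **Decoder steps.** `decoder_steps` plain gradient-descent steps on the
   decoder parameters against the reconstruction loss under the updated
   encoder. Several steps per sweep (default 20) keep the decoder near its
   conditional optimum so the next epoch's pseudo-responses reflect
   structure in the data rather than decoder lag.

An alternative hard disentanglement mode (`mode="exclude"`) masks features
already selected by other dimensions instead of residualizing; residualization
is the default because it constrains the *signal*, not the support.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| step size ν | 0.1 | standard boosting shrinkage; units of response SD |
| updates per epoch | 1 | one feature per dimension per epoch |
| disentanglement | on, residualize | near-uncorrelated latent dimensions |
| ε | 1e-12 | guards numerically zero column norms |
| decoder | linear, lr 0.1, 20 steps/epoch | see above; lr in MSE units |
| epochs | 250 | planted benchmark converges well before this |
| batch | full | desk-scale CCIMs fit in memory |

Training is deterministic given the seed (which only enters through decoder
initialization); two runs with the same config produce identical loss traces.
With `epochs=0` the model is returned in its exact degenerate state: zero
encoder, zero latents, uniform cluster probabilities `1/(2d)`.

## Interpretation outputs

* **Hard assignments**: per-row argmax of the cluster probabilities (lowest
  index on ties); softmax monotonicity makes this equal to the argmax over
  the pre-softmax split activations.
* **Ranked interaction lists**: for a positive-sign cluster, the strictly
  positive entries of its dimension's weight row; for a negative-sign
  cluster, the strictly negative entries in absolute value. Magnitudes are
  min–max normalized to importances in [0, 1] and sorted descending. Zero
  weights are *unselected* and never listed — importance 0 means "weakest
  selected", not "not selected". A single-entry list gets importance 1.
* **2D embedding**: UMAP (umap-learn) of the latent representation `Z` by
  default (probabilities optional); defaults neighbors 15, min_dist 0.1,
  seed 42. The contract is shape, finiteness, row order and within-version
  seed reproducibility only.
* **Exports**: `assignments.tsv`, `ranked_interactions.tsv`,
  `embedding.tsv`, and five figures (embedding colored by cluster, sender
  type, receiver type, one cluster's probability, one feature's scores).

## Synthetic benchmark

`simulate.generate_ccim` plants `K` groups of cell pairs, each elevated by
`effect_size` on its own disjoint block of `signature_size` features, plus
i.i.d. Gaussian noise:

    scores[i, j] = μ · 1[j ∈ signature(label_i)] + Normal(0, σ²)

Noise is placed on the score scale directly (not on counts): the model
consumes standardized real-valued scores, so the fixture models the
post-standardization regime. Sender/receiver types encode the planted label
so type-colored visualizations are testable. What this generator does *not*
emulate: count noise and dropout, correlated features, overlapping
signatures, unbalanced clusters, and pairs sharing cells (rows are
independent). Passing recovery tests therefore demonstrates the mechanism —
sparse selection + soft clustering recovers planted block structure — not
performance on real CCIMs.

The reference benchmark is 4 clusters × 200 pairs, 40 features, signature
size 3, μ=3, σ=1 — trained with `d=4`, disentanglement on, across 5 seeds.
Recovery is scored by the adjusted Rand index between hard assignments and
planted labels (predicted clusters matched to truth greedily by maximum
label overlap; `k` is small, optimal matching is unnecessary) and by top-3
precision/recall of the ranked lists against planted signatures (empty list
⇒ precision and recall 0). These sizes keep the whole benchmark under a
minute on one CPU while leaving each cluster enough rows for stable
standardization.

## Known limitations

* Full-batch only; no minibatching, GPU, or variational variants.
* Latent correlations on the planted benchmark sit near 0.25–0.3 even under
  the disentanglement constraint: centered disjoint-block indicators of K
  equal clusters are themselves correlated at −1/(K−1), so this is a floor
  imposed by the data geometry, not a failure of residualization.
* The split-softmax cluster count is structurally `2d`; empty clusters (no
  matching-sign weights) are valid and yield empty ranked lists.
* Hard-assignment ARI can fall when a planted group's probability mass is
  split between a dimension's two signs early in training; longer training
  consolidates but does not guarantee a unique optimum.
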