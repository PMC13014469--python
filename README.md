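# ccibae

Sparse dimensionality reduction for single-cell-resolved cell–cell
interaction data, built around a boosting autoencoder with a split-softmax
soft-clustering layer.

## The problem

Tools like NICHES turn single-cell expression data plus a ligand–receptor
database into a **cell–cell interaction matrix (CCIM)**: rows are ordered
(sender, receiver) pairs of single cells, columns are ligand–receptor pairs,
entries are interaction scores
`score(s, r, k) = expr[s, ligand_k] · expr[r, receptor_k]`. The usual
downstream recipe — reduce, cluster, then test each ligand–receptor pair for
differential scores per cluster — separates clustering from feature
identification. `ccibae` instead learns both jointly:

* a **linear encoder** `Z = X Bᵀ` whose `d × p` weight matrix `B` starts at
  zero and is fitted by **componentwise boosting**: each epoch, per latent
  dimension, the negative loss gradient w.r.t. that dimension is the
  regression pseudo-response, and only the single ligand–receptor feature
  that best fits it receives a shrunken weight update
  `B[l, j*] += ν · β̂`, `β̂_j = x_jᵀu / (x_jᵀx_j + ε)`. The result is a
  sparse, signed, directly interpretable map from features to dimensions.
  A disentanglement constraint (residualizing each pseudo-response against
  the other dimensions' activations) keeps latent dimensions largely
  uncorrelated.
* a **split-softmax layer** `P = softmax([max(z, 0), max(−z, 0)])` turning
  the `d` latent activations into `2d` soft cluster memberships — one
  positive-sign and one negative-sign cluster per dimension, so `d = 30`
  yields 60 clusters.
* a **decoder** mapping the cluster probabilities back to the feature space;
  encoder and decoder are optimized jointly against the mean squared
  reconstruction error, alternating boosting sweeps with gradient steps.

Outputs per trained model: hard cluster assignments with probabilities,
ranked per-cluster ligand–receptor lists with min–max-normalized importance
scores, and 2D UMAP embeddings of the latent representation for visual
inspection. See `docs/methods.md` for the full model description.

## Worked example

Plant 4 groups of 200 cell pairs over 40 features (disjoint 3-feature
signatures, effect size 3, unit noise), train with `d=4`, and inspect what
the model recovered:

```python
from ccibae import (PlantedCCIMSpec, TrainConfig, generate_ccim,
                    standardize_features, train, assign_clusters,
                    rank_all_clusters, adjusted_rand_index, feature_recovery)

spec = PlantedCCIMSpec(seed=1)            # 4 planted clusters, 800 pairs, 40 features
ccim, truth = generate_ccim(spec)
std = standardize_features(ccim)

model = train(std, TrainConfig(d=4, epochs=250, seed=1))
print(f"loss: {model.loss_trace[0]:.3f} -> {model.loss_trace[-1]:.3f}")

P = model.cluster_probabilities(std.scores)        # 800 x 8 soft memberships
assignments = assign_clusters(P)
ari = adjusted_rand_index(truth.labels, assignments["cluster"].to_numpy())
print(f"adjusted Rand index vs planted labels: {ari:.3f}")

lists = rank_all_clusters(model.B, std.feature_meta)
top = assignments["cluster"].mode().iloc[0]
print(lists[top].head(3)[["rank", "ligand", "receptor", "importance", "raw_weight"]])

prec, rec = feature_recovery(lists, assignments["cluster"].to_numpy(), truth, top_k=3)
print(f"top-3 signature precision/recall: {prec:.2f}/{rec:.2f}")
```

prints

```
loss: 1.011 -> 0.793
adjusted Rand index vs planted labels: 0.939
 rank ligand receptor  importance  raw_weight
    1   L008     R008    1.000000    0.829573
    2   L006     R006    0.962210    0.798579
    3   L007     R007    0.857741    0.712897
top-3 signature precision/recall: 1.00/1.00
```

The reconstruction loss drops as boosting selects features; the hard
assignments recover the planted grouping almost perfectly (ARI 0.94, where 1
is identical and 0 is chance); and the ranked list of the largest cluster is
exactly one planted signature block (features 6–8), with importances ordered
by the learned encoder weights.

The same workflow runs from the shell:

```bash
ccibae simulate  --out-dir work/ccim --seed 1
ccibae build-ccim --expression expr.csv --lr-db pairs.tsv --out-dir work/ccim   # or from real data
ccibae train     --ccim-dir work/ccim_std --out-dir work/model --d 4
ccibae interpret --ccim-dir work/ccim_std --checkpoint work/model --out-dir work/results
```

(`train` refuses unstandardized CCIMs; `build-ccim` filters inactive
features and z-scores automatically, `simulate` writes raw scores plus
ground-truth tables.) `interpret` writes `assignments.tsv`,
`ranked_interactions.tsv`, `embedding.tsv` and the five standard figures
(embedding colored by cluster / sender type / receiver type / one cluster's
probability / one feature's scores).

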