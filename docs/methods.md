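# Methods

## Model

`spotguide` clusters spatial transcriptomics (ST) spots by combining three
ingredients: a spatial graph prior, self-supervised representation
learning, and a small set of marker-gene-derived labels.

**Spatial graph.** Spots are nodes; each spot is joined to its `k = 3`
nearest neighbors by Euclidean distance. Three is the natural choice for
hexagonally packed platforms, where an interior spot has three equidistant
nearest neighbors. k-NN selection is directed, so the edge set is
symmetrized by union: `a_ij = 1` if either spot selected the other. Ties at
the k-th distance are broken toward the lower spot index, which makes graph
construction deterministic on regular lattices. Convolutions use the
self-looped symmetric normalization `S = D̃^(-1/2)(A + I)D̃^(-1/2)`; all of
its eigenvalues lie in [-1, 1], so repeated application cannot blow up
activations.

**Preprocessing.** Counts are scaled per spot to a common library-size
target (the median of per-spot totals by default), `log1p`-transformed, and
reduced to the `n_hvg = 3000` most variable genes, ranked by the variance of
log-normalized expression. Zero-library spots are kept as zero rows so the
expression matrix stays aligned with the coordinate file (a warning is
logged). Normalization precedes HVG selection, the standard order.

**Autoencoder.** The encoder is two GCN layers
(`n_genes → 256 → 64`, ReLU after the first, linear second); the decoder
mirrors it. The reconstruction loss is the squared Frobenius norm
`L_recon = Σ_i ‖x_i − x̂_i‖²`. Depth/width are configurable; two layers keep
the receptive field local (2-hop), matching the scale of tissue domains.

**Contrastive term.** A corrupted view permutes the rows of the feature
matrix uniformly at random while keeping the graph fixed — expression
patterns are destroyed, topology is not. For spot i, the readout
`g_i = sigmoid(mean of its neighbors' embeddings)` (the spot itself is
excluded, in both the readout and the labeling walk, so the summary is
strictly neighborhood context). A trainable bilinear discriminator
`Φ(z, g) = sigmoid(zᵀ M g)` — which subsumes the plain dot product at
`M = I` — scores pairs, and

    L_scl = −(1/2N) Σ_i [ log Φ(z_i, g_i) + log(1 − Φ(z'_i, g_i)) ],

where `z'_i` is the corrupted embedding computed on the *original*
adjacency. `L_scl_corrupt` is the role-swapped mirror on the corrupted
view's readouts: positives `(z'_i, g'_i)`, negatives `(z_i, g'_i)`. The
total pre-training objective is `L = λ₁·L_recon + λ₂·(L_scl + L_scl_corrupt)`
with `λ₁ = 10`, `λ₂ = 1`. Scores are clamped to `[1e-7, 1 − 1e-7]` before
logs for numeric safety.

**Optimization.** Full-batch Adam (lr 1e-3, β = 0.9/0.999), 600 pre-training
epochs by default. Gradients are derived by hand (the whole model is a
composition of sparse-dense matmuls, ReLU, sigmoid and bilinear forms) and
are verified against central finite differences to ~1e-6 relative error in
the test suite. A fresh corruption permutation is drawn each epoch from a
seeded generator, so training is bit-reproducible given the seed.

**Marker labeling.** Counts are variance-stabilized with negative-binomial
Pearson residuals `(x − μ)/sqrt(μ + μ²/θ)`, `μ` proportional to library
size, fixed dispersion `θ = 100`, clipped at `±sqrt(N)`. This is a
deliberately simple stand-in for regularized-NB normalization: a fixed,
generous θ behaves like the near-Poisson limit those methods fit for most
genes, and the clipping bounds leverage the same way. Spots are ranked per
domain by residual expression (rank 1 = highest; multi-marker domains sum
per-gene ranks; ties break toward the lower index). The acceptance walk
compares the mean 15-PC profile of a candidate's graph neighbors with that
of the *previously accepted* spot (comparing against a rejected spot would
propagate rejected context) and accepts when cosine similarity exceeds
0.05. Each rejection increments a patience counter; the walk stops when
patience exceeds 10 or the domain reaches its cap of
`0.3 · N / n_domains` accepted spots. Patience and cap defaults are
package choices (exposed as parameters): patience 10 tolerates isolated
outliers in the ranking without letting a domain bleed into another band,
and the cap keeps any single domain from absorbing more than ~a third of
its proportional share. PCA keeps `n_pcs = 15` components (configurable).
A spot labeled by an earlier domain is skipped by later ones, so labels are
unique; domains are processed in marker-map order.

**Fine-tuning.** A one-hidden-layer MLP head (`64 → 32 → K`) is attached to
the pre-trained encoder and both are trained (encoder not frozen) with
cross-entropy on the labeled spots only. Each epoch first evaluates
labeled-spot accuracy and halts at the first epoch exceeding 0.9, before
any further update: the labels are marker-derived and possibly wrong, so
chasing 100% fit would memorize noise.

**Dynamic clustering.** With label coverage `p < 0.20` the classifier would
overfit its few training spots, so the embeddings are clustered unsupervised
with a full-covariance Gaussian mixture (EM, 10 k-means++-seeded restarts,
covariance ridge 1e-6, best final log-likelihood wins; labels are argmax
responsibilities). At `p ≥ 0.20` the fine-tuned classifier labels every
spot. Exactly 20% routes to the classifier: at the boundary the labeled set
is at its most informative. Before the mixture fit the 64-dim embeddings
are PCA-reduced to 20 components — a full covariance per component in 64
dimensions (~2,000 free parameters each) is badly over-parameterized for
typical spot counts and EM degenerates; 20 components is the convention for
model-based clustering of latent spaces in this family of pipelines.

**Evaluation.** Adjusted Rand index from the contingency table, computed in
exact integer/rational arithmetic, so it is invariant to label renaming and
agrees with exhaustive pair counting to machine precision.

## Synthetic data and the noise protocol

The generator emulates laminar tissue: spots on a triangular lattice
(odd rows offset by half a spacing, row pitch `sqrt(3)/2`), domains as
contiguous horizontal bands of near-equal height, counts negative-binomial.
Background genes share mean 1.0 (a typical per-gene UMI depth); each
domain owns exclusive marker genes whose mean is multiplied by 8 inside the
domain; dispersion `θ = 10` gives moderate overdispersion. Defaults: 30×30
spots, 5 domains, 200 genes, 2 markers per domain, seed-reproducible.

What it does **not** emulate: smooth expression gradients within and across
domains, curved or irregular domain boundaries, spot-specific capture
efficiency beyond library-size variation, spatial autocorrelation of
technical noise, and dropout structure beyond what the NB induces. Passing
tests therefore demonstrate that the machinery recovers planted,
well-separated laminar structure under label noise — not performance on
real tissue, where marker quality and boundary ambiguity are the dominant
difficulties.

The label-noise protocol samples `round(p·N)` spots uniformly without
replacement and reassigns `round(q·|sampled|)` of them a label drawn
uniformly from the *other* classes (a corrupted label never equals the
truth). Rounding is half-away-from-zero. ARI is computed only on the
held-out `1 − p` complement. The grid sweeps
`p ∈ {0.15, 0.2, 0.25, 0.3}` × `q ∈ {0.1, …, 0.5}` with replicates;
replicate r uses seed `base + 1000·r`. Pre-training never sees the labels,
so it runs once per dataset and is shared across replicates.

## Numerical choices and degenerate inputs

- Discriminator scores clamped at 1e-7 before logs; softmax stabilized by
  max subtraction.
- EM: components that empty out are re-seeded at a random data point
  (logged); the log-likelihood trace is monotone for an uninterrupted run
  and this is asserted in tests.
- PCA signs fixed by making each component's largest-magnitude loading
  positive, so PC scores are reproducible across runs and BLAS builds.
- Zero-library spots: kept as zero rows (see above). All-zero genes:
  zero residuals in the VST, never a division by zero.
- Cosine similarity of a zero vector is defined as 0 (fails the 0.05
  acceptance bar rather than raising).
- Duplicate coordinates are legal; distance-0 neighbors are valid.

## Problem sizes used in tests

The test suite and the reproduction script run the 30×30 fixture
(900 spots, 200 genes) with a short-schedule preset — 200 pre-training
epochs, at most 100 fine-tuning epochs — which this problem size saturates:
the loss curve is flat well before epoch 200. Library defaults remain
600/200 for larger inputs. Unit tests use a 10×10 lattice.

## Known limitations

- Full-graph training only; no mini-batching. Fine for tens of thousands of
  spots on CPU, not for millions.
- The mixture uses a fixed K (the number of marker domains); no model
  selection over K or covariance families.
- The marker walk's first-come priority makes labels depend on marker-map
  order when domains compete for a spot.
- The VST's fixed dispersion is a simplification; genes with strong
  mean-variance trends are stabilized only approximately.
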