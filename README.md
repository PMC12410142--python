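# spotguide

Marker-gene-guided graph contrastive learning for spatial transcriptomics
clustering.

## The problem

Spatial transcriptomics (ST) platforms measure gene expression at thousands
of spatially resolved capture spots. Grouping spots into tissue domains
(cortical layers, anatomical structures) is usually done unsupervised, which
ignores the domain knowledge biologists already have: marker genes whose
elevated expression characterizes each domain. `spotguide` injects that
knowledge into the embedding and clustering stages while staying robust to
the noise marker-derived labels inevitably carry.

## The method

1. **Spatial graph.** Each spot is a node connected to its 3 nearest
   neighbors by Euclidean distance (union-symmetrized); graph convolutions
   use the self-looped symmetric normalization
   `S = D̃^(-1/2)(A + I)D̃^(-1/2)`.
2. **Contrastive pre-training.** A two-layer GCN encoder
   `H^(l+1) = σ(S H^(l) W^(l) + b^(l))` maps log-normalized HVG expression to
   64-dim embeddings; a mirrored GCN decoder reconstructs the input. A
   corrupted view permutes spot features over the unchanged graph. A
   bilinear discriminator `Φ(z, g) = σ(zᵀMg)` scores each spot embedding
   against its neighborhood readout `g_i = σ(mean of neighbor embeddings)`;
   binary cross-entropy pulls true (spot, neighborhood) pairs together and
   pushes corrupted ones apart. The total loss is
   `L = λ₁·L_recon + λ₂·(L_scl + L_scl_corrupt)` with λ₁ = 10, λ₂ = 1.
3. **Marker labeling.** Spots are ranked per domain by variance-stabilized
   marker expression (rank-sum across markers); walking the ranking, a spot
   is accepted while its neighborhood principal-component profile stays
   cosine-similar to the previously accepted spot's, under a patience budget
   and a per-domain cap. This yields a sparse label set with coverage `p`.
4. **Fine-tuning.** An MLP head on the encoder is trained with
   cross-entropy on the labeled spots, early-stopping at the first epoch
   whose labeled-spot accuracy exceeds 0.9 (the labels may be noisy;
   perfect fits overfit).
5. **Dynamic clustering.** If `p < 20%` the embeddings are clustered with a
   full-covariance Gaussian mixture (EM, multiple restarts); at `p ≥ 20%`
   the fine-tuned classifier labels every spot. Agreement with ground truth
   is scored by the adjusted Rand index (ARI).

Everything runs full-batch on CPU in numpy; gradients are analytic and
checked against finite differences in the test suite.

## Worked example

```bash
python examples/03_full_pipeline.py
```

generates a 30×30 triangular lattice (900 spots, 200 genes) with 5
horizontal domain bands and 2 exclusive markers per domain (8-fold mean
elevation), then runs the full pipeline:

```
label coverage p = 0.30
clustering branch used: classifier
ARI vs planted truth: 0.800
```

30% of spots were confidently labeled from markers alone, so the
classifier branch was selected, and the final partition recovers the
planted bands with ARI 0.80. `examples/04_label_noise_grid.py` sweeps the
label-noise protocol (reveal fraction `p`, corruption fraction `q`, ARI on
held-out spots):

```
p     q
0.15  0.1    0.751283
      0.5    0.584353
0.30  0.1    0.894213
      0.5    0.270363
```

More supervision helps (p = 0.3 beats p = 0.15 at low noise) and heavier
label corruption hurts — the qualitative robustness signature the method is
designed around.

A CLI mirrors the library: `spotguide run`, `spotguide identify-labels`,
`spotguide simulate`, `spotguide evaluate` (see `spotguide --help`).

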