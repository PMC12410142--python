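"""Graph-convolutional autoencoder with infomax-style contrastive pre-training.

The encoder stacks two graph convolutions,

    H^{(l+1)} = sigma( S H^{(l)} W^{(l)} + b^{(l)} ),   S = D̃^{-1/2}(A+I)D̃^{-1/2},

with ReLU after the first layer and a linear second layer; the decoder
mirrors it back to gene space. Pre-training minimizes

    L = lambda1 * L_recon + lambda2 * (L_scl + L_scl_corrupt),

where ``L_recon`` is the squared Frobenius reconstruction error and the two
contrastive terms are binary cross-entropies that score (spot embedding,
neighborhood readout) pairs with a trainable bilinear discriminator
``Phi(z, g) = sigmoid(z^T M g)``. Positive pairs come from one view's own
embeddings and readouts; negatives pair them with the other view, produced
by randomly permuting the spot features over the unchanged graph. The
readout of a spot is the elementwise sigmoid of the mean embedding of its
graph neighbors (the spot itself excluded).

Fine-tuning attaches a one-hidden-layer MLP classifier to the encoder and
trains both with cross-entropy on the sparse identified labels, halting at
the first epoch whose labeled-spot accuracy exceeds a threshold (0.9 by
default) — the labels are marker-derived and possibly noisy, so perfect
fits are deliberately not pursued.

Everything runs full-batch on CPU in numpy; gradients are analytic and the
optimizer is Adam. Training is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .datasets import ValidationError
from .graph import SpotGraph

logger = logging.getLogger(__name__)

_EPS = 1e-7  # probability clamp before logs


@dataclass
class TrainConfig:
    """Hyperparameters of pre-training and fine-tuning.

    ``lambda1``/``lambda2`` weight reconstruction vs. contrastive terms
    (10 and 1). Architecture: ``n_genes -> hidden_dim -> embed_dim`` encoder,
    mirrored decoder, ``embed_dim -> classifier_hidden -> n_clusters`` head.
    """

    lambda1: float = 10.0
    lambda2: float = 1.0
    learning_rate: float = 1e-3
    pretrain_epochs: int = 600
    finetune_max_epochs: int = 200
    early_stop_accuracy: float = 0.9
    hidden_dim: int = 256
    embed_dim: int = 64
    classifier_hidden: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("lambda1 and lambda2 must be >= 0")
        if not 0 < self.early_stop_accuracy <= 1:
            raise ValidationError("early_stop_accuracy must be in (0, 1]")


@dataclass
class ModelParams:
    """All trainable arrays: encoder, decoder, discriminator, classifier."""

    encoder: list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...]
    decoder: list[tuple[np.ndarray, np.ndarray]]
    discriminator: np.ndarray  # bilinear M, embed_dim x embed_dim
    classifier: list[tuple[np.ndarray, np.ndarray]]

    def copy(self) -> "ModelParams":
        return ModelParams(
            [(w.copy(), b.copy()) for w, b in self.encoder],
            [(w.copy(), b.copy()) for w, b in self.decoder],
            self.discriminator.copy(),
            [(w.copy(), b.copy()) for w, b in self.classifier],
        )

    def save(self, path: str) -> None:
        arrays: dict[str, np.ndarray] = {"discriminator": self.discriminator}
        for name, layers in (
            ("encoder", self.encoder),
            ("decoder", self.decoder),
            ("classifier", self.classifier),
        ):
            for i, (w, b) in enumerate(layers):
                arrays[f"{name}_{i}_W"] = w
                arrays[f"{name}_{i}_b"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "ModelParams":
        with np.load(path) as data:
            out: dict[str, list] = {"encoder": [], "decoder": [], "classifier": []}
            for name in out:
                i = 0
                while f"{name}_{i}_W" in data:
                    out[name].append((data[f"{name}_{i}_W"], data[f"{name}_{i}_b"]))
                    i += 1
            return cls(out["encoder"], out["decoder"], data["discriminator"], out["classifier"])


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def init_params(n_genes: int, n_clusters: int, config: TrainConfig) -> ModelParams:
    """Glorot-uniform initialization of all weights, seeded."""
    rng = np.random.default_rng(config.seed)
    dims = [n_genes, config.hidden_dim, config.embed_dim]
    enc = [(_glorot(rng, dims[i], dims[i + 1]), np.zeros(dims[i + 1])) for i in range(2)]
    rdims = dims[::-1]
    dec = [(_glorot(rng, rdims[i], rdims[i + 1]), np.zeros(rdims[i + 1])) for i in range(2)]
    disc = _glorot(rng, config.embed_dim, config.embed_dim)
    cdims = [config.embed_dim, config.classifier_hidden, n_clusters]
    clf = [(_glorot(rng, cdims[i], cdims[i + 1]), np.zeros(cdims[i + 1])) for i in range(2)]
    return ModelParams(enc, dec, disc, clf)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gcn_layer(
    H: np.ndarray,
    norm_adjacency: sparse.spmatrix,
    W: np.ndarray,
    b: np.ndarray,
    use_activation: bool = True,
) -> np.ndarray:
    """One graph convolution: ``sigma(S H W + b)``, ReLU or identity."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != W.shape[0]:
        raise ValidationError(f"feature dim {H.shape[1]} != weight rows {W.shape[0]}")
    out = norm_adjacency @ H @ W + b
    return np.maximum(out, 0.0) if use_activation else out


def encode(X: np.ndarray, graph: SpotGraph, params: ModelParams) -> np.ndarray:
    """Spot embeddings: ReLU GCN layer then linear GCN layer."""
    (w1, b1), (w2, b2) = params.encoder
    h = gcn_layer(X, graph.norm_adjacency, w1, b1, use_activation=True)
    return gcn_layer(h, graph.norm_adjacency, w2, b2, use_activation=False)


def decode(Z: np.ndarray, graph: SpotGraph, params: ModelParams) -> np.ndarray:
    """Mirror of :func:`encode`, mapping embeddings back to gene space."""
    (w1, b1), (w2, b2) = params.decoder
    h = gcn_layer(Z, graph.norm_adjacency, w1, b1, use_activation=True)
    return gcn_layer(h, graph.norm_adjacency, w2, b2, use_activation=False)


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Sum over spots of squared Euclidean reconstruction error."""
    X, X_hat = np.asarray(X), np.asarray(X_hat)
    if X.shape != X_hat.shape:
        raise ValidationError("shape mismatch")
    return float(((X - X_hat) ** 2).sum())


def corrupt_features(X: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Permute feature rows uniformly at random; the graph stays fixed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(X.shape[0])
    return np.asarray(X)[perm]


def readout(Z: np.ndarray, neighbors: Sequence[int]) -> np.ndarray:
    """Sigmoid of the mean embedding of a spot's neighbors (self excluded)."""
    neighbors = np.asarray(neighbors, dtype=int)
    if neighbors.size == 0:
        raise ValidationError("empty neighbor list")
    return _sigmoid(np.asarray(Z)[neighbors].mean(axis=0))


def readout_all(Z: np.ndarray, graph: SpotGraph) -> np.ndarray:
    """All readouts at once via the neighbor-mean operator."""
    return _sigmoid(graph.neighbor_mean_operator() @ Z)


def discriminator(z: np.ndarray, g: np.ndarray, params: ModelParams) -> float:
    """Bilinear similarity score ``sigmoid(z^T M g)`` in (0, 1)."""
    z, g = np.asarray(z, dtype=float), np.asarray(g, dtype=float)
    if z.shape != g.shape:
        raise ValidationError("embedding/readout length mismatch")
    return float(_sigmoid(np.array(z @ params.discriminator @ g)))


def _pair_scores(Z: np.ndarray, G: np.ndarray, M: np.ndarray) -> np.ndarray:
    return _sigmoid(((Z @ M) * G).sum(axis=1))


def contrastive_loss(
    Z: np.ndarray, Z_corrupt: np.ndarray, G: np.ndarray, params: ModelParams
) -> float:
    """Binary cross-entropy over (z_i, g_i) positives and (z'_i, g_i) negatives."""
    m = params.discriminator
    s_pos = np.clip(_pair_scores(Z, G, m), _EPS, 1 - _EPS)
    s_neg = np.clip(_pair_scores(Z_corrupt, G, m), _EPS, 1 - _EPS)
    n = Z.shape[0]
    return float(-(np.log(s_pos) + np.log1p(-s_neg)).sum() / (2 * n))


def contrastive_loss_corrupt(
    Z: np.ndarray, Z_corrupt: np.ndarray, G_corrupt: np.ndarray, params: ModelParams
) -> float:
    """Role-swapped counterpart on the corrupted view's readouts."""
    return contrastive_loss(Z_corrupt, Z, G_corrupt, params)


def total_loss(l_recon: float, l_scl: float, l_scl_corrupt: float, config: TrainConfig) -> float:
    return config.lambda1 * l_recon + config.lambda2 * (l_scl + l_scl_corrupt)


class Adam:
    """Plain Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, arrays: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _pretrain_forward_backward(
    X: np.ndarray,
    Xc: np.ndarray,
    S: sparse.spmatrix,
    P: sparse.spmatrix,
    params: ModelParams,
    config: TrainConfig,
) -> tuple[dict[str, float], list[np.ndarray]]:
    """One full-batch pass: losses plus analytic gradients of every array.

    Gradient order matches ``_pretrain_arrays``: W1,b1,W2,b2 (encoder),
    W3,b3,W4,b4 (decoder), M (discriminator).
    """
    (w1, b1), (w2, b2) = params.encoder
    (w3, b3), (w4, b4) = params.decoder
    m = params.discriminator
    n = X.shape[0]
    lam1, lam2 = config.lambda1, config.lambda2

    # ---- forward ----
    sx = S @ X
    a0 = sx @ w1 + b1
    h1 = np.maximum(a0, 0.0)
    sh1 = S @ h1
    z = sh1 @ w2 + b2

    sxc = S @ Xc
    a0c = sxc @ w1 + b1
    h1c = np.maximum(a0c, 0.0)
    sh1c = S @ h1c
    zc = sh1c @ w2 + b2

    sz = S @ z
    a1 = sz @ w3 + b3
    d1 = np.maximum(a1, 0.0)
    sd1 = S @ d1
    x_hat = sd1 @ w4 + b4

    pz = P @ z
    g = _sigmoid(pz)
    pzc = P @ zc
    gc = _sigmoid(pzc)

    zm = z @ m
    zcm = zc @ m
    u_pp = (zm * g).sum(axis=1)   # original embed, original readout (positive)
    u_pn = (zcm * g).sum(axis=1)  # corrupt embed, original readout (negative)
    u_cp = (zcm * gc).sum(axis=1)  # corrupt embed, corrupt readout (positive)
    u_cn = (zm * gc).sum(axis=1)   # original embed, corrupt readout (negative)
    s_pp, s_pn = _sigmoid(u_pp), _sigmoid(u_pn)
    s_cp, s_cn = _sigmoid(u_cp), _sigmoid(u_cn)

    clip = lambda s: np.clip(s, _EPS, 1 - _EPS)
    l_recon = float(((x_hat - X) ** 2).sum())
    l_scl = float(-(np.log(clip(s_pp)) + np.log1p(-clip(s_pn))).sum() / (2 * n))
    l_sclc = float(-(np.log(clip(s_cp)) + np.log1p(-clip(s_cn))).sum() / (2 * n))
    losses = {
        "l_recon": l_recon,
        "l_scl": l_scl,
        "l_scl_corrupt": l_sclc,
        "total": lam1 * l_recon + lam2 * (l_scl + l_sclc),
    }

    # ---- backward ----
    c = lam2 / (2 * n)
    g_u_pp = -c * (1 - s_pp)
    g_u_pn = c * s_pn
    g_u_cp = -c * (1 - s_cp)
    g_u_cn = c * s_cn

    t_pp = g_u_pp[:, None] * g
    t_pn = g_u_pn[:, None] * g
    t_cp = g_u_cp[:, None] * gc
    t_cn = g_u_cn[:, None] * gc
    d_m = z.T @ t_pp + zc.T @ t_pn + zc.T @ t_cp + z.T @ t_cn

    dz = t_pp @ m.T + t_cn @ m.T
    dzc = t_pn @ m.T + t_cp @ m.T
    dg = g_u_pp[:, None] * zm + g_u_pn[:, None] * zcm
    dgc = g_u_cp[:, None] * zcm + g_u_cn[:, None] * zm
    dz += P.T @ (dg * g * (1 - g))
    dzc += P.T @ (dgc * gc * (1 - gc))

    # decoder path (reconstruction)
    dx_hat = lam1 * 2.0 * (x_hat - X)
    d_w4 = sd1.T @ dx_hat
    d_b4 = dx_hat.sum(axis=0)
    da1 = (S.T @ dx_hat @ w4.T) * (a1 > 0)
    d_w3 = sz.T @ da1
    d_b3 = da1.sum(axis=0)
    dz += S.T @ da1 @ w3.T

    # encoder, original branch
    d_w2 = sh1.T @ dz
    d_b2 = dz.sum(axis=0)
    da0 = (S.T @ dz @ w2.T) * (a0 > 0)
    d_w1 = sx.T @ da0
    d_b1 = da0.sum(axis=0)
    # encoder, corrupted branch (shared weights)
    d_w2 += sh1c.T @ dzc
    d_b2 += dzc.sum(axis=0)
    da0c = (S.T @ dzc @ w2.T) * (a0c > 0)
    d_w1 += sxc.T @ da0c
    d_b1 += da0c.sum(axis=0)

    grads = [d_w1, d_b1, d_w2, d_b2, d_w3, d_b3, d_w4, d_b4, d_m]
    return losses, grads


def _pretrain_arrays(params: ModelParams) -> list[np.ndarray]:
    (w1, b1), (w2, b2) = params.encoder
    (w3, b3), (w4, b4) = params.decoder
    return [w1, b1, w2, b2, w3, b3, w4, b4, params.discriminator]


def pretrain(
    X: np.ndarray,
    graph: SpotGraph,
    config: TrainConfig,
    params: ModelParams | None = None,
    n_clusters: int = 2,
) -> tuple[ModelParams, pd.DataFrame]:
    """Self-supervised pre-training on the combined loss.

    Each epoch draws a fresh feature permutation for the corrupted view
    (seeded, hence reproducible) and takes one full-batch Adam step.
    Returns the trained parameters and a per-epoch loss log.
    """
    X = np.asarray(X, dtype=float)
    if params is None:
        params = init_params(X.shape[1], n_clusters, config)
    else:
        params = params.copy()
    S = graph.norm_adjacency
    P = graph.neighbor_mean_operator()
    arrays = _pretrain_arrays(params)
    opt = Adam(arrays, config.learning_rate)
    rng = np.random.default_rng(config.seed)

    log: list[dict[str, float]] = []
    for epoch in range(config.pretrain_epochs):
        Xc = corrupt_features(X, rng)
        losses, grads = _pretrain_forward_backward(X, Xc, S, P, params, config)
        if not np.isfinite(losses["total"]):
            raise FloatingPointError(
                f"pre-training diverged at epoch {epoch}: {losses}"
            )
        opt.step(grads)
        log.append({"epoch": epoch, **losses})
        if epoch % 100 == 0:
            logger.info("pretrain epoch %d total loss %.4f", epoch, losses["total"])
    return params, pd.DataFrame(log)


def _classifier_forward(Z: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    (wc1, bc1), (wc2, bc2) = params.classifier
    c1 = np.maximum(Z @ wc1 + bc1, 0.0)
    return c1, c1 @ wc2 + bc2


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def finetune(
    params: ModelParams,
    X: np.ndarray,
    graph: SpotGraph,
    labeled_idx: Sequence[int],
    labeled_classes: Sequence[int],
    config: TrainConfig,
) -> tuple[ModelParams, pd.DataFrame]:
    """Supervised fine-tuning of encoder + classifier on the labeled spots.

    ``labeled_classes`` are contiguous class indices into the classifier's
    output dimension. Each epoch first evaluates labeled-spot accuracy and
    stops (without a further update) as soon as it exceeds
    ``early_stop_accuracy``; otherwise a cross-entropy Adam step follows.
    """
    idx = np.asarray(labeled_idx, dtype=int)
    y = np.asarray(labeled_classes, dtype=int)
    if idx.size == 0:
        raise ValidationError("no labeled spots to fine-tune on")
    n_out = params.classifier[-1][0].shape[1]
    if y.max() >= n_out or y.min() < 0:
        raise ValidationError(
            f"class index {y.max()} out of range for a {n_out}-way classifier"
        )
    params = params.copy()
    (w1, b1), (w2, b2) = params.encoder
    (wc1, bc1), (wc2, bc2) = params.classifier
    arrays = [w1, b1, w2, b2, wc1, bc1, wc2, bc2]
    opt = Adam(arrays, config.learning_rate)
    S = graph.norm_adjacency
    X = np.asarray(X, dtype=float)
    sx = S @ X  # input mixing is fixed; cache it
    k = idx.size

    log: list[dict[str, float]] = []
    for epoch in range(config.finetune_max_epochs):
        a0 = sx @ w1 + b1
        h1 = np.maximum(a0, 0.0)
        sh1 = S @ h1
        z = sh1 @ w2 + b2
        c1, logits = _classifier_forward(z, params)

        probs_l = _softmax(logits[idx])
        pred = logits[idx].argmax(axis=1)
        acc = float((pred == y).mean())
        ce = float(-np.log(np.clip(probs_l[np.arange(k), y], _EPS, None)).mean())
        log.append({"epoch": epoch, "cross_entropy": ce, "accuracy": acc})
        if acc > config.early_stop_accuracy:
            logger.info("early stop at epoch %d (accuracy %.3f)", epoch, acc)
            break

        dlogits = np.zeros_like(logits)
        onehot = np.zeros_like(probs_l)
        onehot[np.arange(k), y] = 1.0
        dlogits[idx] = (probs_l - onehot) / k
        d_wc2 = c1.T @ dlogits
        d_bc2 = dlogits.sum(axis=0)
        dc1 = (dlogits @ wc2.T) * (c1 > 0)
        d_wc1 = z.T @ dc1
        d_bc1 = dc1.sum(axis=0)
        dz = dc1 @ wc1.T
        d_w2 = sh1.T @ dz
        d_b2 = dz.sum(axis=0)
        da0 = (S.T @ dz @ w2.T) * (a0 > 0)
        d_w1 = sx.T @ da0
        d_b1 = da0.sum(axis=0)
        opt.step([d_w1, d_b1, d_w2, d_b2, d_wc1, d_bc1, d_wc2, d_bc2])
    return params, pd.DataFrame(log)
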