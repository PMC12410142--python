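"""Final spot assignment and clustering evaluation.

Two routes produce the final partition, switched on the coverage fraction
``p`` of identified labels:

* ``p < 0.20`` — too few labels to trust the fine-tuned classifier, so the
  embeddings are clustered unsupervised with a full-covariance Gaussian
  mixture fitted by EM (the classic model-based clustering approach; K is
  the number of marker clusters). Multiple k-means++-seeded restarts are
  run and the best final log-likelihood wins.
* ``p >= 0.20`` — enough labels that the classifier generalizes, so the
  fine-tuned head labels every spot. The boundary ``p == 0.20`` takes the
  classifier branch: at the boundary the labeled set is at its most
  informative.

The adjusted Rand index (ARI) used for evaluation is computed from the
contingency table in exact integer arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA

from .datasets import ValidationError
from .graph import SpotGraph
from .labeling import IdentifiedLabels
from .model import ModelParams, _classifier_forward, encode

logger = logging.getLogger(__name__)

SWITCH_FRACTION = 0.20  # label coverage at/above which the classifier is used


@dataclass
class GMMFit:
    """A fitted Gaussian mixture: weights, means, covariances, EM trace."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood_trace: list[float]


@dataclass
class ClusterAssignment:
    """Final labels (one per spot) and which branch produced them."""

    labels: np.ndarray
    method_used: str  # "gmm" or "classifier"
    gmm_fit: Optional[GMMFit] = None


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    sol = solve_triangular(chol, (X - mean).T, lower=True)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _em_run(
    X: np.ndarray,
    K: int,
    rng_state: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    reg: float = 1e-6,
) -> tuple[GMMFit, np.ndarray, float]:
    n, d = X.shape
    means, _ = kmeans_plusplus(X, K, random_state=rng_state)
    base_cov = np.cov(X, rowvar=False) + reg * np.eye(d)
    covs = np.repeat(base_cov[None], K, axis=0)
    weights = np.full(K, 1.0 / K)
    rng = np.random.default_rng(rng_state)

    trace: list[float] = []
    prev = -np.inf
    log_resp = None
    for _ in range(max_iter):
        # E step
        log_prob = np.column_stack(
            [np.log(weights[k]) + _log_gaussian(X, means[k], covs[k]) for k in range(K)]
        )
        norm = logsumexp(log_prob, axis=1)
        ll = float(norm.mean())
        trace.append(ll)
        log_resp = log_prob - norm[:, None]
        resp = np.exp(log_resp)
        # M step
        nk = resp.sum(axis=0)
        for k in range(K):
            if nk[k] < 10 * np.finfo(float).eps:
                # degenerate component: re-seed at a random data point
                logger.warning("empty mixture component re-initialized")
                means[k] = X[rng.integers(n)]
                covs[k] = base_cov
                nk[k] = 1.0
                resp[:, k] = 1.0 / n
                continue
            means[k] = resp[:, k] @ X / nk[k]
            diff = X - means[k]
            covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k] + reg * np.eye(d)
        weights = nk / nk.sum()
        weights /= weights.sum()
        if abs(ll - prev) < tol:
            break
        prev = ll
    labels = np.asarray(log_resp).argmax(axis=1)
    return GMMFit(weights, means, covs, trace), labels, trace[-1]


def gmm_cluster(Z: np.ndarray, K: int, seed: int = 0, n_init: int = 10) -> ClusterAssignment:
    """Full-covariance Gaussian-mixture EM clustering of embeddings.

    Runs ``n_init`` k-means++-seeded EM fits and keeps the one with the best
    final log-likelihood. Labels are argmax posterior responsibilities.
    """
    Z = np.asarray(Z, dtype=float)
    if K < 1:
        raise ValidationError("K must be >= 1")
    if K > Z.shape[0]:
        raise ValidationError(f"K={K} exceeds n_spots={Z.shape[0]}")
    best: tuple[float, GMMFit, np.ndarray] | None = None
    for i in range(n_init):
        fit, labels, ll = _em_run(Z, K, rng_state=seed + i)
        if best is None or ll > best[0]:
            best = (ll, fit, labels)
    _, fit, labels = best
    return ClusterAssignment(labels, "gmm", gmm_fit=fit)


def classify_all(params: ModelParams, X: np.ndarray, graph: SpotGraph) -> ClusterAssignment:
    """Label every spot with the fine-tuned classifier head (argmax logits)."""
    Z = encode(X, graph, params)
    _, logits = _classifier_forward(Z, params)
    return ClusterAssignment(logits.argmax(axis=1), "classifier")


def dynamic_cluster(
    params: ModelParams,
    X: np.ndarray,
    graph: SpotGraph,
    identified: IdentifiedLabels,
    K: int,
    seed: int = 0,
    gmm_pca_dim: Optional[int] = 20,
) -> ClusterAssignment:
    """Choose GMM vs. classifier on label coverage ``p`` (switch at 20%).

    On the GMM branch the embeddings are first PCA-reduced to
    ``gmm_pca_dim`` components (pass ``None`` to skip): a full-covariance
    mixture in the raw embedding space is badly over-parameterized for
    typical spot counts, and model-based clustering in this lineage is
    conventionally run on a PCA of the latent space.
    """
    if identified.p < SWITCH_FRACTION:
        Z = encode(X, graph, params)
        if gmm_pca_dim is not None and gmm_pca_dim < Z.shape[1]:
            Z = PCA(n_components=gmm_pca_dim, svd_solver="full").fit_transform(Z)
        return gmm_cluster(Z, K, seed=seed)
    return classify_all(params, X, graph)


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two partitions, in exact arithmetic.

    ``(sum_ij C(n_ij,2) - E) / (max - E)`` with the permutation-model
    expectation ``E``; invariant to label renaming; 1 for identical
    partitions, ~0 for independent ones.
    """
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b):
        raise ValidationError("label vectors differ in length")
    n = len(a)
    if n < 2:
        raise ValidationError("need at least 2 items")
    table: dict[tuple, int] = {}
    row: dict = {}
    col: dict = {}
    for x, y in zip(a, b):
        table[(x, y)] = table.get((x, y), 0) + 1
        row[x] = row.get(x, 0) + 1
        col[y] = col.get(y, 0) + 1
    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(v, 2) for v in row.values())
    sum_b = sum(comb(v, 2) for v in col.values())
    total = comb(n, 2)
    expected = Fraction(sum_a * sum_b, total)
    max_index = Fraction(sum_a + sum_b, 2)
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))
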