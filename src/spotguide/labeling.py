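"""Marker-gene-driven identification of a sparse set of labeled spots.

Given a per-domain marker gene list, this module assigns labels to a small,
high-confidence subset of spots. The procedure rests on two assumptions:
spots expressing a domain's markers highly are likely members of that
domain, and members of one domain are spatial neighbors with similar
expression profiles.

Per domain, spots are ranked by marker expression (rank-sum across markers
for multi-marker domains) on variance-stabilized counts. Walking the ranked
list, the top spot is accepted unconditionally; each later candidate is
accepted only if the mean principal-component profile of its graph
neighbors is cosine-similar (above a threshold) to that of the previously
accepted spot. Repeated rejections exhaust a patience budget, and a
per-domain cap prevents over-identification of small domains.

The resulting sparse labels (coverage fraction ``p``) drive classifier
fine-tuning downstream; users with their own labels can bypass this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datasets import STDataset, ValidationError
from .graph import SpotGraph

logger = logging.getLogger(__name__)


@dataclass
class MarkerGeneMap:
    """Mapping from cluster/domain name to its marker gene symbols."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError("marker map is empty")

    @property
    def n_clusters(self) -> int:
        return len(self.markers)


@dataclass
class LabelingParams:
    """Knobs of the label-identification walk.

    ``n_pcs`` principal components summarize each spot's neighborhood
    profile; ``cosine_threshold`` is the acceptance bar on neighborhood
    similarity; ``patience_limit`` bounds consecutive-reject tolerance;
    ``max_frac_per_cluster`` caps accepted spots per cluster at
    ``max_frac_per_cluster * n_spots / n_clusters``.
    """

    n_pcs: int = 15
    cosine_threshold: float = 0.05
    patience_limit: int = 10
    max_frac_per_cluster: float = 0.3

    def __post_init__(self) -> None:
        if not -1.0 <= self.cosine_threshold <= 1.0:
            raise ValidationError("cosine_threshold must be in [-1, 1]")
        if self.n_pcs < 1 or self.patience_limit < 1:
            raise ValidationError("n_pcs and patience_limit must be positive")
        if not 0 < self.max_frac_per_cluster <= 1:
            raise ValidationError("max_frac_per_cluster must be in (0, 1]")


@dataclass
class IdentifiedLabels:
    """Sparse spot -> cluster assignments with coverage fraction ``p``."""

    assignments: dict[int, str]
    n_spots: int

    @property
    def p(self) -> float:
        return len(self.assignments) / self.n_spots

    def class_names(self) -> list[str]:
        return sorted(set(self.assignments.values()))


def read_marker_map(path: str) -> MarkerGeneMap:
    """Read markers from CSV (columns cluster,gene) or JSON {cluster: [genes]}."""
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        return MarkerGeneMap({str(c): [str(g) for g in gs] for c, gs in raw.items()})
    df = pd.read_csv(path, dtype=str)
    if not {"cluster", "gene"}.issubset(df.columns):
        raise ValidationError("marker CSV needs columns 'cluster' and 'gene'")
    markers: dict[str, list[str]] = {}
    for c, g in zip(df["cluster"], df["gene"]):
        markers.setdefault(c, []).append(g)
    return MarkerGeneMap(markers)


def write_marker_map(marker_map: MarkerGeneMap, path: str) -> None:
    rows = [(c, g) for c, genes in marker_map.markers.items() for g in genes]
    pd.DataFrame(rows, columns=["cluster", "gene"]).to_csv(path, index=False)


def read_label_csv(path: str, spot_ids: Sequence[str], n_spots: int) -> IdentifiedLabels:
    """Read a sparse label CSV (spot_id,label) into index-keyed assignments."""
    df = pd.read_csv(path, dtype=str)
    index = {s: i for i, s in enumerate(spot_ids)}
    assignments: dict[int, str] = {}
    for s, lab in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if s in index:
            assignments[index[s]] = lab
    return IdentifiedLabels(assignments, n_spots)


def filter_unique_markers(
    marker_map: MarkerGeneMap, gene_names: Sequence[str]
) -> MarkerGeneMap:
    """Drop markers absent from the data or shared between clusters.

    A gene listed under two or more clusters is uninformative for telling
    them apart and is removed everywhere. Any cluster left with no marker
    raises a :class:`ValidationError` naming it.
    """
    present = set(gene_names)
    counts: dict[str, int] = {}
    for genes in marker_map.markers.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    filtered: dict[str, list[str]] = {}
    for cluster, genes in marker_map.markers.items():
        kept = [g for g in dict.fromkeys(genes) if g in present and counts[g] == 1]
        if not kept:
            raise ValidationError(f"cluster '{cluster}' has no usable marker gene")
        if len(kept) == 1:
            logger.warning("cluster '%s' retains a single marker gene", cluster)
        filtered[cluster] = kept
    return MarkerGeneMap(filtered)


def vst_normalize(counts: np.ndarray, theta: float = 100.0) -> np.ndarray:
    """Variance-stabilizing transform via negative-binomial Pearson residuals.

    The expected count of gene g in spot i is proportional to the spot's
    library size: ``mu_ig = n_i * (gene g total) / (grand total)``. Residuals
    ``(x - mu) / sqrt(mu + mu^2/theta)`` use a fixed dispersion ``theta``
    and are clipped to ``±sqrt(n_spots)``. All-zero genes map to zero rows.
    """
    x = np.asarray(counts, dtype=float)
    n_spots = x.shape[0]
    lib = x.sum(axis=1, keepdims=True)
    gene_tot = x.sum(axis=0, keepdims=True)
    grand = x.sum()
    if grand == 0:
        return np.zeros_like(x)
    mu = lib * gene_tot / grand
    denom = np.sqrt(mu + mu**2 / theta)
    resid = np.divide(x - mu, denom, out=np.zeros_like(x), where=denom > 0)
    clip = np.sqrt(n_spots)
    return np.clip(resid, -clip, clip)


def compute_pcs(normalized: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top principal-component scores with a deterministic sign convention.

    Columns are centered; components are ordered by decreasing explained
    variance and each is flipped so its largest-magnitude loading is
    positive (removes the arbitrary sign of eigenvectors).
    """
    x = np.asarray(normalized, dtype=float)
    if n_pcs > min(x.shape):
        raise ValidationError(
            f"n_pcs={n_pcs} exceeds min(n_spots, n_genes)={min(x.shape)}"
        )
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(x)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def rank_spots(
    normalized: np.ndarray,
    marker_map: MarkerGeneMap,
    cluster: str,
    gene_names: Sequence[str],
) -> np.ndarray:
    """Order spots by marker expression, best first.

    Per marker gene, rank 1 is the highest-expressing spot (ties ranked by
    lower spot index). For multi-marker clusters per-gene ranks are summed;
    the final order is ascending cumulative rank, ties again by index.
    """
    if cluster not in marker_map.markers:
        raise ValidationError(f"unknown cluster '{cluster}'")
    gene_index = {g: i for i, g in enumerate(gene_names)}
    n = normalized.shape[0]
    cum = np.zeros(n)
    for gene in marker_map.markers[cluster]:
        expr = normalized[:, gene_index[gene]]
        order = np.lexsort((np.arange(n), -expr))  # high expr first, then index
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        cum += ranks
    return np.lexsort((np.arange(n), cum))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def identify_labels(
    dataset: STDataset,
    graph: SpotGraph,
    marker_map: MarkerGeneMap,
    params: LabelingParams | None = None,
) -> IdentifiedLabels:
    """Run the full marker-based identification walk over all clusters.

    Clusters are processed in the marker map's order; a spot labeled by an
    earlier cluster is skipped by later ones (first-come priority). Returns
    the sparse assignments and their coverage fraction ``p``.
    """
    params = params or LabelingParams()
    marker_map = filter_unique_markers(marker_map, dataset.gene_names)
    vst = vst_normalize(dataset.counts)
    pcs = compute_pcs(vst, min(params.n_pcs, min(vst.shape)))
    neighbor_pcs = graph.neighbor_mean_operator() @ pcs

    n = dataset.n_spots
    cap = max(1, int(params.max_frac_per_cluster * n / marker_map.n_clusters))
    assignments: dict[int, str] = {}
    for cluster in marker_map.markers:
        ranked = rank_spots(vst, marker_map, cluster, dataset.gene_names)
        accepted = 0
        patience = 0
        prev: int | None = None
        for spot in ranked:
            spot = int(spot)
            if spot in assignments:
                continue
            if prev is None:
                ok = True
            else:
                ok = _cosine(neighbor_pcs[spot], neighbor_pcs[prev]) > params.cosine_threshold
            if ok:
                assignments[spot] = cluster
                prev = spot
                accepted += 1
                if accepted >= cap:
                    break
            else:
                patience += 1
                if patience > params.patience_limit:
                    break
        if accepted == 0:
            logger.warning("cluster '%s' accepted zero spots", cluster)
    return IdentifiedLabels(assignments, n)
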