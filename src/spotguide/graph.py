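"""Spatial k-nearest-neighbor graph over spots.

Each spot is connected to its ``k`` nearest neighbors by Euclidean distance
(k=3 by default, matching the near-hexagonal packing of 10x Visium spots,
where interior spots have three equidistant nearest neighbors). The directed
k-NN edge set is symmetrized by union, so every spot keeps at least its own
k neighbors. Graph convolutions use the symmetric normalization
``D̃^{-1/2} (A + I) D̃^{-1/2}``; the contrastive readout uses the
row-stochastic neighbor-averaging operator ``D^{-1} A`` (self excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .datasets import ValidationError


@dataclass
class SpotGraph:
    """Binary spatial adjacency and its derived operators.

    ``adjacency`` is symmetric with a zero diagonal. ``norm_adjacency`` is
    the self-looped symmetric normalization used by the GCN layers.
    ``neighbor_lists[i]`` holds the sorted neighbor indices of spot ``i``.
    """

    adjacency: sparse.csr_matrix
    norm_adjacency: sparse.csr_matrix
    neighbor_lists: list[np.ndarray]
    k: int

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    def neighbor_mean_operator(self) -> sparse.csr_matrix:
        """Row-stochastic ``D^{-1} A``: row i averages over i's neighbors."""
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return sparse.diags(inv) @ self.adjacency


def _knn_edges(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Directed k-NN edges with ties at the k-th distance broken by lower index."""
    n = coords.shape[0]
    tree = cKDTree(coords)
    # over-query to expose ties at the k-th distance, then resolve by index
    m = min(n, k + 8)
    dist, idx = tree.query(coords, k=m)
    rows, cols = [], []
    for i in range(n):
        d_i, j_i = dist[i], idx[i]
        mask = j_i != i
        d_i, j_i = d_i[mask], j_i[mask]
        if len(j_i) > k and d_i[k - 1] == d_i[-1]:
            # tie block may extend beyond the over-query window: brute force
            d_all = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
            j_i = np.delete(np.arange(n), i)
            d_i = d_all[j_i]
        order = np.lexsort((j_i, d_i))  # distance first, then index
        chosen = j_i[order[:k]]
        rows.extend([i] * len(chosen))
        cols.extend(chosen.tolist())
    return np.array(rows), np.array(cols)


def build_knn_graph(coords: np.ndarray, k: int = 3) -> SpotGraph:
    """Build the union-symmetrized k-NN graph on spot coordinates.

    Raises :class:`ValidationError` when ``n_spots <= k`` or coordinates are
    non-finite. Duplicate coordinates are allowed (distance 0 neighbors).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k:
        raise ValidationError(f"need more than k={k} spots, got {n}")
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinates")

    rows, cols = _knn_edges(coords, k)
    a = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    a = a.maximum(a.T)  # union symmetrization; entries stay binary
    a.setdiag(0)
    a.eliminate_zeros()
    a.data[:] = 1.0

    neighbor_lists = [np.sort(a.indices[a.indptr[i]: a.indptr[i + 1]]) for i in range(n)]
    return SpotGraph(a, normalize_adjacency(a), neighbor_lists, k)


def normalize_adjacency(adjacency: sparse.spmatrix) -> sparse.csr_matrix:
    """Self-looped symmetric normalization ``D̃^{-1/2} (A + I) D̃^{-1/2}``."""
    a = sparse.csr_matrix(adjacency, dtype=float)
    n = a.shape[0]
    if a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    a_tilde = a + sparse.identity(n, format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
    return sparse.csr_matrix(d_inv_sqrt @ a_tilde @ d_inv_sqrt)


def write_edge_list(graph: SpotGraph, path: str) -> None:
    """Dump undirected edges (i < j) as a two-column TSV for inspection."""
    coo = sparse.triu(graph.adjacency, k=1).tocoo()
    pd.DataFrame({"i": coo.row, "j": coo.col}).to_csv(path, sep="\t", index=False)
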