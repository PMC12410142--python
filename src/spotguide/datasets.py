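"""Loading, writing and preprocessing of spot-by-gene expression data.

A spatial-transcriptomics run is represented by :class:`STDataset`: a raw
UMI count matrix (spots x genes), 2-D spot coordinates, stable spot/gene
identifiers and, optionally, ground-truth domain labels for evaluation.
Counts can be read from the standard 10x-style Matrix Market triplet
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``) or from a dense CSV.

Preprocessing follows the common single-cell workflow: per-spot library-size
normalization to a shared target (the median library size by default),
``log1p`` transform, and selection of highly variable genes ranked by the
variance of their log-normalized expression.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class STDataset:
    """A spatial transcriptomics sample: counts, coordinates, identifiers.

    Attributes
    ----------
    counts
        Non-negative integer-valued matrix, shape ``(n_spots, n_genes)``.
    coords
        Spot centroids in platform units, shape ``(n_spots, 2)``.
    spot_ids, gene_names
        Unique string identifiers for rows and columns of ``counts``.
    truth_labels
        Optional per-spot domain annotation used only for evaluation.
    """

    counts: np.ndarray
    coords: np.ndarray
    spot_ids: list[str]
    gene_names: list[str]
    truth_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_names = [str(g) for g in self.gene_names]
        n_spot, n_gene = self.counts.shape
        if self.coords.shape != (n_spot, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {n_spot} spots"
            )
        if len(self.spot_ids) != n_spot:
            raise ValidationError("spot_ids length does not match counts rows")
        if len(self.gene_names) != n_gene:
            raise ValidationError("gene_names length does not match counts columns")
        if len(set(self.spot_ids)) != n_spot:
            raise ValidationError("duplicate spot_ids")
        if len(set(self.gene_names)) != n_gene:
            raise ValidationError("duplicate gene_names")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("negative counts")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinates")
        if self.truth_labels is not None:
            self.truth_labels = [str(t) for t in self.truth_labels]
            if len(self.truth_labels) != n_spot:
                raise ValidationError("truth_labels length does not match spots")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class PreprocessConfig:
    """Normalization/HVG settings.

    ``n_hvg`` keeps the top highly variable genes (3000 by default).
    ``target_sum`` is the per-spot library-size target before ``log1p``;
    the string ``"median"`` uses the median of per-spot totals.
    """

    n_hvg: int = 3000
    target_sum: float | str = "median"

    def __post_init__(self) -> None:
        if self.n_hvg < 1:
            raise ValidationError("n_hvg must be >= 1")
        if not (self.target_sum == "median" or float(self.target_sum) > 0):
            raise ValidationError("target_sum must be positive or 'median'")


def _read_tsv_column(path: str) -> list[str]:
    # barcodes.tsv has one column; features.tsv may have id/symbol/type --
    # take the last text column that is unique, preferring symbols (col 2).
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] >= 2 and df.iloc[:, 1].is_unique:
        return df.iloc[:, 1].tolist()
    return df.iloc[:, 0].tolist()


def _load_counts_mtx(count_path: str) -> tuple[np.ndarray, list[str], list[str]]:
    d = count_path if os.path.isdir(count_path) else os.path.dirname(count_path)
    mtx = count_path if count_path.endswith(".mtx") else os.path.join(d, "matrix.mtx")
    barcodes = _read_tsv_column(os.path.join(d, "barcodes.tsv"))
    features = _read_tsv_column(os.path.join(d, "features.tsv"))
    m = spio.mmread(mtx)
    m = m.toarray() if sparse.issparse(m) else np.asarray(m)
    if m.shape == (len(features), len(barcodes)):
        m = m.T  # 10x convention: genes x spots on disk
    elif m.shape != (len(barcodes), len(features)):
        raise ValidationError(
            f"matrix shape {m.shape} matches neither (spots,genes)="
            f"({len(barcodes)},{len(features)}) nor its transpose"
        )
    return m, barcodes, features


def _load_counts_csv(count_path: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(count_path, index_col=0)
    return df.to_numpy(), [str(s) for s in df.index], [str(g) for g in df.columns]


def load_dataset(
    count_path: str,
    coord_path: str,
    label_path: Optional[str] = None,
) -> STDataset:
    """Load counts + coordinates (+ optional labels), aligned by spot id.

    ``count_path`` is either a directory / ``.mtx`` file of a Matrix Market
    triplet, or a dense CSV (header = gene names, index = spot ids).
    ``coord_path`` is a CSV with columns ``spot_id,x,y``. Spot order follows
    the coordinate file; spots present in only one file are dropped with a
    warning.
    """
    if not os.path.exists(count_path):
        raise FileNotFoundError(count_path)
    if not os.path.exists(coord_path):
        raise FileNotFoundError(coord_path)

    if os.path.isdir(count_path) or count_path.endswith(".mtx"):
        counts, spot_ids, gene_names = _load_counts_mtx(count_path)
    else:
        counts, spot_ids, gene_names = _load_counts_csv(count_path)

    coords_df = pd.read_csv(coord_path, dtype={"spot_id": str})
    for col in ("spot_id", "x", "y"):
        if col not in coords_df.columns:
            raise ValidationError(f"coordinate file missing column '{col}'")

    count_index = {s: i for i, s in enumerate(spot_ids)}
    keep = coords_df["spot_id"].isin(count_index)
    n_coord_only = int((~keep).sum())
    n_count_only = len(spot_ids) - int(keep.sum())
    if n_coord_only or n_count_only:
        logger.warning(
            "dropping %d coord-only and %d count-only spots", n_coord_only, n_count_only
        )
    coords_df = coords_df[keep]
    if coords_df.empty:
        raise ValidationError("no overlapping spot_ids between counts and coordinates")

    order = [count_index[s] for s in coords_df["spot_id"]]
    counts = counts[order]
    final_ids = coords_df["spot_id"].tolist()
    coords = coords_df[["x", "y"]].to_numpy(dtype=float)

    truth = None
    if label_path is not None:
        lab = pd.read_csv(label_path, dtype=str)
        lab_map = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
        truth = [lab_map.get(s, "NA") for s in final_ids]

    if counts.size and counts.min() < 0:
        raise ValidationError("negative counts")
    return STDataset(counts, coords, final_ids, gene_names, truth)


def write_dataset(dataset: STDataset, out_dir: str) -> None:
    """Write the standard file set: mtx triplet, coords CSV, truth CSV."""
    os.makedirs(out_dir, exist_ok=True)
    spio.mmwrite(
        os.path.join(out_dir, "matrix.mtx"),
        sparse.csr_matrix(np.asarray(dataset.counts).T),  # genes x spots on disk
        field="integer",
    )
    pd.Series(dataset.spot_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(dataset.gene_names).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.DataFrame(
        {"spot_id": dataset.spot_ids, "x": dataset.coords[:, 0], "y": dataset.coords[:, 1]}
    ).to_csv(os.path.join(out_dir, "coords.csv"), index=False)
    if dataset.truth_labels is not None:
        pd.DataFrame({"spot_id": dataset.spot_ids, "label": dataset.truth_labels}).to_csv(
            os.path.join(out_dir, "truth_labels.csv"), index=False
        )


def log_normalize(dataset: STDataset, config: PreprocessConfig | None = None) -> np.ndarray:
    """Library-size normalize each spot to a common target, then ``log1p``.

    Spots with zero total count stay all-zero (warned); the matrix must
    contain at least one positive count.
    """
    config = config or PreprocessConfig()
    counts = np.asarray(dataset.counts, dtype=float)
    totals = counts.sum(axis=1)
    if totals.sum() == 0:
        raise ValidationError("all-zero count matrix")
    if config.target_sum == "median":
        target = float(np.median(totals[totals > 0]))
    else:
        target = float(config.target_sum)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d spots have zero library size; kept as zero rows", n_zero)
    scale = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    return np.log1p(counts * scale[:, None])


def select_hvg(
    normalized: np.ndarray, gene_names: Sequence[str], n_hvg: int
) -> tuple[np.ndarray, list[str]]:
    """Keep the ``n_hvg`` genes with the largest variance of log expression.

    The original column order is preserved among kept genes; variance ties
    are broken toward the lower column index. With ``n_hvg >= n_genes`` the
    input is returned unchanged.
    """
    if n_hvg < 1:
        raise ValidationError("n_hvg must be >= 1")
    normalized = np.asarray(normalized)
    n_genes = normalized.shape[1]
    if n_hvg >= n_genes:
        return normalized, list(gene_names)
    var = normalized.var(axis=0)
    # stable sort on -var => ties keep ascending column index
    ranked = np.argsort(-var, kind="stable")[:n_hvg]
    keep = np.sort(ranked)
    return normalized[:, keep], [gene_names[i] for i in keep]


def preprocess(
    dataset: STDataset, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """normalize -> log1p -> HVG selection; returns (matrix, kept gene names)."""
    config = config or PreprocessConfig()
    normalized = log_normalize(dataset, config)
    return select_hvg(normalized, dataset.gene_names, config.n_hvg)


def write_labels_csv(path: str, spot_ids: Sequence[str], labels: Sequence, **extra) -> None:
    """Write a labels CSV (spot_id, predicted_label[, extra columns])."""
    df = pd.DataFrame({"spot_id": list(spot_ids), "predicted_label": list(labels)})
    for k, v in extra.items():
        df[k] = v
    df.to_csv(path, index=False)


def write_embeddings_csv(path: str, spot_ids: Sequence[str], Z: np.ndarray) -> None:
    df = pd.DataFrame(Z, columns=[f"dim_{i}" for i in range(Z.shape[1])])
    df.insert(0, "spot_id", list(spot_ids))
    df.to_csv(path, index=False)
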