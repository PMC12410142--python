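"""End-to-end orchestration: load -> preprocess -> graph -> labels ->
pretrain -> finetune -> dynamic clustering -> evaluation.

:class:`RunConfig` bundles every stage's settings; exactly one of a marker
file or a user label file must be supplied (users with their own identified
spots skip the marker step entirely). :func:`run_pipeline` executes the
stages in order and writes labels, embeddings, a training log and — when
ground truth is available — an ARI report into the output directory.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, adjusted_rand_index, dynamic_cluster
from .datasets import (
    PreprocessConfig,
    STDataset,
    ValidationError,
    load_dataset,
    preprocess,
    write_embeddings_csv,
    write_labels_csv,
)
from .graph import build_knn_graph
from .labeling import (
    IdentifiedLabels,
    LabelingParams,
    identify_labels,
    read_label_csv,
    read_marker_map,
)
from .model import ModelParams, TrainConfig, encode, finetune, pretrain

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see module docstring."""

    count_path: str
    coord_path: str
    marker_path: Optional[str] = None
    label_path: Optional[str] = None
    truth_path: Optional[str] = None
    out_dir: str = "spotguide_out"
    n_clusters: Optional[int] = None  # default: number of label classes
    k_neighbors: int = 3
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    labeling: LabelingParams = field(default_factory=LabelingParams)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if (self.marker_path is None) == (self.label_path is None):
            raise ValidationError(
                "provide exactly one of marker_path or label_path"
            )


@dataclass
class RunResult:
    assignment: ClusterAssignment
    embeddings: np.ndarray
    identified: IdentifiedLabels
    training_log: pd.DataFrame
    ari: Optional[float] = None


def run_pipeline(config: RunConfig, dataset: STDataset | None = None) -> RunResult:
    """Execute the full pipeline; ``dataset`` overrides file loading."""
    if dataset is None:
        dataset = load_dataset(config.count_path, config.coord_path, config.truth_path)
    logger.info("stage load: %d spots x %d genes", dataset.n_spots, dataset.n_genes)

    X, _ = preprocess(dataset, config.preprocess)
    graph = build_knn_graph(dataset.coords, k=config.k_neighbors)
    logger.info("stage graph: k=%d, %d edges", config.k_neighbors,
                graph.adjacency.nnz // 2)

    if config.marker_path is not None:
        marker_map = read_marker_map(config.marker_path)
        identified = identify_labels(dataset, graph, marker_map, config.labeling)
    else:
        identified = read_label_csv(config.label_path, dataset.spot_ids, dataset.n_spots)
    if not identified.assignments:
        raise ValidationError("no labeled spots identified or supplied")
    classes = identified.class_names()
    n_clusters = config.n_clusters or len(classes)
    logger.info("stage labels: %d spots labeled (p=%.3f), %d classes",
                len(identified.assignments), identified.p, len(classes))

    params, pretrain_log = pretrain(X, graph, config.train, n_clusters=n_clusters)
    class_index = {cl: i for i, cl in enumerate(classes)}
    idx = sorted(identified.assignments)
    y = [class_index[identified.assignments[i]] for i in idx]
    params, finetune_log = finetune(params, X, graph, idx, y, config.train)

    assignment = dynamic_cluster(
        params, X, graph, identified, K=n_clusters, seed=config.train.seed
    )
    # classifier outputs are class indices; report them as class names
    if assignment.method_used == "classifier":
        pred_labels = [classes[i] for i in assignment.labels]
    else:
        pred_labels = [f"cluster_{i}" for i in assignment.labels]
    embeddings = encode(X, graph, params)

    os.makedirs(config.out_dir, exist_ok=True)
    write_labels_csv(
        os.path.join(config.out_dir, "predicted_labels.csv"),
        dataset.spot_ids, pred_labels, method_used=assignment.method_used,
    )
    write_embeddings_csv(
        os.path.join(config.out_dir, "embeddings.csv"), dataset.spot_ids, embeddings
    )
    pretrain_log.to_csv(os.path.join(config.out_dir, "pretrain_log.csv"), index=False)
    finetune_log.to_csv(os.path.join(config.out_dir, "finetune_log.csv"), index=False)
    params.save(os.path.join(config.out_dir, "checkpoint.npz"))

    ari = None
    if dataset.truth_labels is not None:
        ari = adjusted_rand_index(dataset.truth_labels, pred_labels)
        pd.DataFrame(
            [{"metric": "ARI", "value": ari, "method_used": assignment.method_used,
              "p": identified.p}]
        ).to_csv(os.path.join(config.out_dir, "evaluation.csv"), index=False)
        logger.info("stage evaluate: ARI=%.3f (%s)", ari, assignment.method_used)

    return RunResult(assignment, embeddings, identified, finetune_log, ari)
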