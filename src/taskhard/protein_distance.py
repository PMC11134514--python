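"""Protein-space distances between source and target tasks.

Tasks are compared via their protein embedding vectors (mean-pooled residue
representations). Target tasks are single-protein by construction; a source
task may be a protein complex (several sequences), in which case the distance
is the maximum over complex members — the most pessimistic view of how far
the target protein sits from the complex.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np

from .featurizers import ProteinEmbedding
from .task_io import DistanceMatrix

logger = logging.getLogger(__name__)

Metric = Literal["euclidean", "cosine"]


def protein_pair_distance(u: np.ndarray, v: np.ndarray, metric: Metric = "euclidean") -> float:
    """Distance between two protein vectors: ||u-v|| or cosine distance in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("cosine distance undefined for zero vector")
        return float(1.0 - np.dot(u, v) / (nu * nv))
    raise ValueError(f"unknown metric {metric!r}")


def task_protein_distance(
    target: ProteinEmbedding, source: ProteinEmbedding, metric: Metric = "euclidean"
) -> float:
    """Distance from a single-protein target task to a (possibly complex) source task.

    For a source complex the largest member distance is returned.
    """
    if target.n_proteins != 1:
        raise ValueError(
            f"target task {target.task_id!r} must have exactly one protein "
            f"(has {target.n_proteins})"
        )
    if source.n_proteins == 0:
        raise ValueError(f"source task {source.task_id!r} has no proteins")
    t = target.vectors[0]
    return max(protein_pair_distance(t, s, metric) for s in source.vectors)


def prot_distance_matrix(
    sources: list[ProteinEmbedding],
    targets: list[ProteinEmbedding],
    metric: Metric = "euclidean",
) -> DistanceMatrix:
    """(n_sources x n_targets) matrix of task protein distances.

    All embeddings must come from the same embedder. Sources without any
    protein vector must be excluded by the caller (they are logged and
    rejected here).
    """
    embedders = {e.embedder_name for e in sources} | {e.embedder_name for e in targets}
    if len(embedders) > 1:
        raise ValueError(f"mixed protein embedders: {sorted(embedders)}")
    if not sources or not targets:
        raise ValueError("need at least one source and one target embedding")

    values = np.zeros((len(sources), len(targets)))
    for i, src in enumerate(sources):
        for j, tgt in enumerate(targets):
            values[i, j] = task_protein_distance(tgt, src, metric)
    return DistanceMatrix(
        source_ids=[s.task_id for s in sources],
        target_ids=[t.task_id for t in targets],
        values=values,
        space="prot",
        metadata={"embedder": next(iter(embedders)), "metric": metric},
    )
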