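"""Molecule and protein featurization.

Molecules are embedded either locally (``desc2d``: the full set of RDKit 2D
physico-chemical descriptors) or by loading a precomputed embedding matrix
(``loaded:<path>``), which is how pretrained representations (graph networks,
SMILES language models, 3D models) enter the pipeline. Proteins are embedded
by mean-pooling per-residue token vectors; the built-in embedder uses a
one-hot residue block plus a 2-mer count profile so the pipeline runs without
any model download, while pretrained protein language-model vectors are
loaded from file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .task_io import BioactivityTask

logger = logging.getLogger(__name__)

DESC2D = "desc2d"

#: 20 standard residues plus X (unknown), fixed order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class EmbeddedDataset:
    """Feature matrix plus binary labels for one task under one featurizer."""

    task_id: str
    features: np.ndarray
    labels: np.ndarray
    featurizer_name: str
    standardized: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n_molecules, d)")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("feature/label row counts differ")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"task {self.task_id!r}: non-finite feature entries")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass
class ProteinEmbedding:
    """One embedding vector per protein of a task (rows follow FASTA order)."""

    task_id: str
    vectors: np.ndarray
    embedder_name: str

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError(f"task {self.task_id!r}: non-finite protein embedding")

    @property
    def n_proteins(self) -> int:
        return self.vectors.shape[0]


def _desc2d_names() -> list[str]:
    return [name for name, _ in Descriptors._descList]


def desc2d_dim() -> int:
    """Descriptor count of the installed RDKit build."""
    return len(_desc2d_names())


def _desc2d_matrix(task: BioactivityTask) -> tuple[np.ndarray, np.ndarray]:
    names = _desc2d_names()
    rows, kept = [], []
    RDLogger.DisableLog("rdApp.*")
    try:
        for i, smi in enumerate(task.molecules):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                logger.warning("task %s: dropping unparseable SMILES at row %d", task.task_id, i)
                continue
            try:
                values = Descriptors.CalcMolDescriptors(mol)
            except Exception:  # descriptor failures drop the row, not the task
                logger.warning("task %s: descriptor failure at row %d", task.task_id, i)
                continue
            vec = np.array([values[n] for n in names], dtype=float)
            if not np.all(np.isfinite(vec)):
                logger.warning("task %s: non-finite descriptors at row %d; dropped", task.task_id, i)
                continue
            rows.append(vec)
            kept.append(i)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if not rows:
        raise ValueError(f"task {task.task_id!r}: no molecule could be featurized")
    return np.vstack(rows), task.labels[np.array(kept)]


def featurize_molecules(task: BioactivityTask, featurizer: str = DESC2D) -> EmbeddedDataset:
    """Embed a task's molecules.

    ``featurizer`` is ``"desc2d"`` for local 2D descriptors or
    ``"loaded:<path>"`` to pass through a precomputed matrix (see
    :func:`load_embeddings`). Rows whose descriptors cannot be computed are
    dropped together with their labels and logged.
    """
    if len(task) == 0:
        raise ValueError(f"task {task.task_id!r} is empty")
    if featurizer == DESC2D:
        features, labels = _desc2d_matrix(task)
        return EmbeddedDataset(task.task_id, features, labels, DESC2D)
    if featurizer.startswith("loaded:"):
        return load_embeddings(featurizer.split(":", 1)[1], task)
    raise ValueError(f"unknown featurizer {featurizer!r}")


def load_embeddings(path: str | Path, task: BioactivityTask) -> EmbeddedDataset:
    """Load a precomputed per-molecule embedding matrix for one task.

    Accepts ``.npy`` or CSV. A sidecar ``<path>.ids.txt`` (one SMILES per
    line) switches from positional to keyed matching; without it the matrix
    must have exactly one row per task molecule, in task order.
    """
    path = Path(path)
    if path.suffix == ".npy":
        matrix = np.load(path)
    else:
        matrix = pd.read_csv(path, header=None).to_numpy(dtype=float)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))

    ids_path = Path(f"{path}.ids.txt")
    if ids_path.is_file():
        keys = ids_path.read_text().splitlines()
        if len(keys) != matrix.shape[0]:
            raise ValueError(f"{ids_path}: {len(keys)} ids but {matrix.shape[0]} matrix rows")
        index = {k: i for i, k in enumerate(keys)}
        missing = [s for s in task.molecules if s not in index]
        if missing:
            raise ValueError(f"task {task.task_id!r}: no stored embedding for {missing[:5]}")
        matrix = matrix[[index[s] for s in task.molecules]]
    elif matrix.shape[0] != len(task):
        raise ValueError(
            f"task {task.task_id!r}: {len(task)} molecules but {matrix.shape[0]} embedding rows"
        )
    return EmbeddedDataset(task.task_id, matrix, task.labels, f"loaded:{path}")


@dataclass
class StandardizationStats:
    """Pooled per-dimension affine map: x -> (x - mean) / scale."""

    mean: np.ndarray
    scale: np.ndarray  # std with zero-variance dims mapped to scale 1 (output 0)
    featurizer_name: str


def standardize_features(
    datasets: list[EmbeddedDataset], stats: StandardizationStats | None = None
) -> tuple[list[EmbeddedDataset], StandardizationStats]:
    """Zero-mean unit-variance scaling pooled over all provided datasets.

    Zero-variance dimensions map to 0. Pass previously returned ``stats`` to
    apply the identical affine map to held-out data.
    """
    if not datasets:
        raise ValueError("no datasets given")
    names = {ds.featurizer_name for ds in datasets}
    if len(names) > 1:
        raise ValueError(f"mixed featurizers: {sorted(names)}")
    dims = {ds.dim for ds in datasets}
    if len(dims) > 1:
        raise ValueError(f"mixed dimensions: {sorted(dims)}")

    if stats is None:
        pooled = np.vstack([ds.features for ds in datasets])
        mean = pooled.mean(axis=0)
        std = pooled.std(axis=0)
        scale = np.where(std > 0, std, 1.0)
        centered_zero = std == 0
        stats = StandardizationStats(mean=mean, scale=scale, featurizer_name=next(iter(names)))
    else:
        if stats.featurizer_name != next(iter(names)):
            raise ValueError("stats computed under a different featurizer")
        centered_zero = None

    out = []
    for ds in datasets:
        z = (ds.features - stats.mean) / stats.scale
        if centered_zero is not None:
            z[:, centered_zero] = 0.0
        out.append(
            EmbeddedDataset(ds.task_id, z, ds.labels, ds.featurizer_name, standardized=True)
        )
    return out, stats


def _residue_token(residue: str) -> np.ndarray:
    vec = np.zeros(len(AMINO_ACIDS))
    vec[_AA_INDEX[residue]] = 1.0
    return vec


def embed_protein(sequence: str, embedder: str = "onehot-kmer") -> np.ndarray:
    """Embed one protein sequence as the mean over per-residue token vectors.

    The built-in ``onehot-kmer`` embedder represents each residue by its
    21-way one-hot and appends the sequence's normalized 2-mer count profile
    (441 dims), giving a deterministic 462-dim vector with no model download.
    Pretrained language-model embeddings enter via per-task files instead.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    sequence = sequence.upper()
    illegal = sorted({c for c in sequence if c not in _AA_INDEX})
    if illegal:
        raise ValueError(f"illegal residue characters {illegal}")
    if embedder != "onehot-kmer":
        raise ValueError(f"unknown embedder {embedder!r}; external embeddings are loaded from file")

    tokens = np.vstack([_residue_token(c) for c in sequence])
    composition = tokens.mean(axis=0)

    n_aa = len(AMINO_ACIDS)
    kmer = np.zeros(n_aa * n_aa)
    for a, b in zip(sequence[:-1], sequence[1:]):
        kmer[_AA_INDEX[a] * n_aa + _AA_INDEX[b]] += 1.0
    if len(sequence) > 1:
        kmer /= len(sequence) - 1
    return np.concatenate([composition, kmer])


def embed_task_proteins(task: BioactivityTask, embedder: str = "onehot-kmer") -> ProteinEmbedding:
    """Embed every protein of a task (errors if the task has none)."""
    if not task.proteins:
        raise ValueError(f"task {task.task_id!r} has no protein sequences")
    vectors = np.vstack([embed_protein(seq, embedder) for seq in task.proteins])
    return ProteinEmbedding(task.task_id, vectors, embedder)


def load_protein_embedding(path: str | Path, task_id: str, embedder_name: str = "loaded") -> ProteinEmbedding:
    """Load a stored per-protein embedding matrix (``.npy`` or CSV) for a task."""
    path = Path(path)
    if path.suffix == ".npy":
        matrix = np.load(path)
    else:
        matrix = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return ProteinEmbedding(task_id, matrix, embedder_name)
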