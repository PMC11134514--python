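"""On-disk task representation and matrix/report I/O.

A task lives in one directory::

    <task_id>/
        molecules.csv    # header: smiles,label   (label in {0,1}, 1=active)
        protein.fasta    # optional; >=1 records for protein complexes

Distance matrices are CSV files whose first column holds source task ids and
whose remaining columns are headed by target task ids, with a JSON metadata
sidecar (``<path>.meta.json``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

MOLECULE_FILE = "molecules.csv"
PROTEIN_FILE = "protein.fasta"


class TaskValidationError(ValueError):
    """A task directory or record failed validation."""


@dataclass
class BioactivityTask:
    """One bioactivity-prediction task: labeled molecules plus protein metadata.

    Parameters
    ----------
    task_id
        Unique identifier within a collection.
    molecules
        SMILES strings, order-preserving.
    labels
        Binary activity labels aligned with ``molecules`` (1 = active).
    proteins
        Zero or more amino-acid sequences (single-letter code). More than one
        sequence denotes a protein complex.
    role
        ``"source"`` (available for transfer) or ``"target"`` (task whose
        hardness is being quantified).
    """

    task_id: str
    molecules: list[str]
    labels: np.ndarray
    proteins: list[str] = field(default_factory=list)
    role: Literal["source", "target"] = "source"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.molecules):
            raise TaskValidationError(
                f"task {self.task_id!r}: {len(self.molecules)} molecules but {len(self.labels)} labels"
            )
        bad = np.flatnonzero(~np.isin(self.labels, (0, 1)))
        if bad.size:
            raise TaskValidationError(
                f"task {self.task_id!r}: labels must be 0/1; offending rows {bad.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())


def _validate_smiles(task_id: str, smiles: Sequence[str]) -> None:
    RDLogger.DisableLog("rdApp.*")
    try:
        bad = [(i, s) for i, s in enumerate(smiles) if Chem.MolFromSmiles(str(s)) is None]
    finally:
        RDLogger.EnableLog("rdApp.error")
    if bad:
        listing = ", ".join(f"row {i}: {s!r}" for i, s in bad[:20])
        raise TaskValidationError(f"task {task_id!r}: unparseable SMILES ({listing})")


def load_task(path: str | Path, role: Literal["source", "target"] = "source",
              validate_smiles: bool = True) -> BioactivityTask:
    """Load and validate one task directory.

    Molecule order follows the CSV; protein order follows the FASTA. A missing
    ``molecules.csv`` is a hard error; a missing ``protein.fasta`` yields an
    empty protein list (such a task cannot later enter protein-space
    distances as a target).
    """
    path = Path(path)
    mol_path = path / MOLECULE_FILE
    if not mol_path.is_file():
        raise TaskValidationError(f"{path}: missing {MOLECULE_FILE}")
    table = pd.read_csv(mol_path, dtype={"smiles": str})
    missing_cols = {"smiles", "label"} - set(table.columns)
    if missing_cols:
        raise TaskValidationError(f"{mol_path}: missing columns {sorted(missing_cols)}")

    task_id = path.name
    labels = pd.to_numeric(table["label"], errors="coerce")
    bad = labels.index[~labels.isin((0, 1))].tolist()
    if bad:
        raise TaskValidationError(f"task {task_id!r}: labels outside {{0,1}} at rows {bad}")

    smiles = table["smiles"].tolist()
    if validate_smiles:
        _validate_smiles(task_id, smiles)

    proteins: list[str] = []
    fasta = path / PROTEIN_FILE
    if fasta.is_file():
        proteins = [str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")]

    return BioactivityTask(
        task_id=task_id,
        molecules=smiles,
        labels=labels.to_numpy(dtype=int),
        proteins=proteins,
        role=role,
    )


def write_task(task: BioactivityTask, root: str | Path) -> Path:
    """Write a task to ``root/<task_id>/`` in the standard layout."""
    path = Path(root) / task.task_id
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"smiles": task.molecules, "label": task.labels}).to_csv(
        path / MOLECULE_FILE, index=False
    )
    if task.proteins:
        with open(path / PROTEIN_FILE, "w") as fh:
            for i, seq in enumerate(task.proteins):
                fh.write(f">{task.task_id}_P{i}\n{seq}\n")
    return path


@dataclass
class DistanceMatrix:
    """Source-by-target matrix of task distances.

    Rows index source tasks, columns index target tasks (the n_train x n_test
    convention). Entries are non-negative finite distances in either chemical
    (``space="chem"``) or protein (``space="prot"``) space.
    """

    source_ids: list[str]
    target_ids: list[str]
    values: np.ndarray
    space: Literal["chem", "prot"]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.source_ids or not self.target_ids:
            raise ValueError("DistanceMatrix requires non-empty source and target id lists")
        if self.values.shape != (len(self.source_ids), len(self.target_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"({len(self.source_ids)}, {len(self.target_ids)}) ids"
            )
        if len(set(self.source_ids)) != len(self.source_ids):
            raise ValueError("duplicate source ids")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance entries")
        if np.any(self.values < 0):
            raise ValueError("negative distance entries")
        if self.space not in ("chem", "prot"):
            raise ValueError(f"unknown space {self.space!r}")

    def column(self, target_id: str) -> np.ndarray:
        """Distance vector over sources for one target task."""
        return self.values[:, self.target_ids.index(target_id)]


def write_distance_matrix(m: DistanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(m.values, columns=m.target_ids)
    frame.insert(0, "source_task_id", m.source_ids)
    frame.to_csv(path, index=False)
    meta = dict(m.metadata)
    meta["space"] = m.space
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"source_task_id": str})
    if "source_task_id" not in frame.columns:
        raise ValueError(f"{path}: first column must be 'source_task_id'")
    meta_path = Path(f"{path}.meta.json")
    metadata: dict = {}
    if meta_path.is_file():
        with open(meta_path) as fh:
            metadata = json.load(fh)
    space = metadata.pop("space", "chem")
    return DistanceMatrix(
        source_ids=frame["source_task_id"].tolist(),
        target_ids=[str(c) for c in frame.columns[1:]],
        values=frame.iloc[:, 1:].to_numpy(dtype=float),
        space=space,
        metadata=metadata,
    )
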