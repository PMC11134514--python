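"""Hardness components and their combination.

EXT_CHEM: (difficulty-weighted) mean OTDD distance to the k nearest source
tasks. EXT_PROT: plain mean protein distance to the k nearest source tasks.
INT_CHEM: 1 - ROC-AUC of a single-task classifier trained on m_train samples
of the target task and validated on the remainder. Each component is min-max
normalized across the target collection of one run and combined as a
weighted sum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .featurizers import EmbeddedDataset
from .task_io import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class HardnessConfig:
    """Knobs of the hardness computation.

    ``k`` nearest source tasks feed the external components (default 10);
    EXT_CHEM uses source-difficulty weighting by default while EXT_PROT is
    always a plain mean; ``weights`` combine the normalized components
    (equal by default); INT_CHEM uses a random forest on ``m_train`` = 16
    stratified training samples unless configured otherwise.
    """

    k: int = 10
    ext_chem_weighting: Literal["weighted", "plain"] = "weighted"
    w_chem: float = 1.0
    w_prot: float = 1.0
    w_int: float = 1.0
    int_model: Literal["rf", "knn"] = "rf"
    m_train: int = 16
    split: Literal["stratified", "random", "scaffold"] = "stratified"
    n_estimators: int = 500
    knn_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if min(self.w_chem, self.w_prot, self.w_int) < 0:
            raise ValueError("component weights must be non-negative")
        if self.w_chem + self.w_prot + self.w_int == 0:
            raise ValueError("component weights must not all be zero")
        if self.m_train < 2:
            raise ValueError("m_train must be >= 2")


@dataclass
class HardnessReport:
    """Per-target hardness components (raw and normalized) plus the combined score."""

    table: pd.DataFrame  # index: target task id
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index_label="task_id")
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "HardnessReport":
        table = pd.read_csv(path, index_col="task_id")
        meta_path = Path(f"{path}.meta.json")
        provenance = {}
        if meta_path.is_file():
            with open(meta_path) as fh:
                provenance = json.load(fh)
        return cls(table=table, provenance=provenance)


def _classifier(cfg: HardnessConfig, seed: int):
    if cfg.int_model == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.n_estimators, class_weight="balanced", random_state=seed, n_jobs=1
        )
    if cfg.int_model == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_neighbors)
    raise ValueError(f"unknown internal model {cfg.int_model!r}")


def _scaffold_key(smiles: str) -> str:
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol) or ""


def _split_indices(
    labels: np.ndarray,
    m_train: int,
    split: str,
    seed: int,
    smiles: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    n = labels.size
    idx = np.arange(n)
    if split == "stratified":
        train, val = train_test_split(
            idx, train_size=m_train, random_state=seed, stratify=labels
        )
    elif split == "random":
        train, val = train_test_split(idx, train_size=m_train, random_state=seed)
    elif split == "scaffold":
        if smiles is None:
            raise ValueError("scaffold split requires SMILES strings")
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(smiles):
            groups.setdefault(_scaffold_key(s), []).append(i)
        # largest scaffolds go to train until m_train reached; ties by key
        ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        train_list: list[int] = []
        val_list: list[int] = []
        for _, members in ordered:
            (train_list if len(train_list) < m_train else val_list).extend(members)
        train, val = np.array(train_list), np.array(val_list)
    else:
        raise ValueError(f"unknown split {split!r}")
    return np.sort(train), np.sort(val)


def internal_hardness(
    ds: EmbeddedDataset,
    cfg: HardnessConfig | None = None,
    smiles: Sequence[str] | None = None,
) -> float:
    """1 - ROC-AUC of a few-sample single-task classifier on the task itself.

    The task is split into ``m_train`` training samples and a validation
    remainder (stratified by default). Splits that leave one side single-class
    are re-drawn up to 10 times before erroring. Deterministic under
    ``cfg.seed``.
    """
    cfg = cfg or HardnessConfig()
    y = ds.labels
    if len(np.unique(y)) < 2:
        raise ValueError(f"task {ds.task_id!r}: both classes required")
    if len(ds) < cfg.m_train + 2:
        raise ValueError(
            f"task {ds.task_id!r}: need >= m_train + 2 = {cfg.m_train + 2} molecules, have {len(ds)}"
        )

    for attempt in range(10):
        train, val = _split_indices(y, cfg.m_train, cfg.split, cfg.seed + attempt, smiles)
        if len(np.unique(y[train])) == 2 and len(np.unique(y[val])) == 2:
            break
        if cfg.split == "scaffold":  # deterministic split; re-drawing cannot help
            raise ValueError(f"task {ds.task_id!r}: scaffold split left a side single-class")
    else:
        raise ValueError(f"task {ds.task_id!r}: could not find a two-class split in 10 draws")

    clf = _classifier(cfg, cfg.seed)
    clf.fit(ds.features[train], y[train])
    scores = clf.predict_proba(ds.features[val])[:, list(clf.classes_).index(1)]
    return float(1.0 - roc_auc_score(y[val], scores))


def source_difficulty_weights(
    sources: list[EmbeddedDataset], cfg: HardnessConfig | None = None
) -> dict[str, float]:
    """Per-source difficulty = internal hardness with RF at m_train = 16.

    Sources failing the preconditions receive the mean weight of the
    successes (logged); if every source fails, an error is raised.
    """
    cfg = cfg or HardnessConfig()
    rf_cfg = HardnessConfig(
        k=cfg.k, int_model="rf", m_train=16, split=cfg.split,
        n_estimators=cfg.n_estimators, seed=cfg.seed,
    )
    weights: dict[str, float] = {}
    failed: list[str] = []
    for ds in sources:
        try:
            weights[ds.task_id] = internal_hardness(ds, rf_cfg)
        except ValueError as exc:
            logger.warning("source %s: difficulty weight failed (%s); using mean", ds.task_id, exc)
            failed.append(ds.task_id)
    if not weights:
        raise ValueError("no source yielded a difficulty weight")
    mean_w = float(np.mean(list(weights.values())))
    for task_id in failed:
        weights[task_id] = mean_w
    return weights


def knn_hardness(
    column: np.ndarray,
    k: int,
    weights: np.ndarray | None = None,
    source_ids: Sequence[str] | None = None,
) -> float:
    """(Weighted) mean distance over the k nearest sources in one matrix column.

    Ties in distance are broken by ascending source task id (positional index
    when ids are not given). Weights are renormalized within the selected
    neighborhood.
    """
    column = np.asarray(column, dtype=float)
    n = column.size
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} sources")
    ids = list(source_ids) if source_ids is not None else [f"{i:09d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("source_ids length mismatch")
    order = sorted(range(n), key=lambda i: (column[i], ids[i]))
    chosen = order[:k]
    if weights is None:
        return float(column[chosen].mean())
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError("weights must align with sources")
    if np.any(weights < 0):
        raise ValueError("negative weights")
    w = weights[chosen]
    if w.sum() == 0:
        return float(column[chosen].mean())
    return float(np.sum(w * column[chosen]) / w.sum())


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def compute_hardness(
    chem_dm: DistanceMatrix | None,
    prot_dm: DistanceMatrix | None,
    targets: list[EmbeddedDataset] | None,
    sources: list[EmbeddedDataset] | None,
    cfg: HardnessConfig | None = None,
    target_smiles: Mapping[str, Sequence[str]] | None = None,
) -> HardnessReport:
    """Combine EXT_CHEM, EXT_PROT and INT_CHEM into one hardness score per target.

    Components with zero weight are skipped entirely (their inputs may be
    None). Normalization is min-max across the target collection of this run,
    so reports from different runs are not directly comparable; the provenance
    snapshot records the configuration.
    """
    cfg = cfg or HardnessConfig()
    if cfg.w_chem > 0 and chem_dm is None:
        raise ValueError("chemical distance matrix required (w_chem > 0)")
    if cfg.w_prot > 0 and prot_dm is None:
        raise ValueError("protein distance matrix required (w_prot > 0)")
    if cfg.w_int > 0 and not targets:
        raise ValueError("target datasets required (w_int > 0)")

    target_ids: list[str] | None = None
    for dm in (chem_dm, prot_dm):
        if dm is not None:
            target_ids = dm.target_ids if target_ids is None else target_ids
    if target_ids is None and targets:
        target_ids = [t.task_id for t in targets]
    if target_ids is None:
        raise ValueError("no targets to score")

    columns: dict[str, np.ndarray] = {}

    if cfg.w_chem > 0:
        missing = [t for t in target_ids if t not in chem_dm.target_ids]
        if missing:
            raise ValueError(f"targets missing from chemical matrix: {missing}")
        weight_vec = None
        if cfg.ext_chem_weighting == "weighted":
            if not sources:
                raise ValueError("source datasets required for weighted EXT_CHEM")
            wmap = source_difficulty_weights(sources, cfg)
            missing_src = [s for s in chem_dm.source_ids if s not in wmap]
            if missing_src:
                raise ValueError(f"no difficulty weight for sources: {missing_src}")
            weight_vec = np.array([wmap[s] for s in chem_dm.source_ids])
        raw = np.array([
            knn_hardness(chem_dm.column(t), cfg.k, weight_vec, chem_dm.source_ids)
            for t in target_ids
        ])
        columns["ext_chem_raw"] = raw
        columns["ext_chem_norm"] = minmax_normalize(raw)

    if cfg.w_prot > 0:
        missing = [t for t in target_ids if t not in prot_dm.target_ids]
        if missing:
            raise ValueError(f"targets missing from protein matrix: {missing}")
        raw = np.array([
            knn_hardness(prot_dm.column(t), min(cfg.k, len(prot_dm.source_ids)),
                         None, prot_dm.source_ids)
            for t in target_ids
        ])
        columns["ext_prot_raw"] = raw
        columns["ext_prot_norm"] = minmax_normalize(raw)

    if cfg.w_int > 0:
        by_id = {t.task_id: t for t in targets}
        missing = [t for t in target_ids if t not in by_id]
        if missing:
            raise ValueError(f"target datasets missing for INT_CHEM: {missing}")
        raw = np.array([
            internal_hardness(
                by_id[t], cfg, target_smiles.get(t) if target_smiles else None
            )
            for t in target_ids
        ])
        columns["int_chem_raw"] = raw
        columns["int_chem_norm"] = minmax_normalize(raw)

    combined = np.zeros(len(target_ids))
    for name, w in (("ext_chem_norm", cfg.w_chem), ("ext_prot_norm", cfg.w_prot),
                    ("int_chem_norm", cfg.w_int)):
        if w > 0:
            combined = combined + w * columns[name]
    columns["combined"] = combined

    table = pd.DataFrame(columns, index=pd.Index(target_ids, name="task_id"))
    return HardnessReport(table=table, provenance={"config": asdict(cfg)})


def select_source_tasks(
    target_id: str,
    chem_dm: DistanceMatrix | None,
    prot_dm: DistanceMatrix | None,
    k: int,
    criterion: Literal["chem", "prot", "sum_norm"] = "sum_norm",
) -> list[str]:
    """Rank source tasks by relevance to one target and return the k best.

    ``sum_norm`` sums the two per-matrix min-max-normalized distance columns;
    ``chem``/``prot`` rank by a single matrix. Ties break by ascending source
    task id.
    """
    if criterion == "chem":
        if chem_dm is None:
            raise ValueError("chem criterion requires the chemical matrix")
        ids, score = chem_dm.source_ids, chem_dm.column(target_id)
    elif criterion == "prot":
        if prot_dm is None:
            raise ValueError("prot criterion requires the protein matrix")
        ids, score = prot_dm.source_ids, prot_dm.column(target_id)
    elif criterion == "sum_norm":
        if chem_dm is None or prot_dm is None:
            raise ValueError("sum_norm requires both matrices")
        if chem_dm.source_ids != prot_dm.source_ids:
            common = [s for s in chem_dm.source_ids if s in set(prot_dm.source_ids)]
            if not common:
                raise ValueError("matrices share no source tasks")
            chem_col = np.array([chem_dm.column(target_id)[chem_dm.source_ids.index(s)] for s in common])
            prot_col = np.array([prot_dm.column(target_id)[prot_dm.source_ids.index(s)] for s in common])
            ids = common
        else:
            ids = chem_dm.source_ids
            chem_col = chem_dm.column(target_id)
            prot_col = prot_dm.column(target_id)
        score = minmax_normalize(chem_col) + minmax_normalize(prot_col)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    if k < 1 or k > len(ids):
        raise ValueError(f"k={k} out of range for {len(ids)} sources")
    order = sorted(range(len(ids)), key=lambda i: (score[i], ids[i]))
    return [ids[i] for i in order[:k]]
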