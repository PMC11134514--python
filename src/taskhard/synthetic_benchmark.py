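"""Synthetic task universes with planted inter-task relatedness.

Every stage of the pipeline (OTDD, protein distance, hardness, prototypical
network) is testable on universes produced here, with no external data. Each
task draws molecule feature vectors from a task-specific Gaussian mixture
around a chemistry anchor, labels them by a task-specific linear rule with a
controllable flip probability, and carries a protein vector near a protein
anchor.

Relatedness is planted per target: a target with relatedness ``rho`` shares
its chemistry anchor, protein anchor, and (up to a perturbation scaled by
``1 - rho``) its label rule with ``ceil(rho * 10)`` designated source tasks.
Targets with the same ``rho`` level form one "family" so the designated
sources fit inside a 50-source universe. A target with ``rho = 0`` shares
nothing with any source. Recovery of ``rho`` by the hardness components, and
the anti-correlation between hardness and meta-learning gain, are the
acceptance surface.

Feature matrices are carried directly (the loaded-embedding path); molecule
records are synthetic SMILES surrogates (linear alkanes) that exist only to
satisfy the task file contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats

from .featurizers import EmbeddedDataset, ProteinEmbedding
from .hardness import HardnessReport
from .protonet import EvalRecord, hardness_gain_correlation
from .task_io import BioactivityTask

#: distinct relatedness levels of the default 20-target universe
DEFAULT_RHO_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class UniverseConfig:
    """Shape and noise of a synthetic task universe.

    The defaults are the desk-scale study conditions: 50 source and 20
    target tasks, 16-dim molecule features, 32-dim protein vectors, 200
    molecules per task, relatedness levels {0, 0.25, 0.5, 0.75, 1} with four
    targets each, and a 5% label-flip probability (a realistic assay noise
    floor).
    """

    n_sources: int = 50
    n_targets: int = 20
    chem_dim: int = 16
    prot_dim: int = 32
    n_molecules: int = 200
    label_noise: float = 0.05
    relatedness: tuple[float, ...] | None = None  # per-target rho; default: tiled levels
    n_clusters: int = 4
    anchor_scale: float = 4.0
    cluster_spread: float = 1.5
    within_cluster_std: float = 1.0
    rule_jitter: float = 0.15
    prot_anchor_scale: float = 3.0
    prot_jitter: float = 0.2
    seed: int = 7

    def __post_init__(self) -> None:
        if self.chem_dim < 2 or self.prot_dim < 2:
            raise ValueError("dimensions must be >= 2")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")
        if self.relatedness is None:
            reps = math.ceil(self.n_targets / len(DEFAULT_RHO_LEVELS))
            self.relatedness = tuple(
                (DEFAULT_RHO_LEVELS * reps)[: self.n_targets]
            )
        if len(self.relatedness) != self.n_targets:
            raise ValueError("relatedness must have one entry per target")
        if any(not 0.0 <= r <= 1.0 for r in self.relatedness):
            raise ValueError("relatedness values must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of a universe: per-target rho, anchor id, related sources."""

    rho: dict[str, float]
    anchor_id: dict[str, str]
    related_sources: dict[str, list[str]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {"rho": self.rho, "anchor_id": self.anchor_id,
                 "related_sources": self.related_sources},
                fh, indent=2,
            )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(rho=raw["rho"], anchor_id=raw["anchor_id"],
                   related_sources=raw["related_sources"])


@dataclass
class Universe:
    """A generated task universe: tasks, feature/protein matrices, truth."""

    sources: list[BioactivityTask]
    targets: list[BioactivityTask]
    datasets: dict[str, EmbeddedDataset]
    protein_embeddings: dict[str, ProteinEmbedding]
    truth: PlantedTruth
    config: UniverseConfig

    @property
    def source_datasets(self) -> list[EmbeddedDataset]:
        return [self.datasets[t.task_id] for t in self.sources]

    @property
    def target_datasets(self) -> list[EmbeddedDataset]:
        return [self.datasets[t.task_id] for t in self.targets]


def _surrogate_smiles(n: int) -> list[str]:
    # valid linear alkanes; placeholders only — features come from the
    # loaded-embedding path, never from these strings
    return ["C" * (1 + i % 30) for i in range(n)]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sample_task_data(
    rng: np.random.Generator,
    cfg: UniverseConfig,
    anchor: np.ndarray,
    rule: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    centers = anchor + rng.normal(0.0, cfg.cluster_spread, size=(cfg.n_clusters, cfg.chem_dim))
    assignment = rng.integers(cfg.n_clusters, size=cfg.n_molecules)
    x = centers[assignment] + rng.normal(
        0.0, cfg.within_cluster_std, size=(cfg.n_molecules, cfg.chem_dim)
    )
    projection = (x - anchor) @ rule
    y = (projection > np.median(projection)).astype(int)
    flips = rng.random(cfg.n_molecules) < cfg.label_noise
    y = np.where(flips, 1 - y, y)
    return x, y


def generate_universe(cfg: UniverseConfig | None = None) -> Universe:
    """Generate a seeded universe of source and target tasks with planted truth.

    Deterministic: identical config (including seed) yields a bit-identical
    universe. Raises if the designated related sources across all relatedness
    levels would exceed ``n_sources``.
    """
    cfg = cfg or UniverseConfig()
    rng = np.random.default_rng(cfg.seed)

    levels = sorted({r for r in cfg.relatedness if r > 0})
    need = sum(math.ceil(r * 10) for r in levels)
    if need > cfg.n_sources:
        raise ValueError(
            f"infeasible config: {need} designated related sources exceed n_sources={cfg.n_sources}"
        )

    # one family (anchors + rule direction) per positive relatedness level
    family: dict[float, dict] = {}
    for r in levels:
        family[r] = {
            "name": f"family_rho{r:g}",
            "anchor": rng.normal(0.0, cfg.anchor_scale, size=cfg.chem_dim),
            "rule": _unit(rng.normal(size=cfg.chem_dim)),
            "prot": rng.normal(0.0, cfg.prot_anchor_scale, size=cfg.prot_dim),
            "sources": [],
        }

    datasets: dict[str, EmbeddedDataset] = {}
    prot_embs: dict[str, ProteinEmbedding] = {}
    sources: list[BioactivityTask] = []

    def make_task(task_id: str, role: str, anchor, rule, prot_anchor) -> BioactivityTask:
        x, y = _sample_task_data(rng, cfg, anchor, rule)
        task = BioactivityTask(task_id, _surrogate_smiles(cfg.n_molecules), y, [], role)
        datasets[task_id] = EmbeddedDataset(task_id, x, y, "synthetic")
        prot_vec = prot_anchor + rng.normal(0.0, cfg.prot_jitter, size=cfg.prot_dim)
        prot_embs[task_id] = ProteinEmbedding(task_id, prot_vec[None, :], "synthetic")
        return task

    source_idx = 0
    for r in levels:
        fam = family[r]
        for _ in range(math.ceil(r * 10)):
            task_id = f"src{source_idx:03d}"
            rule = _unit(fam["rule"] + cfg.rule_jitter * rng.normal(size=cfg.chem_dim))
            sources.append(make_task(task_id, "source", fam["anchor"], rule, fam["prot"]))
            fam["sources"].append(task_id)
            source_idx += 1
    while source_idx < cfg.n_sources:
        task_id = f"src{source_idx:03d}"
        anchor = rng.normal(0.0, cfg.anchor_scale, size=cfg.chem_dim)
        rule = _unit(rng.normal(size=cfg.chem_dim))
        prot = rng.normal(0.0, cfg.prot_anchor_scale, size=cfg.prot_dim)
        sources.append(make_task(task_id, "source", anchor, rule, prot))
        source_idx += 1

    targets: list[BioactivityTask] = []
    rho_map: dict[str, float] = {}
    anchor_map: dict[str, str] = {}
    related_map: dict[str, list[str]] = {}
    for j, r in enumerate(cfg.relatedness):
        task_id = f"tgt{j:03d}"
        if r > 0:
            fam = family[r]
            # convex interpolation between the family rule and a random
            # direction: perturbation weight scales with 1 - rho
            rule = _unit(r * fam["rule"] + (1.0 - r) * _unit(rng.normal(size=cfg.chem_dim)))
            targets.append(make_task(task_id, "target", fam["anchor"], rule, fam["prot"]))
            anchor_map[task_id] = fam["name"]
            related_map[task_id] = list(fam["sources"])
        else:
            anchor = rng.normal(0.0, cfg.anchor_scale, size=cfg.chem_dim)
            rule = _unit(rng.normal(size=cfg.chem_dim))
            prot = rng.normal(0.0, cfg.prot_anchor_scale, size=cfg.prot_dim)
            targets.append(make_task(task_id, "target", anchor, rule, prot))
            anchor_map[task_id] = f"isolated_{task_id}"
            related_map[task_id] = []
        rho_map[task_id] = float(r)

    truth = PlantedTruth(rho=rho_map, anchor_id=anchor_map, related_sources=related_map)
    return Universe(sources, targets, datasets, prot_embs, truth, cfg)


def write_universe(universe: Universe, out_dir: str | Path) -> Path:
    """Write a universe to disk: task dirs, feature/protein CSVs, truth.json."""
    from .task_io import write_task

    out_dir = Path(out_dir)
    for group, tasks in (("sources", universe.sources), ("targets", universe.targets)):
        root = out_dir / group
        root.mkdir(parents=True, exist_ok=True)
        for task in tasks:
            task_dir = write_task(task, root)
            ds = universe.datasets[task.task_id]
            np.savetxt(task_dir / "features.csv", ds.features, delimiter=",")
            np.savetxt(
                task_dir / "protein_embedding.csv",
                universe.protein_embeddings[task.task_id].vectors,
                delimiter=",",
            )
    universe.truth.to_json(out_dir / "truth.json")
    return out_dir


def load_universe(out_dir: str | Path, config: UniverseConfig | None = None) -> Universe:
    """Load a universe previously written by :func:`write_universe`."""
    from .task_io import load_task

    out_dir = Path(out_dir)
    datasets: dict[str, EmbeddedDataset] = {}
    prot_embs: dict[str, ProteinEmbedding] = {}
    groups: dict[str, list[BioactivityTask]] = {}
    for group, role in (("sources", "source"), ("targets", "target")):
        tasks = []
        root = out_dir / group
        for task_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            task = load_task(task_dir, role=role, validate_smiles=False)
            features = np.loadtxt(task_dir / "features.csv", delimiter=",", ndmin=2)
            datasets[task.task_id] = EmbeddedDataset(
                task.task_id, features, task.labels, "synthetic"
            )
            prot_embs[task.task_id] = ProteinEmbedding(
                task.task_id,
                np.loadtxt(task_dir / "protein_embedding.csv", delimiter=",", ndmin=2),
                "synthetic",
            )
            tasks.append(task)
        groups[group] = tasks
    truth = PlantedTruth.from_json(out_dir / "truth.json")
    return Universe(groups["sources"], groups["targets"], datasets, prot_embs,
                    truth, config or UniverseConfig())


def selection_benefit(
    universe: Universe,
    chem_dm,
    prot_dm,
    n_select: int = 10,
    n_random_seeds: int = 5,
    support_size: int = 16,
    n_eval_seeds: int = 8,
    n_encoders: int = 3,
    encoder_cfg=None,
    seed: int = 0,
) -> dict:
    """Rational vs random source selection for prototypical-network training.

    For every target task, one prototypical network is trained on the
    ``n_select`` most relevant sources (ranked by the summed normalized
    chemical and protein distances) and compared, by query ROC-AUC on the
    target, against networks trained on ``n_random_seeds`` random source
    draws of the same size. Returns per-target mean ROC-AUCs and the fraction
    of targets where rational selection is at least as good.
    """
    from .featurizers import standardize_features
    from .hardness import select_source_tasks
    from .protonet import EncoderConfig, evaluate_task_ensemble, train_protonet

    encoder_cfg = encoder_cfg or EncoderConfig(episodes=400)
    rng = np.random.default_rng(seed)
    src_std, stats = standardize_features(universe.source_datasets)
    tgt_std, _ = standardize_features(universe.target_datasets, stats)
    by_id = {ds.task_id: ds for ds in src_std}
    all_ids = [s.task_id for s in universe.sources]

    def arm_roc_auc(source_ids: list[str], target_ds) -> float:
        encoders = [
            train_protonet([by_id[s] for s in source_ids], encoder_cfg, seed=seed + i)
            for i in range(n_encoders)
        ]
        return evaluate_task_ensemble(
            encoders, target_ds, support_size, n_eval_seeds, seed=seed + 500
        ).roc_auc

    rows = []
    for ds_std in tgt_std:
        tid = ds_std.task_id
        rational_ids = select_source_tasks(tid, chem_dm, prot_dm, n_select, "sum_norm")
        rational = arm_roc_auc(rational_ids, ds_std)

        random_aucs = []
        for _ in range(n_random_seeds):
            picked = list(rng.choice(all_ids, size=n_select, replace=False))
            random_aucs.append(arm_roc_auc(picked, ds_std))
        rows.append({
            "task_id": tid,
            "rho": universe.truth.rho.get(tid),
            "rational_roc_auc": rational,
            "random_roc_auc": float(np.mean(random_aucs)),
        })
    wins = [r["rational_roc_auc"] >= r["random_roc_auc"] for r in rows]
    return {
        "per_target": rows,
        "win_fraction": float(np.mean(wins)),
        "mean_rational_roc_auc": float(np.mean([r["rational_roc_auc"] for r in rows])),
        "mean_random_roc_auc": float(np.mean([r["random_roc_auc"] for r in rows])),
    }


def recovery_report(
    universe: Universe,
    report: HardnessReport,
    meta_records: list[EvalRecord],
    baseline_records: list[EvalRecord],
    n_shuffles: int = 20,
    shuffle_seed: int = 0,
    thresholds: dict | None = None,
) -> dict:
    """Check that planted relatedness is recovered by the hardness pipeline.

    Computes Pearson/Spearman correlations between planted rho and each
    hardness component, the correlation between combined hardness and the
    meta-learning gain (ΔAUPRC), and a permutation negative control: the mean
    absolute Pearson correlation between shuffled rho and EXT_CHEM over
    ``n_shuffles`` seeded permutations.
    """
    thresholds = thresholds or {
        "rho_ext_chem_max": -0.7,
        "hardness_gain_max": -0.5,
        "shuffle_abs_max": 0.3,
    }
    ids = [t for t in report.table.index if t in universe.truth.rho]
    if len(ids) < 3:
        raise ValueError("need >= 3 targets present in both truth and report")
    rho = np.array([universe.truth.rho[t] for t in ids])
    if np.std(rho) == 0:
        raise ValueError("degenerate rho variance")

    out: dict = {"n_targets": len(ids), "thresholds": thresholds}
    for component in ("ext_chem_raw", "ext_prot_raw", "int_chem_raw", "combined"):
        if component not in report.table.columns:
            continue
        values = report.table.loc[ids, component].to_numpy(dtype=float)
        if np.std(values) == 0:
            out[f"pearson_rho_{component}"] = float("nan")
            continue
        out[f"pearson_rho_{component}"] = float(sp_stats.pearsonr(rho, values).statistic)
        out[f"spearman_rho_{component}"] = float(sp_stats.spearmanr(rho, values).statistic)

    corr = hardness_gain_correlation(report, meta_records, baseline_records, metric="auprc")
    out["pearson_hardness_gain"] = corr["pearson_gain"]
    out["spearman_hardness_gain"] = corr["spearman_gain"]
    out["pearson_hardness_absolute"] = corr["pearson_absolute"]

    ext_chem = report.table.loc[ids, "ext_chem_raw"].to_numpy(dtype=float)
    rng = np.random.default_rng(shuffle_seed)
    shuffled = [
        abs(float(sp_stats.pearsonr(rng.permutation(rho), ext_chem).statistic))
        for _ in range(n_shuffles)
    ]
    out["shuffled_rho_mean_abs_corr"] = float(np.mean(shuffled))

    out["pass_rho_ext_chem"] = out["pearson_rho_ext_chem_raw"] <= thresholds["rho_ext_chem_max"]
    out["pass_hardness_gain"] = out["pearson_hardness_gain"] <= thresholds["hardness_gain_max"]
    out["pass_shuffle_control"] = out["shuffled_rho_mean_abs_corr"] <= thresholds["shuffle_abs_max"]
    return out
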