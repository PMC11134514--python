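"""Prototypical network and single-task baselines for few-shot evaluation.

The prototypical network classifies query molecules by softmax over negative
squared Euclidean distances to class prototypes (class means of the encoded
support set). The encoder is a small feed-forward network trained
episodically on the source tasks; with an identity encoder the model reduces
to nearest-class-centroid classification in raw feature space.

Evaluation compares the prototypical network against single-task baselines
(random forest, kNN fit on the support set only); the per-task performance
gain is what the hardness score is validated against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sp_stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .featurizers import EmbeddedDataset
from .hardness import HardnessConfig, HardnessReport, _classifier

logger = logging.getLogger(__name__)


@dataclass
class Episode:
    """Support/query split of one task for few-shot evaluation."""

    task_id: str
    support_features: np.ndarray
    support_labels: np.ndarray
    query_features: np.ndarray
    query_labels: np.ndarray
    support_size: int
    seed: int


@dataclass
class PrototypeSet:
    """Class prototypes (mean encoded support vectors) with class counts."""

    prototypes: dict[int, np.ndarray]
    counts: dict[int, int]

    @property
    def classes(self) -> list[int]:
        return sorted(self.prototypes)


@dataclass
class EvalRecord:
    """Seed-averaged few-shot performance of one method on one task."""

    task_id: str
    method: Literal["protonet", "rf", "knn"]
    support_size: int
    roc_auc: float
    auprc: float
    seed: int
    n_seeds: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.roc_auc <= 1.0 and 0.0 <= self.auprc <= 1.0):
            raise ValueError("metrics must lie in [0, 1]")


@dataclass
class EncoderConfig:
    """Feed-forward encoder and episodic-training settings.

    ``hidden=()`` with ``identity=True`` gives the parameter-free identity
    encoder (prototypes in raw feature space). The bottleneck output keeps
    the representation compact so episodic training concentrates on
    directions that are informative across source tasks.
    """

    hidden: tuple[int, ...] = (128, 128)
    out_dim: int = 8
    identity: bool = False
    episodes: int = 1000
    lr: float = 3e-3
    support_size: int = 16
    query_size: int = 64


class MLPEncoder:
    """ReLU MLP encoder with manual backprop (linear final layer)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator | None = None):
        self.dims = list(dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        rng = rng or np.random.default_rng(0)
        for fan_in, fan_out in zip(self.dims[:-1], self.dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def is_identity(self) -> bool:
        return not self.weights

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return encoding plus per-layer activations (for backprop)."""
        activations = [np.asarray(x, dtype=float)]
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            pre = activations[-1] @ w + b
            if layer < len(self.weights) - 1:
                pre = np.maximum(pre, 0.0)
            activations.append(pre)
        return activations[-1], activations

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, activations: list[np.ndarray], grad_out: np.ndarray):
        """Gradients of the loss w.r.t. weights/biases given d(loss)/d(encoding)."""
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        delta = grad_out
        for layer in reversed(range(len(self.weights))):
            grads_w[layer] = activations[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (activations[layer] > 0)
        return grads_w, grads_b


def build_episode(ds: EmbeddedDataset, support_size: int, seed: int) -> Episode:
    """Stratified support draw of ``support_size`` molecules; the rest is query.

    Re-draws with incremented seeds (up to 10) if a side misses a class.
    Reproducible: the same seed yields the identical episode.
    """
    y = ds.labels
    if len(ds) < support_size + 2:
        raise ValueError(
            f"task {ds.task_id!r}: need >= support_size + 2 = {support_size + 2} molecules"
        )
    if len(np.unique(y)) < 2:
        raise ValueError(f"task {ds.task_id!r}: both classes required")
    idx = np.arange(len(ds))
    for attempt in range(10):
        support, query = train_test_split(
            idx, train_size=support_size, random_state=seed + attempt, stratify=y
        )
        if len(np.unique(y[support])) == 2:
            support, query = np.sort(support), np.sort(query)
            return Episode(
                task_id=ds.task_id,
                support_features=ds.features[support],
                support_labels=y[support],
                query_features=ds.features[query],
                query_labels=y[query],
                support_size=support_size,
                seed=seed,
            )
    raise ValueError(f"task {ds.task_id!r}: no two-class support draw in 10 attempts")


def compute_prototypes(embedded_support: np.ndarray, labels: np.ndarray) -> PrototypeSet:
    """Class-mean prototypes in encoder output space."""
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes required in the support set")
    prototypes, counts = {}, {}
    for k in classes:
        members = embedded_support[labels == k]
        if members.shape[0] == 0:
            raise ValueError(f"empty class {k}")
        prototypes[int(k)] = members.mean(axis=0)
        counts[int(k)] = int(members.shape[0])
    return PrototypeSet(prototypes=prototypes, counts=counts)


def classify_query(embedded_query: np.ndarray, prototypes: PrototypeSet) -> np.ndarray:
    """Class probabilities: softmax over negative squared distances to prototypes.

    Columns follow ``prototypes.classes`` (ascending class label); rows sum
    to 1.
    """
    embedded_query = np.atleast_2d(np.asarray(embedded_query, dtype=float))
    classes = prototypes.classes
    if len(classes) < 2:
        raise ValueError("need at least two prototypes")
    proto = np.vstack([prototypes.prototypes[k] for k in classes])
    if proto.shape[1] != embedded_query.shape[1]:
        raise ValueError("query/prototype dimension mismatch")
    d2 = ((embedded_query[:, None, :] - proto[None, :, :]) ** 2).sum(axis=2)
    logits = -d2
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def _episode_loss_grad(encoder: MLPEncoder, episode: Episode):
    """Cross-entropy of query classification and its parameter gradients."""
    x = np.vstack([episode.support_features, episode.query_features])
    z, activations = encoder.forward(x)
    s = episode.support_features.shape[0]
    z_s, z_q = z[:s], z[s:]
    y_s, y_q = episode.support_labels, episode.query_labels

    classes = sorted(np.unique(y_s).tolist())
    masks = [y_s == k for k in classes]
    proto = np.vstack([z_s[m].mean(axis=0) for m in masks])
    d2 = ((z_q[:, None, :] - proto[None, :, :]) ** 2).sum(axis=2)
    logits = -d2
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_p = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    y_idx = np.array([classes.index(k) for k in y_q])
    q = len(y_q)
    loss = float(-log_p[np.arange(q), y_idx].mean())

    g_logits = (np.exp(log_p) - np.eye(len(classes))[y_idx]) / q
    grad_zq = 2.0 * g_logits @ proto - 2.0 * g_logits.sum(axis=1, keepdims=True) * z_q
    grad_proto = 2.0 * g_logits.T @ z_q - 2.0 * g_logits.sum(axis=0)[:, None] * proto
    grad_zs = np.zeros_like(z_s)
    for ci, m in enumerate(masks):
        grad_zs[m] = grad_proto[ci] / m.sum()

    grad_z = np.vstack([grad_zs, grad_zq])
    grads_w, grads_b = encoder.backward(activations, grad_z)
    return loss, grads_w, grads_b


def train_protonet(
    source_datasets: list[EmbeddedDataset],
    cfg: EncoderConfig | None = None,
    seed: int = 0,
) -> MLPEncoder:
    """Episodically train the encoder on the source tasks (Adam, seeded).

    Each step samples one source task, draws a support/query episode, and
    minimizes the cross-entropy of prototype-softmax query classification.
    With ``cfg.identity`` (or zero episodes and no hidden layers) the
    returned encoder is the identity map.
    """
    cfg = cfg or EncoderConfig()
    if cfg.identity:
        return MLPEncoder([])
    if len(source_datasets) < 2:
        raise ValueError("need at least two source tasks for episodic training")
    d = source_datasets[0].dim
    rng = np.random.default_rng(seed)
    encoder = MLPEncoder([d, *cfg.hidden, cfg.out_dim], rng)

    usable = [
        ds for ds in source_datasets
        if len(ds) >= cfg.support_size + 2 and len(np.unique(ds.labels)) == 2
    ]
    if len(usable) < 2:
        raise ValueError("need at least two source tasks large enough for episodes")

    m_w = [np.zeros_like(w) for w in encoder.weights]
    v_w = [np.zeros_like(w) for w in encoder.weights]
    m_b = [np.zeros_like(b) for b in encoder.biases]
    v_b = [np.zeros_like(b) for b in encoder.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for step in range(1, cfg.episodes + 1):
        ds = usable[rng.integers(len(usable))]
        episode = build_episode(ds, cfg.support_size, seed=int(rng.integers(2**31 - 1)))
        if episode.query_features.shape[0] > cfg.query_size:
            pick = rng.choice(episode.query_features.shape[0], cfg.query_size, replace=False)
            episode.query_features = episode.query_features[pick]
            episode.query_labels = episode.query_labels[pick]
        if len(np.unique(episode.query_labels)) < 2:
            continue
        loss, grads_w, grads_b = _episode_loss_grad(encoder, episode)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite episode loss at step {step} on task {ds.task_id!r}"
            )
        for i in range(len(encoder.weights)):
            m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
            v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
            m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
            v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
            mw_hat = m_w[i] / (1 - beta1**step)
            vw_hat = v_w[i] / (1 - beta2**step)
            mb_hat = m_b[i] / (1 - beta1**step)
            vb_hat = v_b[i] / (1 - beta2**step)
            encoder.weights[i] -= cfg.lr * mw_hat / (np.sqrt(vw_hat) + eps)
            encoder.biases[i] -= cfg.lr * mb_hat / (np.sqrt(vb_hat) + eps)
    return encoder


def _score_episode(
    method: str, episode: Episode, encoder: MLPEncoder | None, seed: int,
    rf_estimators: int, knn_neighbors: int,
) -> np.ndarray:
    if method == "protonet":
        if encoder is None:
            raise ValueError("protonet evaluation requires an encoder")
        z_s = encoder.encode(episode.support_features)
        z_q = encoder.encode(episode.query_features)
        protos = compute_prototypes(z_s, episode.support_labels)
        return classify_query(z_q, protos)[:, protos.classes.index(1)]
    if method in ("rf", "knn"):
        cfg = HardnessConfig(
            int_model=method, n_estimators=rf_estimators, knn_neighbors=knn_neighbors,
            m_train=max(episode.support_size, 2), seed=seed,
        )
        clf = _classifier(cfg, seed)
        clf.fit(episode.support_features, episode.support_labels)
        return clf.predict_proba(episode.query_features)[:, list(clf.classes_).index(1)]
    raise ValueError(f"unknown method {method!r}")


def evaluate_task(
    method: Literal["protonet", "rf", "knn"],
    ds: EmbeddedDataset,
    support_size: int,
    n_seeds: int = 5,
    encoder: MLPEncoder | None = None,
    seed: int = 0,
    rf_estimators: int = 500,
    knn_neighbors: int = 5,
) -> EvalRecord:
    """Seed-averaged ROC-AUC / AUPRC of one method on one task's query sets.

    Episode draws use seeds ``seed .. seed + n_seeds - 1``; draws whose query
    set is single-class are skipped and logged.
    """
    aucs, aps = [], []
    for s in range(seed, seed + n_seeds):
        episode = build_episode(ds, support_size, s)
        if len(np.unique(episode.query_labels)) < 2:
            logger.warning("task %s seed %d: single-class query; skipped", ds.task_id, s)
            continue
        scores = _score_episode(method, episode, encoder, s, rf_estimators, knn_neighbors)
        aucs.append(roc_auc_score(episode.query_labels, scores))
        aps.append(average_precision_score(episode.query_labels, scores))
    if not aucs:
        raise ValueError(f"task {ds.task_id!r}: no usable episode")
    return EvalRecord(
        task_id=ds.task_id,
        method=method,
        support_size=support_size,
        roc_auc=float(np.mean(aucs)),
        auprc=float(np.mean(aps)),
        seed=seed,
        n_seeds=len(aucs),
    )


def evaluate_task_ensemble(
    encoders: list[MLPEncoder],
    ds: EmbeddedDataset,
    support_size: int,
    n_seeds: int = 5,
    seed: int = 0,
) -> EvalRecord:
    """Protonet evaluation averaged over independently trained encoders.

    Episodic training of a small encoder has run-to-run variance; averaging
    the metrics of a few independently seeded encoders gives a stabler
    estimate of the meta-learner's per-task performance.
    """
    if not encoders:
        raise ValueError("need at least one encoder")
    records = [
        evaluate_task("protonet", ds, support_size, n_seeds, encoder=e, seed=seed)
        for e in encoders
    ]
    return EvalRecord(
        task_id=ds.task_id,
        method="protonet",
        support_size=support_size,
        roc_auc=float(np.mean([r.roc_auc for r in records])),
        auprc=float(np.mean([r.auprc for r in records])),
        seed=seed,
        n_seeds=sum(r.n_seeds for r in records),
    )


def hardness_gain_correlation(
    report: HardnessReport,
    meta_records: list[EvalRecord],
    baseline_records: list[EvalRecord],
    metric: Literal["auprc", "roc_auc"] = "auprc",
) -> dict:
    """Correlate combined hardness with the meta-learning gain per target.

    Gain = meta-learner metric - baseline metric on the same task. Returns
    Pearson and Spearman coefficients for the gain and for the absolute
    meta-learner metric, plus the aligned vectors for plotting.
    """
    meta = {r.task_id: getattr(r, metric) for r in meta_records}
    base = {r.task_id: getattr(r, metric) for r in baseline_records}
    ids = [t for t in report.table.index if t in meta and t in base]
    if len(ids) < 3:
        raise ValueError("need >= 3 targets with both hardness and evaluations")
    hardness = report.table.loc[ids, "combined"].to_numpy(dtype=float)
    gain = np.array([meta[t] - base[t] for t in ids])
    absolute = np.array([meta[t] for t in ids])
    if np.std(hardness) == 0 or np.std(gain) == 0:
        raise ValueError("zero variance in hardness or gain")
    pearson_gain = sp_stats.pearsonr(hardness, gain)
    spearman_gain = sp_stats.spearmanr(hardness, gain)
    pearson_abs = sp_stats.pearsonr(hardness, absolute)
    return {
        "metric": metric,
        "task_ids": ids,
        "hardness": hardness,
        "gain": gain,
        "absolute": absolute,
        "pearson_gain": float(pearson_gain.statistic),
        "spearman_gain": float(spearman_gain.statistic),
        "pearson_absolute": float(pearson_abs.statistic),
    }
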