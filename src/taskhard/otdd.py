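"""Optimal transport dataset distance (OTDD) between labeled molecule sets.

The distance between two labeled datasets D_A = {(x_i, y_i)} and
D_B = {(x'_j, y'_j)} is the optimal-transport cost under the feature-label
ground metric

    d((x, y), (x', y'))^2 = ||x - x'||^2 + W2(alpha_y, alpha_{y'})^2,

where alpha_y is the distribution of features carrying label y in its own
dataset, modeled as a Gaussian so the 2-Wasserstein label term has the
Bures closed form in the class means and covariances. The reported distance
is the square root of the optimal cost (p = 2 throughout).

Two discrete OT solvers are provided: an exact one (Hungarian assignment for
uniform square marginals, where an optimal vertex of the Birkhoff polytope
is a permutation; a HiGHS linear program otherwise) and log-domain Sinkhorn
for entropic regularization on larger instances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from scipy import optimize
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .featurizers import EmbeddedDataset
from .task_io import DistanceMatrix

logger = logging.getLogger(__name__)

_ABS_COV_FLOOR = 1e-8


@dataclass
class GaussianLabelModel:
    """Gaussian model of the feature distribution of one label class."""

    label: int
    mean: np.ndarray
    covariance: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean dimension")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class TransportPlan:
    """Discrete OT coupling with its linear cost (no entropy term)."""

    plan: np.ndarray
    cost: float
    a: np.ndarray
    b: np.ndarray
    solver: Literal["exact", "sinkhorn"]
    converged: bool = True


@dataclass
class OTDDConfig:
    """Settings for dataset-distance computation.

    ``max_samples_per_task`` caps each dataset by stratified subsampling
    before OT; ``covariance_shrinkage`` adds ``shrinkage * (trace/d) * I`` to
    each class covariance (classes can have fewer samples than feature
    dimensions); the exact solver is used while the cost matrix stays at or
    below ``exact_max_entries`` entries, Sinkhorn otherwise with
    ``epsilon = sinkhorn_epsilon_scale * mean(cost)``.
    """

    solver: Literal["auto", "exact", "sinkhorn"] = "auto"
    sinkhorn_epsilon_scale: float = 0.1
    sinkhorn_max_iter: int = 10_000
    sinkhorn_tol: float = 1e-9
    max_samples_per_task: int = 1000
    covariance_shrinkage: float = 1e-3
    exact_max_entries: int = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sinkhorn_epsilon_scale <= 0:
            raise ValueError("sinkhorn epsilon scale must be > 0")
        if self.max_samples_per_task < 1:
            raise ValueError("max_samples_per_task must be >= 1")
        if self.covariance_shrinkage < 0:
            raise ValueError("covariance_shrinkage must be >= 0")


def fit_label_gaussians(
    ds: EmbeddedDataset, shrinkage: float = 1e-3
) -> dict[int, GaussianLabelModel]:
    """Fit one Gaussian per label present in the dataset.

    The covariance uses denominator n (stable for singleton classes) plus
    ``shrinkage * (trace/d) * I`` and an absolute floor of ``1e-8 * I``.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    d = ds.dim
    if d == 0:
        raise ValueError("zero-dimensional features")
    models: dict[int, GaussianLabelModel] = {}
    for label in np.unique(ds.labels):
        x = ds.features[ds.labels == label]
        mean = x.mean(axis=0)
        centered = x - mean
        cov = centered.T @ centered / x.shape[0]
        cov += (shrinkage * np.trace(cov) / d + _ABS_COV_FLOOR) * np.eye(d)
        models[int(label)] = GaussianLabelModel(int(label), mean, cov, x.shape[0])
    return models


def _psd_sqrtm(matrix: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, eigenvalues clipped at 0."""
    sym = (matrix + matrix.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    eigval = np.clip(eigval, 0.0, None)
    return (eigvec * np.sqrt(eigval)) @ eigvec.T


def wasserstein2_gaussians(g1: GaussianLabelModel, g2: GaussianLabelModel) -> float:
    """Closed-form 2-Wasserstein (Bures) distance between two Gaussians.

    W2^2 = ||mu1 - mu2||^2 + tr(S1 + S2 - 2 (S2^{1/2} S1 S2^{1/2})^{1/2}).
    """
    if g1.dim != g2.dim:
        raise ValueError(f"dimension mismatch: {g1.dim} vs {g2.dim}")
    for g in (g1, g2):
        if not (np.all(np.isfinite(g.mean)) and np.all(np.isfinite(g.covariance))):
            raise ValueError("non-finite Gaussian parameters")
    mean_term = float(np.sum((g1.mean - g2.mean) ** 2))
    root2 = _psd_sqrtm(g2.covariance)
    cross = _psd_sqrtm(root2 @ g1.covariance @ root2)
    trace_term = float(np.trace(g1.covariance) + np.trace(g2.covariance) - 2.0 * np.trace(cross))
    # eigendecomposition roundoff leaves O(eps * tr) residue for (near-)equal
    # covariances; treat anything below the relative noise floor as zero
    noise_floor = 1e-9 * float(np.trace(g1.covariance) + np.trace(g2.covariance))
    if trace_term < noise_floor:
        trace_term = 0.0
    return float(np.sqrt(mean_term + max(trace_term, 0.0)))


def ground_cost_matrix(
    dsA: EmbeddedDataset,
    dsB: EmbeddedDataset,
    labelsW: Mapping[tuple[int, int], float],
) -> np.ndarray:
    """Squared feature-label ground cost: ||x_i - x'_j||^2 + W2(y_i, y'_j)^2."""
    cost = cdist(dsA.features, dsB.features, metric="sqeuclidean")
    w2sq = np.empty_like(cost)
    for ya in np.unique(dsA.labels):
        for yb in np.unique(dsB.labels):
            key = (int(ya), int(yb))
            if key not in labelsW:
                raise KeyError(f"missing label-pair Wasserstein distance for {key}")
            w2sq[np.ix_(dsA.labels == ya, dsB.labels == yb)] = labelsW[key] ** 2
    return cost + w2sq


def _check_marginals(cost: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (cost.shape[0],) or b.shape != (cost.shape[1],):
        raise ValueError("marginal shapes do not match cost matrix")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative marginal entries")
    if abs(a.sum() - 1.0) > 1e-8 or abs(b.sum() - 1.0) > 1e-8:
        raise ValueError("marginals must each sum to 1 (within 1e-8)")
    if not np.all(np.isfinite(cost)):
        raise ValueError("non-finite cost entries")
    return a, b


def solve_exact_ot(cost: np.ndarray, a: np.ndarray, b: np.ndarray) -> TransportPlan:
    """Exact discrete optimal transport.

    Uniform square marginals reduce to the assignment problem (Birkhoff: some
    optimal coupling is a scaled permutation); general marginals go through
    the HiGHS LP solver.
    """
    cost = np.asarray(cost, dtype=float)
    a, b = _check_marginals(cost, a, b)
    n, m = cost.shape

    uniform_square = n == m and np.allclose(a, 1.0 / n) and np.allclose(b, 1.0 / m)
    if uniform_square:
        rows, cols = optimize.linear_sum_assignment(cost)
        plan = np.zeros_like(cost)
        plan[rows, cols] = 1.0 / n
    else:
        # LP over flattened plan; one marginal constraint is redundant.
        A_eq_rows = []
        for i in range(n):
            row = np.zeros(n * m)
            row[i * m : (i + 1) * m] = 1.0
            A_eq_rows.append(row)
        for j in range(m - 1):
            col = np.zeros(n * m)
            col[j::m] = 1.0
            A_eq_rows.append(col)
        rhs = np.concatenate([a, b[:-1]])
        res = optimize.linprog(
            cost.ravel(), A_eq=np.vstack(A_eq_rows), b_eq=rhs, bounds=(0, None), method="highs"
        )
        if not res.success:
            raise RuntimeError(f"exact OT LP failed: {res.message}")
        plan = res.x.reshape(n, m)

    return TransportPlan(plan=plan, cost=float(np.sum(plan * cost)), a=a, b=b, solver="exact")


def solve_sinkhorn(
    cost: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    epsilon: float,
    max_iter: int = 10_000,
    tol: float = 1e-9,
) -> TransportPlan:
    """Entropic-regularized OT via log-domain Sinkhorn iterations.

    Reported cost is the linear part <plan, cost> (no entropy term). The
    returned plan is rounded onto the coupling polytope (marginals matched
    exactly), so its cost is a true upper bound on the unregularized optimum.
    Non-convergence within ``max_iter`` returns the current plan with
    ``converged=False`` and a warning.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    cost = np.asarray(cost, dtype=float)
    a, b = _check_marginals(cost, a, b)

    log_a = np.log(np.where(a > 0, a, 1e-300))
    log_b = np.log(np.where(b > 0, b, 1e-300))
    neg_c = -cost / epsilon
    f = np.zeros_like(a)
    g = np.zeros_like(b)
    converged = False
    plan = np.exp(neg_c)
    for _ in range(max_iter):
        f = epsilon * (log_a - logsumexp(neg_c + g[None, :] / epsilon, axis=1))
        g = epsilon * (log_b - logsumexp(neg_c + f[:, None] / epsilon, axis=0))
        plan = np.exp(neg_c + (f[:, None] + g[None, :]) / epsilon)
        violation = max(
            np.abs(plan.sum(axis=1) - a).max(), np.abs(plan.sum(axis=0) - b).max()
        )
        if violation < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "Sinkhorn did not converge within %d iterations (violation %.3g)", max_iter, violation
        )
    plan = _round_to_coupling(plan, a, b)
    return TransportPlan(
        plan=plan, cost=float(np.sum(plan * cost)), a=a, b=b, solver="sinkhorn", converged=converged
    )


def _round_to_coupling(plan: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Project an almost-feasible plan onto the coupling polytope.

    Scale rows then columns down where they overshoot their marginals and
    spread the residual mass as a rank-one correction; the result satisfies
    both marginals exactly.
    """
    row = plan.sum(axis=1)
    plan = plan * np.where(row > 0, np.minimum(a / np.where(row > 0, row, 1.0), 1.0), 0.0)[:, None]
    col = plan.sum(axis=0)
    plan = plan * np.where(col > 0, np.minimum(b / np.where(col > 0, col, 1.0), 1.0), 0.0)[None, :]
    err_a = a - plan.sum(axis=1)
    err_b = b - plan.sum(axis=0)
    mass = err_a.sum()
    if mass > 0:
        plan = plan + np.outer(err_a, err_b) / mass
    return plan


def _stratified_subsample(ds: EmbeddedDataset, cap: int, rng: np.random.Generator) -> EmbeddedDataset:
    n = len(ds)
    if n <= cap:
        return ds
    keep: list[np.ndarray] = []
    labels = np.unique(ds.labels)
    # proportional allocation, remainder to the larger classes
    quotas = {}
    for lab in labels:
        quotas[int(lab)] = int(np.floor(cap * np.sum(ds.labels == lab) / n))
    while sum(quotas.values()) < cap:
        lab = max(labels, key=lambda L: np.sum(ds.labels == L) - quotas[int(L)])
        quotas[int(lab)] += 1
    for lab in labels:
        idx = np.flatnonzero(ds.labels == lab)
        take = min(quotas[int(lab)], idx.size)
        keep.append(rng.choice(idx, size=take, replace=False))
    idx = np.sort(np.concatenate(keep))
    return EmbeddedDataset(ds.task_id, ds.features[idx], ds.labels[idx], ds.featurizer_name, ds.standardized)


def otdd_distance(dsA: EmbeddedDataset, dsB: EmbeddedDataset, cfg: OTDDConfig | None = None) -> float:
    """Dataset distance sqrt(OT cost) under the feature-label ground metric."""
    cfg = cfg or OTDDConfig()
    if len(dsA) == 0 or len(dsB) == 0:
        raise ValueError("empty dataset")
    if dsA.featurizer_name != dsB.featurizer_name:
        raise ValueError(
            f"featurizer mismatch: {dsA.featurizer_name!r} vs {dsB.featurizer_name!r}"
        )

    rng = np.random.default_rng(cfg.seed)
    dsA = _stratified_subsample(dsA, cfg.max_samples_per_task, rng)
    dsB = _stratified_subsample(dsB, cfg.max_samples_per_task, rng)

    gA = fit_label_gaussians(dsA, cfg.covariance_shrinkage)
    gB = fit_label_gaussians(dsB, cfg.covariance_shrinkage)
    labelsW = {
        (ya, yb): wasserstein2_gaussians(gA[ya], gB[yb]) for ya in gA for yb in gB
    }
    cost = ground_cost_matrix(dsA, dsB, labelsW)
    n, m = cost.shape
    a = np.full(n, 1.0 / n)
    b = np.full(m, 1.0 / m)

    solver = cfg.solver
    if solver == "auto":
        solver = "exact" if n * m <= cfg.exact_max_entries else "sinkhorn"
    if solver == "exact":
        plan = solve_exact_ot(cost, a, b)
    else:
        epsilon = cfg.sinkhorn_epsilon_scale * float(cost.mean())
        plan = solve_sinkhorn(cost, a, b, max(epsilon, 1e-12), cfg.sinkhorn_max_iter, cfg.sinkhorn_tol)
    return float(np.sqrt(max(plan.cost, 0.0)))


def chem_distance_matrix(
    sources: list[EmbeddedDataset],
    targets: list[EmbeddedDataset],
    cfg: OTDDConfig | None = None,
    cache_path: str | Path | None = None,
) -> DistanceMatrix:
    """Pairwise OTDD between every source and target task.

    ``cache_path`` (JSON) makes the computation resumable: completed pairs
    are re-used, failed pairs become NaN and their targets are dropped from
    the returned matrix (logged with the pair identity).
    """
    cfg = cfg or OTDDConfig()
    cache: dict[str, float] = {}
    if cache_path is not None and Path(cache_path).is_file():
        with open(cache_path) as fh:
            cache = json.load(fh)

    values = np.zeros((len(sources), len(targets)))
    failed_targets: set[str] = set()
    dirty = False
    for j, tgt in enumerate(targets):
        for i, src in enumerate(sources):
            key = f"{src.task_id}\t{tgt.task_id}"
            if key in cache:
                values[i, j] = cache[key]
                continue
            try:
                values[i, j] = otdd_distance(src, tgt, cfg)
            except Exception as exc:
                logger.error("OTDD failed for pair (%s, %s): %s", src.task_id, tgt.task_id, exc)
                values[i, j] = np.nan
                failed_targets.add(tgt.task_id)
            cache[key] = float(values[i, j])
            dirty = True
    if cache_path is not None and dirty:
        with open(cache_path, "w") as fh:
            json.dump(cache, fh)

    target_ids = [t.task_id for t in targets]
    if failed_targets:
        logger.warning("dropping targets with failed pairs: %s", sorted(failed_targets))
        keep = [j for j, t in enumerate(target_ids) if t not in failed_targets]
        if not keep:
            raise RuntimeError("all targets failed OTDD computation")
        values = values[:, keep]
        target_ids = [target_ids[j] for j in keep]

    featurizers = {s.featurizer_name for s in sources} | {t.featurizer_name for t in targets}
    return DistanceMatrix(
        source_ids=[s.task_id for s in sources],
        target_ids=target_ids,
        values=values,
        space="chem",
        metadata={
            "featurizer": sorted(featurizers),
            "solver": cfg.solver,
            "epsilon_scale": cfg.sinkhorn_epsilon_scale,
            "max_samples_per_task": cfg.max_samples_per_task,
            "covariance_shrinkage": cfg.covariance_shrinkage,
            "seed": cfg.seed,
        },
    )
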