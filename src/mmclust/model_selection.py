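"""Cluster-number heuristics, internal validity metrics and model selection.

Three validity metrics on binary data: Calinski–Harabasz (between/within
dispersion ratio, higher better), Davies–Bouldin (worst-pair compactness vs
separation, lower better) and silhouette (per-point cohesion vs
nearest-other-cluster separation, higher better, in [-1, 1]). The 0/1 rows
are treated as points in real p-space with mean centroids; Davies–Bouldin
and silhouette additionally expose a matching-dissimilarity variant, since
squared Euclidean distance on 0/1 vectors equals matching dissimilarity.

Cluster number is chosen per method: the elbow of the scree curve for
k-modes and k-medoids (automated as the point of maximum perpendicular
distance to the first-to-last chord), and minimal BIC for LCA.

Because singleton clusters can flatter separation-based metrics, singleton
counts and cluster-size summaries are first-class fields of every report.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import silhouette_samples

from mmclust.clustering import ClusterModel, ClusteringError, ConditionMatrix

logger = logging.getLogger(__name__)

SILHOUETTE_SUBSAMPLE_THRESHOLD = 20_000
SILHOUETTE_SUBSAMPLE_SIZE = 10_000

METRIC_FIELDS = ("calinski_harabasz", "davies_bouldin", "silhouette")


class MetricUndefinedError(ValueError):
    """Metric is undefined for this labelling (e.g. a single cluster)."""


@dataclass
class ValidityReport:
    """The three validity metrics plus cluster-size accounting for one model
    (or the mean +/- sd across repeated runs of one method)."""

    method: str
    k: int
    calinski_harabasz: float
    davies_bouldin: float
    silhouette: float
    n_singleton_clusters: int
    median_cluster_size: float
    min_cluster_size: int
    max_cluster_size: int
    aggregated_as: str = "single"
    ch_sd: float | None = None
    db_sd: float | None = None
    sil_sd: float | None = None
    seed: int | None = None
    objective: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.silhouette <= 1.0 + 1e-9:
            raise ValueError("silhouette must lie in [-1, 1]")
        if self.n_singleton_clusters > self.k:
            raise ValueError("cannot have more singleton clusters than clusters")
        if not (
            self.min_cluster_size <= self.median_cluster_size <= self.max_cluster_size
        ):
            raise ValueError("cluster-size summary must satisfy min <= median <= max")


@dataclass
class SelectionResult:
    """The chosen model and a structured account of why it was chosen."""

    chosen_method: str
    chosen_k: int
    chosen_seed: int | None
    rationale: dict


def _check_labels(labels: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, int]:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per row")
    uniq, dense = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise MetricUndefinedError("metric undefined with fewer than 2 clusters")
    if k >= n:
        raise MetricUndefinedError("metric undefined when every point is a cluster")
    return labels, dense, k


def calinski_harabasz(X: ConditionMatrix | np.ndarray, labels) -> float:
    """Between/within dispersion ratio scaled by (n-k)/(k-1).

    Rows are treated as points in real p-space with mean centroids. Perfectly
    separated point-mass clusters have zero within-cluster dispersion; the
    metric then diverges and +inf is returned.
    """
    data = X.values if isinstance(X, ConditionMatrix) else np.asarray(X)
    data = data.astype(float)
    n = data.shape[0]
    _, dense, k = _check_labels(labels, n)
    overall = data.mean(axis=0)
    within = 0.0
    between = 0.0
    for j in range(k):
        members = data[dense == j]
        centroid = members.mean(axis=0)
        within += float(((members - centroid) ** 2).sum())
        between += len(members) * float(((centroid - overall) ** 2).sum())
    if within == 0.0:
        return np.inf
    return (between / within) * (n - k) / (k - 1)


def davies_bouldin(
    X: ConditionMatrix | np.ndarray,
    labels,
    dissimilarity: str = "euclidean_binary",
) -> float:
    """Mean over clusters of the worst (sigma_i + sigma_j) / d(c_i, c_j).

    ``euclidean_binary`` matches the standard Euclidean definition with mean
    centroids; ``matching`` uses L1 distance to the mean centroid, which
    equals matching dissimilarity when both arguments are binary.
    Coincident centroids contribute +inf (logged), reflecting a degenerate
    partition.
    """
    data = X.values if isinstance(X, ConditionMatrix) else np.asarray(X)
    data = data.astype(float)
    n = data.shape[0]
    _, dense, k = _check_labels(labels, n)
    if dissimilarity == "euclidean_binary":
        dist = lambda a, b: float(np.sqrt(((a - b) ** 2).sum(axis=-1)))
        spread = lambda members, c: float(
            np.sqrt(((members - c) ** 2).sum(axis=1)).mean()
        )
    elif dissimilarity == "matching":
        dist = lambda a, b: float(np.abs(a - b).sum(axis=-1))
        spread = lambda members, c: float(np.abs(members - c).sum(axis=1).mean())
    else:
        raise ValueError(f"unknown dissimilarity {dissimilarity!r}")
    centroids = np.stack([data[dense == j].mean(axis=0) for j in range(k)])
    sigmas = np.array([spread(data[dense == j], centroids[j]) for j in range(k)])
    worst = np.zeros(k)
    degenerate = False
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = dist(centroids[i], centroids[j])
            if d == 0.0:
                degenerate = True
                ratio = np.inf
            else:
                ratio = (sigmas[i] + sigmas[j]) / d
            worst[i] = max(worst[i], ratio)
    if degenerate:
        logger.warning("Davies–Bouldin: coincident centroids give +inf contribution")
    return float(worst.mean())


def silhouette(
    X: ConditionMatrix | np.ndarray,
    labels,
    dissimilarity: str = "matching",
    subsample_threshold: int = SILHOUETTE_SUBSAMPLE_THRESHOLD,
    subsample_size: int = SILHOUETTE_SUBSAMPLE_SIZE,
    seed: int = 0,
) -> float:
    """Mean silhouette (b - a) / max(a, b); singletons contribute 0.

    Silhouette is O(n^2), so above ``subsample_threshold`` rows it is
    evaluated on a seeded subsample of ``subsample_size`` rows; below the
    threshold the computation is exact and full. Silhouette is invariant to
    uniform scaling of the dissimilarity, so the ``matching`` variant uses
    the hamming fraction internally.
    """
    data = X.values if isinstance(X, ConditionMatrix) else np.asarray(X)
    n = data.shape[0]
    labels_arr, dense, _ = _check_labels(labels, n)
    if dissimilarity == "matching":
        metric = "hamming"
    elif dissimilarity == "euclidean_binary":
        metric = "euclidean"
    else:
        raise ValueError(f"unknown dissimilarity {dissimilarity!r}")
    if n > subsample_threshold:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=subsample_size, replace=False)
        data, dense = data[idx], dense[idx]
        if len(np.unique(dense)) < 2:
            raise MetricUndefinedError("subsample collapsed to a single cluster")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = silhouette_samples(data.astype(float), dense, metric=metric)
    return float(np.nan_to_num(vals, nan=0.0).mean())


def cluster_size_summary(labels, k: int | None = None) -> dict:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    sizes = np.array([int((labels == u).sum()) for u in uniq])
    return {
        "n_clusters": len(uniq),
        "n_singleton_clusters": int((sizes == 1).sum()),
        "median_cluster_size": float(np.median(sizes)),
        "min_cluster_size": int(sizes.min()),
        "max_cluster_size": int(sizes.max()),
    }


def evaluate_model(
    X: ConditionMatrix, model: ClusterModel, silhouette_seed: int = 0
) -> ValidityReport:
    """All three metrics plus size accounting for one fitted model."""
    sizes = cluster_size_summary(model.labels)
    return ValidityReport(
        method=model.method,
        k=model.k,
        calinski_harabasz=calinski_harabasz(X, model.labels),
        davies_bouldin=davies_bouldin(X, model.labels),
        silhouette=silhouette(X, model.labels, seed=silhouette_seed),
        n_singleton_clusters=sizes["n_singleton_clusters"],
        median_cluster_size=sizes["median_cluster_size"],
        min_cluster_size=sizes["min_cluster_size"],
        max_cluster_size=sizes["max_cluster_size"],
        seed=model.seed,
        objective=model.objective,
    )


def scree_elbow(objective_by_k: Mapping[int, float]) -> int:
    """Automated elbow: the k with maximum perpendicular distance to the
    chord joining the first and last scree points.

    A flat or strictly linear curve has no elbow; the smallest k is returned
    with a warning. The full scree table is the caller's to emit, so a human
    can always override the automated choice.
    """
    if len(objective_by_k) < 3:
        raise ValueError("need at least 3 k values for an elbow")
    ks = np.array(sorted(objective_by_k))
    costs = np.array([objective_by_k[k] for k in ks], dtype=float)
    if not np.isfinite(costs).all():
        raise ValueError("scree costs must be finite")
    p0 = np.array([ks[0], costs[0]])
    p1 = np.array([ks[-1], costs[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        logger.warning("scree curve is flat; no elbow, returning smallest k")
        return int(ks[0])
    pts = np.stack([ks, costs], axis=1) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    if dist.max() < 1e-9 * max(1.0, np.abs(costs).max()):
        logger.warning("scree curve is linear; no elbow, returning smallest k")
        return int(ks[0])
    return int(ks[int(dist.argmax())])


def bic_select(lca_models_by_k: Mapping[int, ClusterModel | float]) -> int:
    """k of minimal BIC; ties go to the smaller k."""
    if len(lca_models_by_k) < 2:
        raise ValueError("need at least 2 candidate k values")
    bics = {
        k: (m.bic if isinstance(m, ClusterModel) else float(m))
        for k, m in lca_models_by_k.items()
    }
    return min(sorted(bics), key=lambda k: bics[k])


def aggregate_repeats(reports: Sequence[ValidityReport]) -> ValidityReport:
    """Mean and sample standard deviation (n-1 denominator) across repeats of
    one method at one k; a single report passes through as ``single``."""
    if not reports:
        raise ValueError("need at least one report")
    methods = {r.method for r in reports}
    if len(methods) > 1:
        raise ValueError(f"cannot aggregate mixed methods {sorted(methods)}")
    if len(reports) == 1:
        return dataclasses.replace(reports[0])
    ch = np.array([r.calinski_harabasz for r in reports])
    db = np.array([r.davies_bouldin for r in reports])
    sil = np.array([r.silhouette for r in reports])
    return ValidityReport(
        method=reports[0].method,
        k=int(round(np.mean([r.k for r in reports]))),
        calinski_harabasz=float(ch.mean()),
        davies_bouldin=float(db.mean()),
        silhouette=float(sil.mean()),
        ch_sd=float(ch.std(ddof=1)),
        db_sd=float(db.std(ddof=1)),
        sil_sd=float(sil.std(ddof=1)),
        n_singleton_clusters=int(round(np.mean([r.n_singleton_clusters for r in reports]))),
        median_cluster_size=float(np.mean([r.median_cluster_size for r in reports])),
        min_cluster_size=int(min(r.min_cluster_size for r in reports)),
        max_cluster_size=int(max(r.max_cluster_size for r in reports)),
        aggregated_as="mean_sd",
    )


def select_best(
    all_reports: Sequence[ValidityReport],
    rule: str | Callable[[Sequence[ValidityReport]], SelectionResult] = "default",
) -> SelectionResult:
    """Pick the best model from per-run validity reports.

    The default rule mirrors the intended analysis workflow: rank methods by their mean
    metric ranks (Calinski–Harabasz and silhouette descending, Davies–Bouldin
    ascending), note singleton-cluster pathologies in the rationale, then
    within the winning method pick the single run with the highest
    Calinski–Harabasz score. The decision trace is recorded in
    ``rationale``; the rule is pluggable via a callable.
    """
    if not all_reports:
        raise ValueError("no candidate models to select from")
    if callable(rule):
        return rule(all_reports)
    if rule != "default":
        raise ValueError(f"unknown selection rule {rule!r}")

    methods = sorted({r.method for r in all_reports})
    per_method = {
        m: aggregate_repeats([r for r in all_reports if r.method == m])
        for m in methods
    }

    def ranks(values: list[float], higher_better: bool) -> dict[str, float]:
        order = sorted(
            range(len(values)), key=lambda i: -values[i] if higher_better else values[i]
        )
        out: dict[int, float] = {}
        for rank, i in enumerate(order):
            out[i] = float(rank)
        return out

    ch_r = ranks([per_method[m].calinski_harabasz for m in methods], True)
    db_r = ranks([per_method[m].davies_bouldin for m in methods], False)
    sil_r = ranks([per_method[m].silhouette for m in methods], True)
    mean_rank = {
        m: (ch_r[i] + db_r[i] + sil_r[i]) / 3.0 for i, m in enumerate(methods)
    }
    singleton_flags = {
        m: per_method[m].n_singleton_clusters for m in methods
    }
    best_method = min(
        methods,
        key=lambda m: (mean_rank[m], -per_method[m].calinski_harabasz),
    )
    candidates = [r for r in all_reports if r.method == best_method]
    chosen = max(candidates, key=lambda r: r.calinski_harabasz)
    rationale = {
        "rule": "best mean metric rank across methods, then highest "
        "Calinski–Harabasz run within that method",
        "method_mean_ranks": mean_rank,
        "method_summaries": {
            m: {
                "calinski_harabasz": per_method[m].calinski_harabasz,
                "davies_bouldin": per_method[m].davies_bouldin,
                "silhouette": per_method[m].silhouette,
                "n_singleton_clusters": singleton_flags[m],
            }
            for m in methods
        },
        "singleton_caveats": [
            f"{m}: {c} singleton cluster(s); separation-based metrics may be optimistic"
            for m, c in singleton_flags.items()
            if c > 0
        ],
        "chosen_run_calinski_harabasz": chosen.calinski_harabasz,
    }
    if singleton_flags.get(best_method, 0) >= max(1, chosen.k - 1):
        rationale["singleton_caveats"].append(
            f"chosen method {best_method} is dominated by singleton clusters"
        )
    return SelectionResult(
        chosen_method=best_method,
        chosen_k=chosen.k,
        chosen_seed=chosen.seed,
        rationale=rationale,
    )
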