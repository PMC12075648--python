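"""Clustering methods for binary condition profiles.

Four methods appropriate for categorical data: k-modes (matching
dissimilarity to per-cluster modes), PAM k-medoids (build + swap on the
pairwise matching-dissimilarity matrix), latent class analysis (EM for a
mixture of products of Bernoullis), and agglomerative hierarchical
clustering (scipy linkage on matching dissimilarity).

All methods consume a :class:`ConditionMatrix` and return a
:class:`ClusterModel` with labels, method-specific centers, the final
objective and its per-iteration trace. k-modes and PAM minimise total
matching dissimilarity (cost, non-increasing per iteration); LCA maximises
the log-likelihood (non-decreasing per EM iteration).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

METHODS = ("kmodes", "kmedoids", "lca", "ahc")
STOCHASTIC_METHODS = ("kmodes", "lca")

LCA_PROB_FLOOR = 1e-6  # item-probability clamp keeping EM in the log domain


class ClusteringError(ValueError):
    pass


@dataclass
class ConditionMatrix:
    """Persons x conditions binary matrix with names and ids.

    Every entry is 0/1 with no missing values; every row has at least one
    condition (zero-condition persons belong to the reference group and are
    excluded upstream of clustering).
    """

    values: np.ndarray
    condition_names: list[str]
    person_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ClusteringError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.condition_names) != p:
            raise ClusteringError("condition_names length must match columns")
        if len(self.person_ids) != n:
            raise ClusteringError("person_ids length must match rows")
        if not np.isin(self.values, (0, 1)).all():
            raise ClusteringError("entries must be 0 or 1 with no missing values")
        if n and (self.values.sum(axis=1) == 0).any():
            raise ClusteringError(
                "every person must have at least one condition; "
                "exclude zero-condition persons before clustering"
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str = "person_id"):
        names = [c for c in df.columns if c != id_column]
        ids = (
            df[id_column].astype(str).tolist()
            if id_column in df
            else [str(i) for i in range(len(df))]
        )
        return cls(df[names].to_numpy(), names, ids)

    @classmethod
    def from_csv(cls, path, id_column: str = "person_id"):
        return cls.from_dataframe(pd.read_csv(path), id_column=id_column)


@dataclass
class ClusterModel:
    """A fitted partition with method-specific parameters and diagnostics."""

    method: str
    k: int
    labels: np.ndarray
    centers: dict
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    seed: int | None = None
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.k
        ):
            raise ClusteringError("labels must lie in [0, k)")

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    @property
    def n_empty_clusters(self) -> int:
        return int((self.cluster_sizes() == 0).sum())

    @property
    def bic(self) -> float:
        """BIC for LCA models: -2 logL + [(k-1) + k*p] ln n."""
        if self.method != "lca":
            raise ClusteringError("BIC is defined for LCA models only")
        n, p = self.extras["n_persons"], self.extras["n_conditions"]
        n_free = (self.k - 1) + self.k * p
        return -2.0 * self.objective + n_free * np.log(n)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "k": self.k,
            "labels": self.labels.tolist(),
            "centers": {
                key: (val.tolist() if isinstance(val, np.ndarray) else val)
                for key, val in self.centers.items()
            },
            "objective": self.objective,
            "objective_trace": self.objective_trace,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload))

    def labels_frame(self, person_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame({"person_id": list(person_ids), "cluster": self.labels})


def matching_dissimilarity(a, b) -> int:
    """Number of attribute positions where two categorical vectors differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ClusteringError("vectors must have equal length")
    return int((a != b).sum())


def pairwise_matching(X: np.ndarray, block_size: int = 2048) -> np.ndarray:
    """Full pairwise matching-dissimilarity matrix, computed in row blocks.

    Blocked computation is exactly equal to the full-matrix result; blocks
    only bound peak memory for large cohorts.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    n, p = X.shape
    if n <= block_size:
        return (squareform(pdist(X, metric="hamming")) * p).round().astype(np.int32)
    D = np.empty((n, n), dtype=np.int32)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        # hamming counts via XOR-free integer arithmetic
        block = X[start:stop].astype(np.int32)
        D[start:stop] = (
            block @ (1 - X.T.astype(np.int32)) + (1 - block) @ X.T.astype(np.int32)
        )
    return D


def _distances_to_modes(X: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """n x k matching-dissimilarity to each mode."""
    return (X[:, None, :] != modes[None, :, :]).sum(axis=2)


def _mode_of(rows: np.ndarray) -> np.ndarray:
    """Per-column majority; exact 50/50 ties resolve to 0 (absence)."""
    counts = rows.sum(axis=0)
    return (2 * counts > rows.shape[0]).astype(np.int8)


def _cao_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic density-based initialisation (attribute-frequency density)."""
    n, p = X.shape
    col_freq1 = X.sum(axis=0) / n
    # density of each object: average frequency of its own attribute values
    dens = (X * col_freq1 + (1 - X) * (1 - col_freq1)).sum(axis=1) / p
    chosen = [int(dens.argmax())]
    for _ in range(1, k):
        d_to_chosen = _distances_to_modes(X, X[chosen])
        score = dens * d_to_chosen.min(axis=1)
        score[chosen] = -np.inf
        chosen.append(int(score.argmax()))
    return X[chosen].copy()


def _huang_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Frequency-weighted random modes, snapped to nearest distinct data points."""
    n, p = X.shape
    col_freq1 = X.sum(axis=0) / n
    proto = (rng.random((k, p)) < col_freq1).astype(np.int8)
    modes = np.empty_like(proto)
    taken: set[int] = set()
    for j in range(k):
        dist = (X != proto[j]).sum(axis=1).astype(float)
        dist[list(taken)] = np.inf
        idx = int(dist.argmin())
        taken.add(idx)
        modes[j] = X[idx]
    return modes


def kmodes_fit(
    X: ConditionMatrix,
    k: int,
    init: str = "cao",
    max_iter: int = 100,
    seed: int | None = None,
    init_modes: np.ndarray | None = None,
) -> ClusterModel:
    """k-modes clustering: alternate assignment to nearest mode and mode update.

    Total matching dissimilarity to cluster modes is non-increasing across
    iterations; iteration stops when no label changes or at ``max_iter``.
    An empty cluster is re-seeded with the point farthest from its own mode.
    ``init_modes`` overrides the initialisation (used e.g. to start from a
    known optimum).
    """
    data = X.values
    n = data.shape[0]
    if not 1 <= k <= n:
        raise ClusteringError(f"k must lie in [1, n_persons]; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    if init_modes is not None:
        modes = np.asarray(init_modes, dtype=np.int8).copy()
        if modes.shape != (k, data.shape[1]):
            raise ClusteringError("init_modes must have shape (k, n_conditions)")
    elif init == "cao":
        modes = _cao_init(data, k)
    elif init == "huang":
        modes = _huang_init(data, k, rng)
    elif init == "random":
        modes = data[rng.choice(n, size=k, replace=False)].copy()
    else:
        raise ClusteringError(f"unknown init {init!r}")

    labels = np.full(n, -1, dtype=int)
    trace: list[float] = []
    converged = False
    for iteration in range(1, max_iter + 1):
        dist = _distances_to_modes(data, modes)
        new_labels = dist.argmin(axis=1)
        cost = float(dist[np.arange(n), new_labels].sum())
        trace.append(cost)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for j in range(k):
            members = data[labels == j]
            if len(members) == 0:
                # re-seed with the point farthest from this cluster's mode
                far = int((data != modes[j]).sum(axis=1).argmax())
                logger.info("k-modes: empty cluster %d re-seeded with point %d", j, far)
                modes[j] = data[far]
                labels[far] = j
            else:
                modes[j] = _mode_of(members)
    final_dist = _distances_to_modes(data, modes)
    labels = final_dist.argmin(axis=1)
    cost = float(final_dist[np.arange(n), labels].sum())
    return ClusterModel(
        method="kmodes",
        k=k,
        labels=labels,
        centers={"modes": modes},
        objective=cost,
        objective_trace=trace,
        n_iterations=len(trace),
        seed=seed,
        converged=converged,
    )


def kmodes_cost(X: ConditionMatrix, labels: np.ndarray, k: int) -> float:
    """Cost of a partition under optimal per-cluster modes (tie rule: 0)."""
    data = X.values
    total = 0
    for j in range(k):
        members = data[np.asarray(labels) == j]
        if len(members):
            mode = _mode_of(members)
            total += int((members != mode).sum())
    return float(total)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(D.sum(axis=1).argmin())]
    d_nearest = D[:, medoids[0]].astype(float)
    while len(medoids) < k:
        gains = np.maximum(d_nearest[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(gains.argmax())
        medoids.append(best)
        d_nearest = np.minimum(d_nearest, D[:, best])
    return medoids


def kmedoids_fit(
    X: ConditionMatrix,
    k: int,
    seed: int | None = None,
    max_swaps: int = 1000,
    init_medoids: Sequence[int] | None = None,
) -> ClusterModel:
    """PAM k-medoids on the matching-dissimilarity matrix (build + swap).

    Medoids are actual persons. The swap phase repeatedly applies the best
    improving (medoid, non-medoid) exchange until none improves the total
    cost, so the cost trace is strictly decreasing after the build step.
    PAM is deterministic given the data; ``seed`` is recorded for provenance
    only.
    """
    data = X.values
    n = data.shape[0]
    if not 1 <= k <= n:
        raise ClusteringError(f"k must lie in [1, n_persons]; got k={k}, n={n}")
    D = pairwise_matching(data).astype(float)
    if init_medoids is not None:
        medoids = list(dict.fromkeys(int(m) for m in init_medoids))
        if len(medoids) != k or not all(0 <= m < n for m in medoids):
            raise ClusteringError("init_medoids must be k distinct row indices")
    else:
        medoids = _pam_build(D, k)
    trace = [float(D[:, medoids].min(axis=1).sum())]
    n_swaps = 0
    converged = False
    for _ in range(max_swaps):
        dmat = D[:, medoids]
        order = np.argsort(dmat, axis=1)
        d1 = dmat[np.arange(n), order[:, 0]]
        nearest = order[:, 0]
        d2 = dmat[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-9, None
        medoid_set = set(medoids)
        candidates = [h for h in range(n) if h not in medoid_set]
        if not candidates:
            converged = True
            break
        for mi in range(k):
            served = nearest == mi
            Dh = D[:, candidates]  # n x c
            # points served by medoid mi: new dist = min(D[:,h], d2); others: min(D[:,h], d1)
            loss = np.where(
                served[:, None],
                np.minimum(Dh, d2[:, None]) - d1[:, None],
                np.minimum(Dh - d1[:, None], 0.0),
            ).sum(axis=0)
            ci = int(loss.argmin())
            if loss[ci] < best_delta:
                best_delta = float(loss[ci])
                best_swap = (mi, candidates[ci])
        if best_swap is None:
            converged = True
            break
        medoids[best_swap[0]] = best_swap[1]
        n_swaps += 1
        trace.append(float(D[:, medoids].min(axis=1).sum()))
    labels = D[:, medoids].argmin(axis=1)
    cost = float(D[np.arange(n), [medoids[j] for j in labels]].sum())
    return ClusterModel(
        method="kmedoids",
        k=k,
        labels=labels,
        centers={"medoid_indices": np.asarray(medoids)},
        objective=cost,
        objective_trace=trace,
        n_iterations=n_swaps,
        seed=seed,
        converged=converged,
    )


def lca_loglik(X: np.ndarray, weights: np.ndarray, theta: np.ndarray) -> float:
    """Log-likelihood of a Bernoulli-mixture model on binary data."""
    log_members = _lca_log_members(X, weights, theta)
    return float(logsumexp(log_members, axis=1).sum())


def _lca_log_members(X, weights, theta):
    Xf = X.astype(float)
    log_theta = np.log(theta)
    log_1m = np.log1p(-theta)
    return np.log(weights)[None, :] + Xf @ log_theta.T + (1 - Xf) @ log_1m.T


def lca_fit(
    X: ConditionMatrix,
    k: int,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
) -> ClusterModel:
    """Latent class analysis: EM for a mixture of products of Bernoullis.

    The E-step computes posterior class responsibilities; the M-step updates
    class weights and item probabilities (clamped to [1e-6, 1-1e-6] to avoid
    log-domain collapse). The log-likelihood is non-decreasing each
    iteration; convergence when its change falls below ``tol``. The best of
    ``n_starts`` random restarts by final log-likelihood is returned; hard
    labels are the posterior argmax.
    """
    data = X.values
    n, p = data.shape
    if k < 1:
        raise ClusteringError("k must be at least 1")
    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        if k == 1:
            weights = np.ones(1)
            theta = np.clip(
                data.mean(axis=0, keepdims=True), LCA_PROB_FLOOR, 1 - LCA_PROB_FLOOR
            )
        else:
            weights = np.full(k, 1.0 / k)
            theta = np.clip(
                rng.uniform(0.25, 0.75, size=(k, p)), LCA_PROB_FLOOR, 1 - LCA_PROB_FLOOR
            )
        trace: list[float] = []
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            log_members = _lca_log_members(data, weights, theta)
            ll_rows = logsumexp(log_members, axis=1)
            ll = float(ll_rows.sum())
            trace.append(ll)
            resp = np.exp(log_members - ll_rows[:, None])
            nk = resp.sum(axis=0)
            weights = np.clip(nk / n, 1e-12, None)
            weights = weights / weights.sum()
            theta = np.clip(
                resp.T @ data.astype(float) / np.maximum(nk[:, None], 1e-12),
                LCA_PROB_FLOOR,
                1 - LCA_PROB_FLOOR,
            )
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                converged = True
                break
            prev_ll = ll
        log_members = _lca_log_members(data, weights, theta)
        final_ll = float(logsumexp(log_members, axis=1).sum())
        if best is None or final_ll > best[0]:
            best = (final_ll, weights, theta, trace, converged, log_members)
        if k == 1:
            break  # closed-form optimum; restarts are identical
    final_ll, weights, theta, trace, converged, log_members = best
    labels = log_members.argmax(axis=1)
    return ClusterModel(
        method="lca",
        k=k,
        labels=labels,
        centers={"class_weights": weights, "item_probs": theta},
        objective=final_ll,
        objective_trace=trace,
        n_iterations=len(trace),
        seed=seed,
        converged=converged,
        extras={"n_persons": n, "n_conditions": p},
    )


def ahc_linkage(X: ConditionMatrix, linkage_method: str = "average") -> list[tuple]:
    """Full agglomerative merge tree under a deterministic tie rule.

    Lance–Williams agglomeration on matching dissimilarity (``average`` or
    ``complete``) or on squared Euclidean distance for ``ward_on_binary``
    (identical to matching dissimilarity on 0/1 data at the leaves). At each
    step the closest active pair merges; ties are broken by the lowest
    (row-major) pair index, so the tree is deterministic given the row
    order. Returns the merge list [(i, j, height)] where i < j are the
    surviving and absorbed cluster representatives (original row indices).
    """
    data = X.values.astype(float)
    n, p = data.shape
    if linkage_method in ("average", "complete"):
        D = squareform(pdist(data, metric="hamming") * p)
    elif linkage_method == "ward_on_binary":
        D = squareform(pdist(data, metric="sqeuclidean"))
    else:
        raise ClusteringError(f"unknown linkage {linkage_method!r}")
    D = D.astype(float)
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    merges: list[tuple] = []
    for _ in range(n - 1):
        flat = int(np.argmin(D))  # row-major => lowest-index tie break
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        height = D[i, j]
        ni, nj = sizes[i], sizes[j]
        others = active.copy()
        others[[i, j]] = False
        if linkage_method == "average":
            new = (ni * D[i, others] + nj * D[j, others]) / (ni + nj)
        elif linkage_method == "complete":
            new = np.maximum(D[i, others], D[j, others])
        else:  # ward on squared Euclidean
            nl = sizes[others]
            new = (
                (ni + nl) * D[i, others]
                + (nj + nl) * D[j, others]
                - nl * height
            ) / (ni + nj + nl)
        D[i, others] = new
        D[others, i] = new
        D[j, :] = np.inf
        D[:, j] = np.inf
        active[j] = False
        sizes[i] = ni + nj
        merges.append((i, j, float(height)))
    return merges


def cut_merges(merges: list[tuple], n: int, k: int) -> np.ndarray:
    """Labels after replaying the first n-k merges, numbered by first appearance."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in merges[: n - k]:
        parent[find(j)] = find(i)
    labels = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for row in range(n):
        root = find(row)
        if root not in mapping:
            mapping[root] = len(mapping)
        labels[row] = mapping[root]
    return labels


def ahc_fit(
    X: ConditionMatrix,
    k: int,
    linkage_method: str = "average",
    merges: list[tuple] | None = None,
) -> ClusterModel:
    """Agglomerative hierarchical clustering cut to k clusters.

    Deterministic given the data ordering (see :func:`ahc_linkage` for the
    tie rule). Clusters are numbered 0..k-1 by first appearance. The
    objective reported is the total matching dissimilarity to per-cluster
    modes, comparable with k-modes. A precomputed ``merges`` tree (from
    :func:`ahc_linkage`) can be reused across cuts at different k.
    """
    n = X.n_persons
    if not 1 <= k <= n:
        raise ClusteringError(f"k must lie in [1, n_persons]; got k={k}, n={n}")
    if merges is None:
        merges = ahc_linkage(X, linkage_method)
    labels = cut_merges(merges, n, k)
    cost = kmodes_cost(X, labels, k)
    return ClusterModel(
        method="ahc",
        k=k,
        labels=labels,
        centers={"merges": merges, "linkage_method": linkage_method},
        objective=cost,
        objective_trace=[cost],
        n_iterations=n - 1,
        seed=None,
        converged=True,
    )


def run_repeats(
    method: str,
    X: ConditionMatrix,
    k: int,
    n_repeats: int = 5,
    seeds: Sequence[int] | None = None,
    **kwargs,
) -> list[ClusterModel]:
    """Run a method across seeds: five seeded repeats for the
    initialisation-sensitive methods (k-modes, LCA), one run for the
    deterministic ones (PAM, AHC)."""
    if method not in METHODS:
        raise ClusteringError(f"unknown method {method!r}")
    if method in STOCHASTIC_METHODS:
        if seeds is None:
            seeds = list(range(n_repeats))
        fitter = {"kmodes": kmodes_fit, "lca": lca_fit}[method]
        if method == "kmodes" and "init" not in kwargs and "init_modes" not in kwargs:
            # repeats need a randomisable initialisation; the Cao default is
            # deterministic, so seeded Huang starts are used unless overridden
            kwargs = {**kwargs, "init": "huang"}
        return [fitter(X, k, seed=s, **kwargs) for s in seeds]
    logger.info("%s is deterministic; running once regardless of n_repeats", method)
    fitter = {"kmedoids": kmedoids_fit, "ahc": ahc_fit}[method]
    return [fitter(X, k, **kwargs)]
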