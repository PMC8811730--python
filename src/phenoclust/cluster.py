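"""Clustering of z-scored phenotype vectors into reference phenotypes.

Two dissimilarities are supported on z-scored vectors:

* ``sed`` — squared Euclidean distance, ``||u - v||^2``; clusters are
  compact in every dimension on a common scale.
* ``cd`` — cosine distance, ``1 - cos(theta)``; vectors pointing the same
  way cluster together regardless of magnitude, which groups phenotypes by
  the *direction* of their rate pattern.

k-means uses k-means++ seeding and best-of-replicates Lloyd iteration; with
the cosine metric the update is spherical k-means (centroid = renormalized
mean of the assigned unit vectors).  DBSCAN sorts vectors into
core/border/noise points given a neighbourhood radius ``eps`` and a minimum
neighbour count ``min_samples`` (rule of thumb: twice the dimensionality).

Whatever the metric, each cluster's *reference phenotype* (the re-scaled
centroid zeta) is the per-dimension median of the raw, un-normalized rate
vectors assigned to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.utils.validation import check_array, check_is_fitted

from .rates import RateVector, vectors_to_matrix
from .registry import CompoundSpec, default_registry

__all__ = [
    "NOISE",
    "dist_sed",
    "dist_cd",
    "PhenotypeKMeans",
    "PhenotypeDBSCAN",
    "ClusterModel",
    "kmeans_cluster",
    "dbscan_cluster",
    "evaluate_k",
    "sweep_dbscan",
    "default_np_min",
]

logger = logging.getLogger(__name__)

#: label given to DBSCAN noise points (clusters are numbered 1..k)
NOISE = -1


def dist_sed(u, v) -> float:
    """Squared Euclidean distance between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    d = u - v
    return float(d @ d)


def dist_cd(u, v) -> float:
    """Cosine distance ``1 - cos(theta)`` between two nonzero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero-norm vector")
    return float(1.0 - (u @ v) / (nu * nv))


def _pairwise(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    """(n, k) dissimilarity matrix between rows of X and centroids C."""
    if metric == "sed":
        return cdist(X, C, "sqeuclidean")
    if metric == "cd":
        return cdist(X, C, "cosine")
    raise ValueError(f"unknown metric {metric!r}")


class PhenotypeKMeans(BaseEstimator, ClusterMixin):
    """k-means under squared-Euclidean or cosine dissimilarity.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    metric : {'sed', 'cd'}
        Dissimilarity.  With ``'cd'`` the fit is spherical k-means: inputs
        are unit-normalized and centroids are renormalized means.
    n_replicates : int, default 1
        Independent k-means++ restarts; the solution with the lowest total
        within-cluster dissimilarity is kept.
    max_iter : int, default 300
    random_state : int or None
        Seed; fits are deterministic given the seed.

    Attributes
    ----------
    labels_ : (n,) int array, clusters numbered 0..k-1 (ties to the lowest
        index).
    cluster_centers_ : (k, m) centroids in z-space (unit rows for ``'cd'``).
    inertia_ : total within-cluster point-to-centroid dissimilarity.
    objective_history_ : per-iteration objective of the winning replicate
        (non-increasing).
    """

    def __init__(self, n_clusters: int = 8, metric: str = "cd",
                 n_replicates: int = 1, max_iter: int = 300,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.metric = metric
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "cd":
            norms = np.linalg.norm(X, axis=1)
            if np.any(norms == 0):
                raise ValueError(
                    "zero-norm vector(s) cannot be clustered under cosine "
                    "distance; drop them upstream"
                )
            return X / norms[:, None]
        return X

    def _init_pp(self, Xw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """k-means++ seeding: next center sampled with probability
        proportional to the current dissimilarity to the closest center."""
        n = Xw.shape[0]
        centers = np.empty((self.n_clusters, Xw.shape[1]))
        first = rng.integers(n)
        centers[0] = Xw[first]
        dmin = _pairwise(Xw, centers[:1], self.metric)[:, 0]
        for c in range(1, self.n_clusters):
            total = dmin.sum()
            if total <= 0:
                idx = rng.integers(n)
            else:
                idx = rng.choice(n, p=dmin / total)
            centers[c] = Xw[idx]
            dmin = np.minimum(dmin, _pairwise(Xw, centers[c : c + 1], self.metric)[:, 0])
        return centers

    def _update_centers(self, Xw, labels, centers):
        new = centers.copy()
        for c in range(self.n_clusters):
            members = Xw[labels == c]
            if len(members) == 0:
                continue
            m = members.mean(axis=0)
            if self.metric == "cd":
                norm = np.linalg.norm(m)
                m = m / norm if norm > 0 else centers[c]
            new[c] = m
        return new

    def _lloyd(self, Xw: np.ndarray, rng: np.random.Generator):
        centers = self._init_pp(Xw, rng)
        history: list[float] = []
        labels = None
        for _ in range(self.max_iter):
            D = _pairwise(Xw, centers, self.metric)
            new_labels = D.argmin(axis=1)
            # empty-cluster repair: reseed with the farthest point
            for c in range(self.n_clusters):
                if not np.any(new_labels == c):
                    far = D[np.arange(len(Xw)), new_labels].argmax()
                    centers[c] = Xw[far]
                    new_labels[far] = c
                    D[:, c] = _pairwise(Xw, centers[c : c + 1], self.metric)[:, 0]
            obj = float(D[np.arange(len(Xw)), new_labels].sum())
            history.append(obj)
            if labels is not None and np.array_equal(labels, new_labels):
                break
            labels = new_labels
            centers = self._update_centers(Xw, labels, centers)
        # final objective against the final centers
        D = _pairwise(Xw, centers, self.metric)
        labels = D.argmin(axis=1)
        obj = float(D[np.arange(len(Xw)), labels].sum())
        history.append(obj)
        return labels, centers, obj, history

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        X = check_array(X)
        if self.n_clusters > X.shape[0]:
            raise ValueError("n_clusters cannot exceed the number of vectors")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        Xw = self._prepare(X)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_replicates):
            labels, centers, obj, history = self._lloyd(Xw, rng)
            if best is None or obj < best[2]:
                best = (labels, centers, obj, history)
        self.labels_, self.cluster_centers_, self.inertia_, self.objective_history_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        Xw = self._prepare(check_array(X))
        return _pairwise(Xw, self.cluster_centers_, self.metric).argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def default_np_min(n_dimensions: int) -> int:
    """DBSCAN minimum-neighbour default: twice the dimensionality."""
    return 2 * n_dimensions


class PhenotypeDBSCAN(BaseEstimator, ClusterMixin):
    """DBSCAN under squared-Euclidean or cosine dissimilarity.

    Clusters are renumbered 1..k by first appearance in the input order;
    noise points get the label ``NOISE`` (-1).  ``frac_clustered_`` and
    ``frac_in_cluster1_`` are the screening diagnostics: the proportion of
    non-noise points, and the proportion of *clustered* points that sit in
    cluster 1.
    """

    def __init__(self, eps: float = 0.5, min_samples: int | None = None,
                 metric: str = "sed"):
        self.eps = eps
        self.min_samples = min_samples
        self.metric = metric

    def fit(self, X, y=None):
        X = check_array(X)
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        min_samples = (
            self.min_samples if self.min_samples is not None
            else default_np_min(X.shape[1])
        )
        if min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        sk_metric = {"sed": "sqeuclidean", "cd": "cosine"}[self.metric]
        raw = DBSCAN(eps=self.eps, min_samples=min_samples, metric=sk_metric,
                     algorithm="brute").fit(X).labels_
        # renumber by first appearance
        mapping: dict[int, int] = {}
        labels = np.empty_like(raw)
        for i, lab in enumerate(raw):
            if lab == -1:
                labels[i] = NOISE
            else:
                if lab not in mapping:
                    mapping[lab] = len(mapping) + 1
                labels[i] = mapping[lab]
        self.labels_ = labels
        self.n_clusters_ = len(mapping)
        n = len(labels)
        n_clustered = int((labels != NOISE).sum())
        self.frac_clustered_ = n_clustered / n if n else 0.0
        self.frac_in_cluster1_ = (
            int((labels == 1).sum()) / n_clustered if n_clustered else 0.0
        )
        self.min_samples_ = min_samples
        return self


@dataclass
class ClusterModel:
    """A fitted clustering of phenotype vectors.

    ``labels`` are 1..k (k-means) or 1..k plus ``NOISE`` (DBSCAN), aligned
    with ``index`` (experiment_id, time) pairs.  ``z_centroids`` live in
    z-space; ``raw_centroids`` are the reference phenotypes zeta — per-
    dimension medians of the raw rate vectors of each cluster, in registry
    dimension order (mu first).
    """

    method: str
    metric: str
    k: int
    labels: np.ndarray
    index: list[tuple[str, float]]
    z_centroids: np.ndarray | None
    raw_centroids: np.ndarray
    dimension_labels: list[str]
    params: dict = field(default_factory=dict)

    def assignments(self) -> dict[tuple[str, float], int]:
        return {key: int(lab) for key, lab in zip(self.index, self.labels)}

    def centroid(self, cluster: int) -> dict[str, float]:
        """Reference phenotype of one cluster as {dimension label: rate}."""
        row = self.raw_centroids[cluster - 1]
        return dict(zip(self.dimension_labels, row.tolist()))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(assignments, raw centroid) tables for delimited-text export."""
        assign = pd.DataFrame(
            {
                "experiment_id": [e for e, _ in self.index],
                "time_h": [t for _, t in self.index],
                "cluster": self.labels,
            }
        )
        cent = pd.DataFrame(self.raw_centroids, columns=self.dimension_labels)
        cent.insert(0, "cluster", np.arange(1, len(cent) + 1))
        return assign, cent

    def save(self, model_dir) -> None:
        """Write assignments.csv, centroids_raw.csv (and centroids_z.csv)."""
        from pathlib import Path

        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        assign, cent = self.to_frames()
        assign.to_csv(model_dir / "assignments.csv", index=False)
        cent.to_csv(model_dir / "centroids_raw.csv", index=False)
        if self.z_centroids is not None:
            z = pd.DataFrame(self.z_centroids, columns=self.dimension_labels)
            z.insert(0, "cluster", np.arange(1, len(z) + 1))
            z.to_csv(model_dir / "centroids_z.csv", index=False)
        meta = pd.DataFrame(
            [{"method": self.method, "metric": self.metric, "k": self.k}]
        )
        meta.to_csv(model_dir / "model.csv", index=False)

    @classmethod
    def load(cls, model_dir) -> "ClusterModel":
        from pathlib import Path

        model_dir = Path(model_dir)
        meta = pd.read_csv(model_dir / "model.csv").iloc[0]
        assign = pd.read_csv(model_dir / "assignments.csv")
        cent = pd.read_csv(model_dir / "centroids_raw.csv")
        dims = [c for c in cent.columns if c != "cluster"]
        z_path = model_dir / "centroids_z.csv"
        z = (
            pd.read_csv(z_path)[dims].to_numpy() if z_path.exists() else None
        )
        return cls(
            method=str(meta["method"]),
            metric=str(meta["metric"]),
            k=int(meta["k"]),
            labels=assign["cluster"].to_numpy(dtype=int),
            index=[
                (str(e), float(t))
                for e, t in zip(assign["experiment_id"], assign["time_h"])
            ],
            z_centroids=z,
            raw_centroids=cent[dims].to_numpy(),
            dimension_labels=dims,
        )


def _raw_medians(raw: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    out = np.full((k, raw.shape[1]), np.nan)
    for c in range(1, k + 1):
        members = raw[labels == c]
        if len(members):
            out[c - 1] = np.median(members, axis=0)
    return out


def _model_inputs(
    vectors: Sequence[RateVector], registry: Sequence[CompoundSpec] | None
) -> tuple[np.ndarray, list[tuple[str, float]], list[str], list[CompoundSpec]]:
    registry = list(registry) if registry is not None else default_registry()
    raw = vectors_to_matrix(vectors, registry)
    index = [(v.experiment_id, v.time) for v in vectors]
    dims = ["mu"] + [c.abbreviation for c in registry if c.role != "biomass"]
    return raw, index, dims, registry


def kmeans_cluster(
    z_vectors: np.ndarray,
    vectors: Sequence[RateVector],
    k: int,
    metric: str = "cd",
    replicates: int = 20,
    seed: int | None = None,
    registry: Sequence[CompoundSpec] | None = None,
) -> ClusterModel:
    """Best-of-replicates k-means of z-scored vectors; raw-median centroids."""
    raw, index, dims, _ = _model_inputs(vectors, registry)
    est = PhenotypeKMeans(
        n_clusters=k, metric=metric, n_replicates=replicates, random_state=seed
    ).fit(np.asarray(z_vectors, dtype=float))
    labels = est.labels_ + 1
    return ClusterModel(
        method="kmeans",
        metric=metric,
        k=k,
        labels=labels,
        index=index,
        z_centroids=est.cluster_centers_,
        raw_centroids=_raw_medians(raw, labels, k),
        dimension_labels=dims,
        params={"replicates": replicates, "seed": seed, "inertia": est.inertia_},
    )


def dbscan_cluster(
    z_vectors: np.ndarray,
    vectors: Sequence[RateVector],
    eps: float,
    np_min: int | None = None,
    metric: str = "sed",
    registry: Sequence[CompoundSpec] | None = None,
) -> ClusterModel:
    """DBSCAN of z-scored vectors; raw-median centroids of each cluster."""
    raw, index, dims, _ = _model_inputs(vectors, registry)
    est = PhenotypeDBSCAN(eps=eps, min_samples=np_min, metric=metric).fit(
        np.asarray(z_vectors, dtype=float)
    )
    return ClusterModel(
        method="dbscan",
        metric=metric,
        k=est.n_clusters_,
        labels=est.labels_,
        index=index,
        z_centroids=None,
        raw_centroids=_raw_medians(raw, est.labels_, est.n_clusters_),
        dimension_labels=dims,
        params={
            "eps": eps,
            "np_min": est.min_samples_,
            "frac_clustered": est.frac_clustered_,
            "frac_in_cluster1": est.frac_in_cluster1_,
        },
    )


_CRITERIA = ("silhouette", "gap", "davies_bouldin", "calinski_harabasz")


def evaluate_k(
    z_vectors: np.ndarray,
    criterion: str = "silhouette",
    metric: str = "cd",
    k_max: int = 30,
    seed: int | None = None,
    gap_b: int = 50,
) -> tuple[pd.DataFrame, int]:
    """Score k-means clusterings over a range of k and pick the optimum.

    One k-means run (single replicate) per k.  Silhouette and the Gap
    statistic work with either metric; the Davies-Bouldin and
    Calinski-Harabasz criteria are defined for Euclidean geometry and are
    only allowed with ``metric='sed'``.  The optimum maximizes silhouette /
    Calinski-Harabasz, minimizes Davies-Bouldin, and for Gap is the
    smallest k with ``Gap(k) >= Gap(k+1) - s(k+1)`` (one-standard-error
    rule, uniform reference over the per-dimension data range).
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion in ("davies_bouldin", "calinski_harabasz") and metric != "sed":
        raise ValueError(f"criterion {criterion!r} is only defined with metric 'sed'")
    X = np.asarray(z_vectors, dtype=float)
    n = X.shape[0]
    k_min = 1 if criterion == "gap" else 2
    ks = [k for k in range(k_min, k_max + 1) if k <= n]
    rng = np.random.default_rng(seed)

    def _fit(data: np.ndarray, k: int, seed_: int) -> PhenotypeKMeans:
        return PhenotypeKMeans(
            n_clusters=k, metric=metric, n_replicates=1, random_state=seed_
        ).fit(data)

    rows = []
    if criterion == "gap":
        lo, hi = X.min(axis=0), X.max(axis=0)
        # reference draws are shared across k so Gap(k) curves are comparable
        refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(gap_b)]
        gaps, sks = [], []
        for k in ks:
            logW = np.log(_fit(X, k, int(rng.integers(2**31))).inertia_)
            logWstar = np.array(
                [np.log(_fit(R, k, int(rng.integers(2**31))).inertia_) for R in refs]
            )
            gap = float(logWstar.mean() - logW)
            sk = float(logWstar.std(ddof=0) * np.sqrt(1 + 1 / gap_b))
            gaps.append(gap)
            sks.append(sk)
            rows.append({"k": k, "score": gap, "sk": sk})
        optimal = ks[-1]
        for i in range(len(ks) - 1):
            if gaps[i] >= gaps[i + 1] - sks[i + 1]:
                optimal = ks[i]
                break
    else:
        sk_metric = {"sed": "sqeuclidean", "cd": "cosine"}[metric]
        for k in ks:
            est = _fit(X, k, int(rng.integers(2**31)))
            labels = est.labels_
            if criterion == "silhouette":
                score = silhouette_score(X, labels, metric=sk_metric)
            elif criterion == "davies_bouldin":
                score = davies_bouldin_score(X, labels)
            else:
                score = calinski_harabasz_score(X, labels)
            rows.append({"k": k, "score": float(score)})
        scores = [r["score"] for r in rows]
        idx = int(np.argmin(scores)) if criterion == "davies_bouldin" else int(np.argmax(scores))
        optimal = ks[idx]
    return pd.DataFrame(rows), int(optimal)


def sweep_dbscan(
    z_vectors: np.ndarray,
    eps_grid: Sequence[float],
    np_min: int | None = None,
    metric: str = "sed",
) -> pd.DataFrame:
    """DBSCAN screening: one row of diagnostics per eps value."""
    if len(eps_grid) == 0:
        raise ValueError("empty eps grid")
    X = np.asarray(z_vectors, dtype=float)
    rows = []
    for eps in eps_grid:
        est = PhenotypeDBSCAN(eps=float(eps), min_samples=np_min, metric=metric).fit(X)
        rows.append(
            {
                "eps": float(eps),
                "n_clusters": est.n_clusters_,
                "frac_clustered": est.frac_clustered_,
                "frac_in_cluster1": est.frac_in_cluster1_,
            }
        )
    return pd.DataFrame(rows)
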