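"""Superposition decomposition: a phenotype as a mixture of references.

Any observed phenotype vector a (or a whole time course of them) can be
approximated as a non-negative combination of the k reference-cluster
centroids.  After per-dimension rescaling of centroids and query to [0, 1]
(so no dimension dominates by scale), the non-negative least-squares
problem

    min_x || A** x - a** ||^2,   x >= 0

is solved with the deterministic active-set algorithm; the coefficients are
rendered as percentages x_CL / sum(x) * 100.  The residual-sum-of-squares
RSS = ||A** x - a**||^2 measures how well the references span the query.
For time courses, each proportion trace is smoothed with a Gaussian-
weighted moving average (window of five points) to damp sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .cluster import ClusterModel
from .rates import RateVector
from .registry import CompoundSpec, default_registry

__all__ = [
    "SuperpositionFit",
    "rescale_01",
    "nnls_decompose",
    "decompose_timecourse",
    "SuperpositionDecomposer",
    "gaussian_smooth",
]

logger = logging.getLogger(__name__)


@dataclass
class SuperpositionFit:
    """NNLS mixture description of one query phenotype."""

    query_id: tuple[str, float] | None
    coefficients: np.ndarray  # (k,), >= 0
    proportions: np.ndarray | None  # (k,) percentages summing to 100, or None
    residual: np.ndarray  # (m,) residual vector y**
    rss: float

    @property
    def dominant_cluster(self) -> int | None:
        """1-based index of the largest proportion (None if undefined)."""
        if self.proportions is None:
            return None
        return int(np.argmax(self.proportions)) + 1


def rescale_01(
    centroids: np.ndarray,
    queries: np.ndarray,
    pool_queries: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-dimension affine map of centroids (and queries) onto [0, 1].

    For each dimension the min and max are taken over the pooled set of
    centroid values and (by default) query values; the same map is applied
    to both, so queries may fall outside [0, 1] when ``pool_queries=False``.
    Dimensions with zero spread are dropped (warned).  Returns
    ``(A**, a**, kept_dims)`` with ``A**`` of shape (m', k) and queries of
    shape (n, m').
    """
    C = np.atleast_2d(np.asarray(centroids, dtype=float))  # (k, m)
    Q = np.atleast_2d(np.asarray(queries, dtype=float))  # (n, m)
    if C.shape[1] != Q.shape[1]:
        raise ValueError("centroids and queries must share dimensions")
    pooled = np.vstack([C, Q]) if pool_queries else C
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    spread = hi - lo
    keep = spread > 0
    if not np.any(keep):
        raise ValueError("all values identical in every dimension; cannot rescale")
    if not np.all(keep):
        logger.warning(
            "dropping %d zero-spread dimension(s) before rescaling",
            int((~keep).sum()),
        )
    A = ((C[:, keep] - lo[keep]) / spread[keep]).T  # (m', k)
    q = (Q[:, keep] - lo[keep]) / spread[keep]  # (n, m')
    return A, q, np.flatnonzero(keep)


def nnls_decompose(
    A: np.ndarray, a: np.ndarray, query_id: tuple[str, float] | None = None
) -> SuperpositionFit:
    """Solve the NNLS problem for one rescaled query vector.

    Proportions are ``100 * x / sum(x)``; when every coefficient is zero
    (query outside the non-negative cone) they are undefined (None) and
    RSS equals ``||a**||^2``.
    """
    A = np.asarray(A, dtype=float)
    a = np.asarray(a, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != a.size:
        raise ValueError(f"shape mismatch: A {A.shape} vs query {a.shape}")
    x, _ = nnls(A, a)
    resid = A @ x - a
    rss = float(resid @ resid)
    total = x.sum()
    proportions = 100.0 * x / total if total > 0 else None
    return SuperpositionFit(
        query_id=query_id,
        coefficients=x,
        proportions=proportions,
        residual=resid,
        rss=rss,
    )


def gaussian_smooth(
    traces: np.ndarray, window: int = 5, sigma: float | None = None
) -> np.ndarray:
    """Gaussian-weighted moving average along axis 0.

    ``sigma`` defaults to ``(window - 1) / 5`` index units (0.8 for the
    5-point window); at the edges the weights are renormalized over the
    available points.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return np.asarray(traces, dtype=float).copy()
    if sigma is None:
        sigma = (window - 1) / 5.0
    arr = np.asarray(traces, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[:, None]
    n = arr.shape[0]
    half = window // 2
    offsets = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (offsets / sigma) ** 2)
    out = np.empty_like(arr)
    for i in range(n):
        sel = (i + offsets >= 0) & (i + offsets < n)
        idx = i + offsets[sel]
        ww = w[sel] / w[sel].sum()
        out[i] = ww @ arr[idx]
    return out.ravel() if one_d else out


class SuperpositionDecomposer(BaseEstimator, TransformerMixin):
    """Transformer mapping raw phenotype vectors to cluster proportions.

    Fit on a (k, m) matrix of reference centroids; ``transform`` rescales
    each query together with the centroids and solves NNLS, returning the
    (n, k) matrix of proportions (NaN rows where undefined).
    """

    def __init__(self, pool_queries: bool = True):
        self.pool_queries = pool_queries

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 reference centroids")
        self.centroids_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def decompose(self, X) -> list[SuperpositionFit]:
        check_is_fitted(self, "centroids_")
        X = check_array(X)
        fits = []
        for row in X:
            A, q, _ = rescale_01(
                self.centroids_, row[None, :], pool_queries=self.pool_queries
            )
            fits.append(nnls_decompose(A, q[0]))
        return fits

    def transform(self, X) -> np.ndarray:
        fits = self.decompose(X)
        k = self.centroids_.shape[0]
        out = np.full((len(fits), k), np.nan)
        for i, f in enumerate(fits):
            if f.proportions is not None:
                out[i] = f.proportions
        return out


def decompose_timecourse(
    vectors: Sequence[RateVector],
    model: ClusterModel,
    smooth_window: int = 5,
    registry: Sequence[CompoundSpec] | None = None,
    pool_queries: bool = True,
) -> tuple[list[SuperpositionFit], pd.DataFrame]:
    """Describe one experiment's time course as cluster proportions.

    ``vectors`` must be time-ordered phenotypes of a single experiment.
    Each time point is rescaled (together with the model's raw centroids)
    and NNLS-decomposed; the proportion traces are then smoothed with the
    Gaussian window and renormalized to sum to 100.  Returns the per-point
    fits plus a tidy table (time_h, RSS, pct_cluster_1..k, smoothed).
    """
    if len(vectors) < 1:
        raise ValueError("need at least one vector")
    exp_ids = {v.experiment_id for v in vectors}
    if len(exp_ids) > 1:
        raise ValueError(f"vectors span several experiments: {sorted(exp_ids)}")
    times = [v.time for v in vectors]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("vectors must be strictly time-ordered")
    registry = list(registry) if registry is not None else default_registry()
    X = np.vstack([v.as_array(registry) for v in vectors])
    dec = SuperpositionDecomposer(pool_queries=pool_queries).fit(model.raw_centroids)
    fits = dec.decompose(X)
    for f, v in zip(fits, vectors):
        f.query_id = (v.experiment_id, v.time)
    k = model.raw_centroids.shape[0]
    raw_props = np.full((len(fits), k), np.nan)
    for i, f in enumerate(fits):
        if f.proportions is not None:
            raw_props[i] = f.proportions
    smoothed = gaussian_smooth(np.nan_to_num(raw_props), window=smooth_window)
    totals = smoothed.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(totals[:, None] > 0, 100.0 * smoothed / totals[:, None], np.nan)
    table = pd.DataFrame({"time_h": times, "RSS": [f.rss for f in fits]})
    for c in range(k):
        table[f"pct_cluster_{c + 1}"] = smoothed[:, c]
    return fits, table
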