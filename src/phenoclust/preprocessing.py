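"""Z-score normalization of phenotype vectors.

Rate dimensions differ in scale by orders of magnitude (mu ~ 0.1/h,
substrate uptake ~ 10 mmol/g/h); without normalization the large dimensions
dominate every distance.  Each dimension is centered on its mean and scaled
by its sample standard deviation (denominator n - 1), z = (a - abar) / S.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["ZScoreScaler", "zscore_fit", "zscore_apply"]


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Center and scale each dimension by its sample standard deviation.

    Unlike the population-variance convention of ``StandardScaler``, the
    scale is the *sample* standard deviation (ddof=1).  A dimension with
    zero spread cannot be normalized and raises at fit time, naming the
    offending column.

    Attributes
    ----------
    mean_ : ndarray of shape (m,)
        Per-dimension mean of the fitting set.
    scale_ : ndarray of shape (m,)
        Per-dimension sample standard deviation (ddof=1).
    """

    def __init__(self, dimension_labels: Sequence[str] | None = None):
        self.dimension_labels = dimension_labels

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(self.scale_ == 0)
        if zero.size:
            labels = (
                [self.dimension_labels[i] for i in zero]
                if self.dimension_labels is not None
                else list(zero)
            )
            raise ValueError(f"zero-spread dimension(s), cannot z-score: {labels}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = check_array(Z)
        return Z * self.scale_ + self.mean_


def zscore_fit(X, dimension_labels: Sequence[str] | None = None) -> ZScoreScaler:
    """Fit a :class:`ZScoreScaler` on an (n, m) matrix of rate vectors."""
    return ZScoreScaler(dimension_labels=dimension_labels).fit(X)


def zscore_apply(model: ZScoreScaler, X) -> np.ndarray:
    """Apply a fitted scaler, returning the z-scored vectors."""
    return model.transform(X)
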