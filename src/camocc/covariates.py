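"""Site-covariate preparation: standardization and collinearity pruning.

Land-cover proportions and distance covariates are z-scored (sample SD,
n-1 denominator) so that effect sizes are comparable across covariates,
and pairwise-collinear covariates (|Pearson r| above a threshold, 0.7 by
default) are pruned before model fitting.  Both steps are exposed as
scikit-learn transformers so they compose with pipelines, plus thin
functional wrappers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CovariateStandardizer",
    "CollinearityPruner",
    "zscore",
    "prune_correlated",
    "proportions",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class CovariateStandardizer(TransformerMixin, BaseEstimator):
    """Z-score covariates column-wise using the sample standard deviation.

    Unlike ``sklearn.preprocessing.StandardScaler`` this uses the n-1
    denominator, so a standardized column has sample SD exactly 1.  The
    fitted means and SDs are kept for back-transforming effect plots.

    Attributes
    ----------
    mean_, scale_ : Series
        Per-column mean and sample SD estimated at fit time.
    """

    def fit(self, X, y=None):
        frame = _as_frame(X)
        if not np.isfinite(frame.to_numpy(dtype=float)[~frame.isna().to_numpy()]).all():
            raise ValueError("covariates contain non-finite values")
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.mean_ = frame.mean()
        self.scale_ = frame.std(ddof=1)
        constant = self.scale_[self.scale_ <= 1e-12].index.tolist()
        if constant:
            raise ValueError(f"constant column(s) cannot be standardized: {constant}")
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = _as_frame(X)
        return (frame - self.mean_) / self.scale_

    def inverse_transform(self, X) -> pd.DataFrame:
        frame = _as_frame(X)
        return frame * self.scale_ + self.mean_


class CollinearityPruner(TransformerMixin, BaseEstimator):
    """Drop covariates until no retained pair exceeds the |r| threshold.

    Greedy rule: repeatedly locate the worst offending pair (largest
    |Pearson r| strictly above ``threshold``, complete cases only) and drop
    its lower-priority member.  Priority defaults to column order; a pair
    at exactly the threshold is retained (strictly-greater rule).

    Parameters
    ----------
    threshold : float in (0, 1]
    priority : sequence of str, optional
        Columns listed earlier are preferred.  Unlisted columns rank after
        all listed ones, in column order.

    Attributes
    ----------
    kept_ : list of retained column names.
    dropped_ : list of (name, reason) tuples, in drop order.
    """

    def __init__(self, threshold: float = 0.7, priority=None):
        self.threshold = threshold
        self.priority = priority

    def fit(self, X, y=None):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        frame = _as_frame(X)
        cols = list(frame.columns)
        listed = [c for c in (self.priority or []) if c in cols]
        rank = {c: i for i, c in enumerate(listed)}
        for c in cols:
            rank.setdefault(c, len(rank))

        kept = list(cols)
        dropped: list[tuple[str, str]] = []
        while len(kept) > 1:
            corr = frame[kept].corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
            worst = corr[i, j]
            if not worst > self.threshold:
                break
            a, b = kept[i], kept[j]
            drop = b if rank[b] > rank[a] else a
            keep = a if drop == b else b
            dropped.append((drop, f"|r|={worst:.3f} with {keep}"))
            kept.remove(drop)
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.kept_ = kept
        self.dropped_ = dropped
        return self

    def transform(self, X) -> pd.DataFrame:
        return _as_frame(X)[self.kept_]


def zscore(cov: pd.DataFrame):
    """Standardize covariates; returns (standardized frame, fitted transformer)."""
    scaler = CovariateStandardizer().fit(cov)
    return scaler.transform(cov), scaler


def prune_correlated(cov: pd.DataFrame, threshold: float = 0.7, priority=None):
    """Prune collinear covariates; returns (pruned frame, drop log)."""
    pruner = CollinearityPruner(threshold=threshold, priority=priority).fit(cov)
    return pruner.transform(cov), list(pruner.dropped_)


def proportions(areas: pd.DataFrame, buffer_area: float) -> pd.DataFrame:
    """Convert per-site class areas (same units as ``buffer_area``) to fractions.

    Raises if any class area, or any site's total, exceeds the buffer area.
    """
    if buffer_area <= 0:
        raise ValueError("buffer_area must be positive")
    frame = _as_frame(areas)
    vals = frame.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("class areas must be non-negative")
    tol = buffer_area * 1e-9
    if (vals > buffer_area + tol).any():
        raise ValueError("a class area exceeds the buffer area")
    if (vals.sum(axis=1) > buffer_area + tol).any():
        raise ValueError("summed class areas exceed the buffer area at some site")
    return frame / buffer_area
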