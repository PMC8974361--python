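"""First-principal-component composite exposure indices with theta reliability.

Individual media sources are treated as noisy indicators of one underlying
quantity — what the communication environment as a whole is saying about
the topic.  The composite weights each source by its loading on the first
principal component of the inter-source correlation matrix; the internal
consistency of that weighted sum is theta,

    theta = (p / (p - 1)) * (1 - 1 / lambda_1),

the component-weighted analogue of Cronbach's alpha, where ``lambda_1`` is
the leading eigenvalue and ``p`` the number of items.  Sources whose
oriented loading is negative do not covary with the common factor and are
split out as standalone standardized variables, with the component refit on
the remainder.

The correlation (not covariance) matrix is used throughout because sources
live on wildly different scales — a daily newspaper probability sum near 4
against tens of thousands of tweets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "first_principal_component",
    "theta",
    "composite_scores",
    "loading_screen",
    "PCEIndex",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _orient(w: np.ndarray) -> np.ndarray:
    """Flip the eigenvector so the majority of loadings are positive
    (deterministic tie-break: make the first loading non-negative)."""
    pos, neg = int((w > 0).sum()), int((w < 0).sum())
    if neg > pos or (neg == pos and w[0] < 0):
        return -w
    return w


def first_principal_component(X) -> tuple[np.ndarray, float]:
    """Leading eigenvector (unit norm) and eigenvalue of the correlation matrix.

    Requires at least two columns, three complete rows, and no constant
    column (zero variance has no correlation).
    """
    M, _ = _as_matrix(X)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need at least two source columns")
    if M.shape[0] < 3:
        raise ValueError("need at least three rows")
    if np.isnan(M).any():
        raise ValueError("missing values: listwise-delete before the PCA")
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column (zero variance)")
    corr = np.corrcoef(M, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    lambda1 = float(eigval[-1])
    weights = _orient(eigvec[:, -1])
    return weights, lambda1


def theta(lambda1: float, p: int) -> float:
    """Composite reliability from the leading eigenvalue of p items.

    Equals 1 when all items are perfectly correlated (lambda_1 = p) and 0
    when they are independent (lambda_1 = 1); clipped to [0, 1].
    """
    if p < 2:
        raise ValueError("theta requires at least two items")
    if lambda1 < 1.0 - 1e-9:
        raise ValueError(
            "leading eigenvalue of a correlation matrix cannot be < 1; "
            "upstream input was probably not a correlation structure"
        )
    return float(np.clip((p / (p - 1)) * (1.0 - 1.0 / lambda1), 0.0, 1.0))


def composite_scores(X, weights) -> np.ndarray:
    """Standardized weighted sum of standardized columns (mean 0, SD 1)."""
    M, _ = _as_matrix(X)
    weights = np.asarray(weights, dtype=float)
    if M.shape[1] != weights.shape[0]:
        raise ValueError("weights do not match the number of columns")
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    s = Z @ weights
    return (s - s.mean()) / s.std(ddof=1)


def loading_screen(X, sources: list[str] | None = None):
    """Split sources into composite members and negatively loading outliers.

    Fits the first component over all candidates, drops every source with a
    strictly negative oriented loading, and refits on the survivors.

    Returns
    -------
    included : list of source names kept in the composite
    excluded : list of (source, loading) pairs screened out
    weights, lambda1 : refit first component over the included set
    """
    M, names = _as_matrix(X)
    if sources is not None:
        names = list(sources)
    w_all, _ = first_principal_component(M)
    keep = w_all >= 0
    excluded = [(names[i], float(w_all[i])) for i in np.flatnonzero(~keep)]
    included = [names[i] for i in np.flatnonzero(keep)]
    if len(included) < 2:
        raise ValueError("fewer than two sources load positively on the component")
    w, lam = first_principal_component(M[:, keep])
    return included, excluded, w, lam


class PCEIndex(TransformerMixin, BaseEstimator):
    """Composite media-coverage index as an sklearn transformer.

    ``fit`` learns the first-component weights over day-level source
    columns (optionally screening out negatively loading sources) and the
    standardization constants; ``transform`` returns the standardized
    composite score for each row.  Fitted on the data it scores, the output
    has mean 0 and SD 1.

    Parameters
    ----------
    screen_negative : bool, default True
        Exclude sources with strictly negative oriented loadings and refit
        the component on the remainder.

    Attributes
    ----------
    weights_ : loadings of the included sources on the first component
    lambda1_ : leading eigenvalue of their correlation matrix
    theta_ : composite reliability of the included set
    included_sources_, excluded_sources_ : the screening decision
    """

    def __init__(self, screen_negative: bool = True):
        self.screen_negative = screen_negative

    def fit(self, X, y=None) -> "PCEIndex":
        M, names = _as_matrix(X)
        if self.screen_negative:
            included, excluded, w, lam = loading_screen(M, names)
        else:
            w, lam = first_principal_component(M)
            included, excluded = list(names), []
        keep_idx = [names.index(n) for n in included]
        kept = M[:, keep_idx]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = M.shape[1]
        self.included_sources_ = included
        self.excluded_sources_ = excluded
        self._keep_idx = keep_idx
        self.weights_ = w
        self.lambda1_ = float(lam)
        self.theta_ = theta(self.lambda1_, len(included))
        self.col_means_ = kept.mean(axis=0)
        self.col_sds_ = kept.std(axis=0, ddof=1)
        raw = ((kept - self.col_means_) / self.col_sds_) @ self.weights_
        self.score_mean_ = float(raw.mean())
        self.score_sd_ = float(raw.std(ddof=1))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        M, _ = _as_matrix(X)
        if M.shape[1] == self.n_features_in_:
            M = M[:, self._keep_idx]
        elif M.shape[1] != len(self._keep_idx):
            raise ValueError("column count matches neither the full nor the screened set")
        raw = ((M - self.col_means_) / self.col_sds_) @ self.weights_
        return (raw - self.score_mean_) / self.score_sd_

    def summary(self) -> dict:
        """Weights, eigenvalue, theta and screening decision as plain JSON."""
        check_is_fitted(self, "weights_")
        return {
            "included_sources": list(self.included_sources_),
            "weights": [float(w) for w in self.weights_],
            "lambda1": self.lambda1_,
            "theta": self.theta_,
            "excluded_sources": [
                {"source": s, "loading": l} for s, l in self.excluded_sources_
            ],
        }
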