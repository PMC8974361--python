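"""Outcome models with survey weights and date-cluster-robust inference.

Respondents interviewed on the same day share identical media-exposure
scores, so observations are correlated within interview dates by
construction.  All inference here therefore clusters on date: the sandwich
variance sums score contributions within clusters, with the G/(G-1)
small-sample factor.  Survey weights enter the likelihood as importance
weights, which leaves coefficients invariant to rescaling all weights.

The module provides sklearn-style estimators (:class:`ClusteredLogit`,
:class:`ClusteredOLS`, :class:`RandomInterceptLogit`), thin functional
wrappers over them, the design builder for the intention and belief models,
model-implied adjusted predictions with delta-method intervals, and the
survey-side scale and validity statistics (Cronbach's alpha, intention to
follow-up behavior validity).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "SeparationError",
    "ModelResult",
    "ClusteredLogit",
    "ClusteredOLS",
    "RandomInterceptLogit",
    "fit_weighted_logistic",
    "fit_weighted_ols",
    "fit_random_intercept_logistic",
    "cluster_robust",
    "build_design",
    "adjusted_predictions",
    "cronbach_alpha",
    "predictive_validity",
    "derive_established_smoker",
    "derive_intention",
    "belief_scale",
]

Z95 = norm.ppf(0.975)


class SeparationError(RuntimeError):
    """The outcome is perfectly predicted; the MLE does not exist."""


# ---------------------------------------------------------------------------
# shared design / variance machinery


def _design(X, fit_intercept: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = [f"x{i+1}" for i in range(M.shape[1])]
    if fit_intercept:
        M = np.column_stack([np.ones(len(M)), M])
        names = ["const"] + names
    return M, names


def _check_weights(w, n: int) -> np.ndarray:
    if w is None:
        return np.ones(n)
    w = np.asarray(w, dtype=float)
    if len(w) != n:
        raise ValueError("sample_weight length mismatch")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


def _sandwich(bread: np.ndarray, scores: np.ndarray, clusters) -> tuple[np.ndarray, int]:
    """Cluster-robust covariance: bread @ meat @ bread with G/(G-1).

    ``scores`` holds per-observation score contributions (rows), summed
    within clusters to form the meat.  Invariant to cluster relabeling and
    within-cluster row order.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(scores):
        raise ValueError("clusters length mismatch")
    _, inv = np.unique(clusters, return_inverse=True)
    G = inv.max() + 1
    if G < 2:
        raise ValueError("cluster-robust variance needs at least two clusters")
    S = np.zeros((G, scores.shape[1]))
    np.add.at(S, inv, scores)
    meat = S.T @ S
    cov = bread @ meat @ bread * (G / (G - 1))
    return cov, int(G)


# ---------------------------------------------------------------------------
# results container


@dataclass
class ModelResult:
    """Coefficient table plus fit metadata for one fitted model."""

    family: str
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    nobs: int
    n_clusters: int | None
    converged: bool
    extra: dict = field(default_factory=dict)

    @property
    def conf_int(self) -> np.ndarray:
        lo = self.params - Z95 * self.bse
        hi = self.params + Z95 * self.bse
        return np.column_stack([lo, hi])

    @property
    def odds_ratios(self) -> np.ndarray:
        if self.family != "logit":
            raise AttributeError("odds ratios are defined for logistic models only")
        return np.exp(self.params)

    @property
    def pvalues(self) -> np.ndarray:
        z = np.divide(self.params, self.bse, out=np.full_like(self.params, np.nan),
                      where=self.bse > 0)
        return 2 * norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.terms,
        )
        if self.family == "logit":
            out.insert(0, "odds_ratio", np.exp(self.params))
            out["or_ci_low"] = np.exp(ci[:, 0])
            out["or_ci_high"] = np.exp(ci[:, 1])
        return out

    def to_json_dict(self) -> dict:
        d = {
            "family": self.family,
            "n": self.nobs,
            "n_clusters": self.n_clusters,
            "converged": self.converged,
            "terms": {
                t: {
                    "coef": float(b),
                    "se": float(s),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p": float(p),
                }
                for t, b, s, (lo, hi), p in zip(
                    self.terms, self.params, self.bse, self.conf_int, self.pvalues
                )
            },
        }
        if self.family == "logit":
            for t, orr in zip(self.terms, np.exp(self.params)):
                d["terms"][t]["odds_ratio"] = float(orr)
        d.update({k: v for k, v in self.extra.items()})
        return d


# ---------------------------------------------------------------------------
# weighted logistic regression (IRLS)


def _irls_logit(
    M: np.ndarray, y: np.ndarray, w: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, bool, np.ndarray]:
    """Maximize the weight-multiplied Bernoulli log-likelihood.

    Newton/IRLS with step-halving; converged when the largest absolute
    score component drops below ``tol``.  Raises :class:`SeparationError`
    when the fitted probabilities run to 0/1 while classifying perfectly.
    """
    n, k = M.shape
    beta = np.zeros(k)
    eta = M @ beta
    p = expit(eta)

    def loglik(p_):
        return float(w @ (y * np.log(np.clip(p_, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - p_, 1e-300, 1))))

    ll = loglik(p)
    converged = False
    for _ in range(max_iter):
        # separation first: a diverging fit drives the score to zero, so the
        # convergence test alone would silently accept an infinite MLE
        if np.max(np.abs(eta)) > 14:
            at_limit = (p < 1e-6) | (p > 1 - 1e-6)
            if at_limit.all() and np.all((p > 0.5) == (y > 0.5)):
                raise SeparationError(
                    "perfect separation: outcome exactly predicted, MLE diverges"
                )
        score = M.T @ (w * (y - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        W = w * p * (1 - p)
        H = (M * W[:, None]).T @ M
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular information matrix: design is rank deficient "
                "or the fit is degenerate"
            ) from err
        # step-halve if the likelihood does not improve
        for _ in range(30):
            beta_new = beta + step
            p_new = expit(M @ beta_new)
            ll_new = loglik(p_new)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        beta, p, ll = beta_new, p_new, ll_new
        eta = M @ beta
    return beta, converged, p


class ClusteredLogit(BaseEstimator):
    """Weighted logistic regression with date-cluster-robust inference.

    Fits by iteratively reweighted least squares on the importance-weighted
    Bernoulli likelihood; standard errors use the cluster sandwich when
    ``clusters`` is passed to :meth:`fit`, otherwise the inverse observed
    information.

    Parameters
    ----------
    fit_intercept : bool, default True
    tol : float, default 1e-8
        Convergence threshold on the largest absolute score component.
    max_iter : int, default 100

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients (sklearn layout)
    params_, bse_, cov_params_ : full coefficient vector and its covariance
    n_clusters_ : number of clusters used by the sandwich (None if classical)
    converged_ : bool
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None, clusters=None) -> "ClusteredLogit":
        M, names = _design(X, self.fit_intercept)
        y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        w = _check_weights(sample_weight, len(y))
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        beta, converged, p = _irls_logit(M, y, w, self.tol, self.max_iter)
        W = w * p * (1 - p)
        H = (M * W[:, None]).T @ M
        bread = np.linalg.inv(H)
        if clusters is not None:
            scores = M * (w * (y - p))[:, None]
            cov, G = _sandwich(bread, scores, clusters)
            self.n_clusters_ = G
        else:
            cov = bread
            self.n_clusters_ = None
        self.feature_names_ = names
        self.params_ = beta
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.converged_ = converged
        self.n_obs_ = len(y)
        self.intercept_ = beta[0] if self.fit_intercept else 0.0
        self.coef_ = beta[1:] if self.fit_intercept else beta
        self._bread = bread
        self._w = w
        self._y = y
        self._M = M
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        M, _ = _design(X, self.fit_intercept)
        p = expit(M @ self.params_)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def result(self) -> ModelResult:
        check_is_fitted(self, "params_")
        return ModelResult(
            family="logit",
            terms=self.feature_names_,
            params=self.params_.copy(),
            bse=self.bse_.copy(),
            nobs=self.n_obs_,
            n_clusters=self.n_clusters_,
            converged=self.converged_,
        )


class ClusteredOLS(BaseEstimator):
    """Weighted least squares with the same cluster sandwich as the logit."""

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y, sample_weight=None, clusters=None) -> "ClusteredOLS":
        M, names = _design(X, self.fit_intercept)
        y = np.asarray(y, dtype=float).ravel()
        w = _check_weights(sample_weight, len(y))
        H = (M * w[:, None]).T @ M
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        bread = np.linalg.inv(H)
        beta = bread @ (M.T @ (w * y))
        resid = y - M @ beta
        if clusters is not None:
            scores = M * (w * resid)[:, None]
            cov, G = _sandwich(bread, scores, clusters)
            self.n_clusters_ = G
        else:
            sigma2 = float((w * resid**2).sum() / max(len(y) - M.shape[1], 1))
            cov = bread * sigma2
            self.n_clusters_ = None
        self.feature_names_ = names
        self.params_ = beta
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.converged_ = True
        self.n_obs_ = len(y)
        self.intercept_ = beta[0] if self.fit_intercept else 0.0
        self.coef_ = beta[1:] if self.fit_intercept else beta
        self.resid_ = resid
        self._bread = bread
        self._w = w
        self._M = M
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        M, _ = _design(X, self.fit_intercept)
        return M @ self.params_

    def result(self) -> ModelResult:
        check_is_fitted(self, "params_")
        return ModelResult(
            family="ols",
            terms=self.feature_names_,
            params=self.params_.copy(),
            bse=self.bse_.copy(),
            nobs=self.n_obs_,
            n_clusters=self.n_clusters_,
            converged=True,
        )


# ---------------------------------------------------------------------------
# random-intercept logistic (sensitivity model)


class RandomInterceptLogit(BaseEstimator):
    """Logistic regression with a normal random intercept per cluster.

    The marginal likelihood integrates the cluster intercept out with
    fixed-node Gauss-Hermite quadrature (default 15 nodes) and is maximized
    by L-BFGS-B over (beta, sigma), sigma bounded at zero.  With sigma = 0
    the model reduces to the plain weighted logit.

    Attributes
    ----------
    params_, bse_ : fixed effects and (numerical-Hessian) standard errors
    sigma_ : estimated cluster intercept SD
    loglik_ : maximized marginal log-likelihood
    """

    def __init__(self, fit_intercept: bool = True, n_quad: int = 15):
        self.fit_intercept = fit_intercept
        self.n_quad = n_quad

    def _negll(self, theta, M, y, w, starts, counts, nodes, logwts):
        beta, sigma = theta[:-1], theta[-1]
        eta = M @ beta
        offs = np.sqrt(2.0) * sigma * nodes  # (K,)
        # per-observation loglik at each node: (n, K)
        e = eta[:, None] + offs[None, :]
        ll_obs = w[:, None] * (y[:, None] * e - np.logaddexp(0.0, e))
        ll_cluster = np.add.reduceat(ll_obs, starts, axis=0)  # (G, K)
        return -float(logsumexp(ll_cluster + logwts[None, :], axis=1).sum())

    def fit(self, X, y, clusters, sample_weight=None) -> "RandomInterceptLogit":
        M, names = _design(X, self.fit_intercept)
        y = np.asarray(y, dtype=float).ravel()
        w = _check_weights(sample_weight, len(y))
        clusters = np.asarray(clusters)
        uniq, inv = np.unique(clusters, return_inverse=True)
        if len(uniq) < 10:
            raise ValueError("random-intercept fit needs at least 10 clusters")
        order = np.argsort(inv, kind="stable")
        M, y, w, inv = M[order], y[order], w[order], inv[order]
        starts = np.flatnonzero(np.r_[True, np.diff(inv) > 0])
        counts = np.diff(np.r_[starts, len(inv)])
        x_gh, w_gh = hermgauss(self.n_quad)
        logwts = np.log(w_gh) - 0.5 * np.log(np.pi)

        start_logit = ClusteredLogit(fit_intercept=False).fit(M, y, sample_weight=w)
        x0 = np.r_[start_logit.params_, 0.5]
        from scipy.optimize import minimize

        bounds = [(None, None)] * M.shape[1] + [(0.0, 10.0)]
        res = minimize(
            self._negll, x0, args=(M, y, w, starts, counts, x_gh, logwts),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta_hat = res.x
        self._fit_args = (M, y, w, starts, counts)
        self._theta_hat = theta_hat
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.sigma_ = float(theta_hat[-1])
        self.params_ = theta_hat[:-1]
        self.feature_names_ = names
        self.n_obs_ = len(y)
        self.n_clusters_ = len(uniq)
        cov = self._hessian_cov(theta_hat, (M, y, w, starts, counts, x_gh, logwts))
        self.cov_params_ = cov[:-1, :-1]
        self.bse_ = np.sqrt(np.clip(np.diag(self.cov_params_), 0, None))
        self.sigma_se_ = float(np.sqrt(max(cov[-1, -1], 0.0)))
        return self

    def _hessian_cov(self, theta, args) -> np.ndarray:
        """Covariance from a central-difference Hessian of the negative LL."""
        d = len(theta)
        h = 1e-4 * np.maximum(1.0, np.abs(theta))
        Hm = np.zeros((d, d))
        f = lambda t: self._negll(t, *args)
        for i in range(d):
            for j in range(i, d):
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                Hm[i, j] = Hm[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(Hm)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(Hm)

    def marginal_loglik(self, n_quad: int | None = None) -> float:
        """Re-evaluate the marginal log-likelihood at the fitted parameters,
        optionally on a finer quadrature grid (a stability check: at
        convergence the value should barely move when nodes are doubled)."""
        check_is_fitted(self, "params_")
        if n_quad is None or n_quad == self.n_quad:
            return self.loglik_
        M, y, w, starts, counts = self._fit_args
        x_gh, w_gh = hermgauss(n_quad)
        logwts = np.log(w_gh) - 0.5 * np.log(np.pi)
        return -self._negll(self._theta_hat, M, y, w, starts, counts, x_gh, logwts)

    def result(self) -> ModelResult:
        check_is_fitted(self, "params_")
        return ModelResult(
            family="logit",
            terms=self.feature_names_,
            params=self.params_.copy(),
            bse=self.bse_.copy(),
            nobs=self.n_obs_,
            n_clusters=self.n_clusters_,
            converged=self.converged_,
            extra={"sigma": self.sigma_, "sigma_se": self.sigma_se_,
                   "loglik": self.loglik_},
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_weighted_logistic(y, X, weights=None, clusters=None, **kw) -> ModelResult:
    est = ClusteredLogit(**kw).fit(X, y, sample_weight=weights, clusters=clusters)
    return est.result()


def fit_weighted_ols(y, X, weights=None, clusters=None, **kw) -> ModelResult:
    est = ClusteredOLS(**kw).fit(X, y, sample_weight=weights, clusters=clusters)
    return est.result()


def fit_random_intercept_logistic(y, X, clusters, weights=None, **kw) -> ModelResult:
    est = RandomInterceptLogit(**kw).fit(X, y, clusters=clusters, sample_weight=weights)
    return est.result()


def cluster_robust(model: ClusteredLogit | ClusteredOLS, clusters) -> pd.DataFrame:
    """Recompute SEs/CIs/p-values of a fitted model under date clustering."""
    check_is_fitted(model, "params_")
    if isinstance(model, ClusteredLogit):
        p = expit(model._M @ model.params_)
        scores = model._M * (model._w * (model._y - p))[:, None]
    else:
        scores = model._M * (model._w * model.resid_)[:, None]
    cov, G = _sandwich(model._bread, scores, clusters)
    model.cov_params_ = cov
    model.bse_ = np.sqrt(np.diag(cov))
    model.n_clusters_ = G
    return model.result().to_frame()


# ---------------------------------------------------------------------------
# design builder for the intention / belief models


def build_design(
    respondents: pd.DataFrame,
    scores: pd.DataFrame,
    outcome: str = "intention",
    include_youtube: bool = True,
    include_interaction: bool = False,
    date_col: str = "interview_date",
    weight_col: str = "weight",
    smoker_col: str = "established_smoker",
):
    """Assemble outcome, design matrix, clusters and weights for one model.

    ``scores`` is indexed by interview date with columns ``anti_index``,
    ``pro_index`` and (optionally) ``anti_youtube``/``pro_youtube``.  Rows
    with any missing model variable are deleted listwise; when the YouTube
    terms are excluded, YouTube missingness drops no one.  Time is days
    since the first interview, standardized over the analysis sample.

    Returns ``(y, X, clusters, weights, info)``.
    """
    df = respondents.copy()
    dates = pd.to_datetime(df[date_col])
    missing_dates = ~dates.isin(scores.index)
    if missing_dates.any():
        bad = sorted(dates[missing_dates].dt.date.unique())
        raise ValueError(f"no exposure scores for interview dates: {bad[:5]}")
    cols = ["anti_index", "pro_index"]
    if include_youtube:
        cols += ["anti_youtube", "pro_youtube"]
    merged = scores.loc[dates, cols].reset_index(drop=True)
    X = pd.DataFrame({"time": (dates - dates.min()).dt.days.astype(float).values})
    X[smoker_col] = df[smoker_col].astype(float).values
    for c in cols:
        X[c] = merged[c].values
    if include_interaction:
        X["smoker_x_anti"] = X[smoker_col] * X["anti_index"]
    y = pd.to_numeric(df[outcome]).astype(float).reset_index(drop=True)
    weights = df[weight_col].astype(float).reset_index(drop=True)
    clusters = dates.dt.normalize().reset_index(drop=True)

    used = ~(X.isna().any(axis=1) | y.isna() | weights.isna())
    n_in, n_used = len(X), int(used.sum())
    X, y = X.loc[used].reset_index(drop=True), y.loc[used].reset_index(drop=True)
    weights = weights.loc[used].reset_index(drop=True)
    clusters = clusters.loc[used].reset_index(drop=True)
    X["time"] = (X["time"] - X["time"].mean()) / X["time"].std(ddof=1)
    X = X.rename(columns={"time": "time_std"})
    info = {"n_input": n_in, "n_used": n_used, "n_dropped": n_in - n_used}
    return y, X, clusters, weights, info


def adjusted_predictions(
    model: ClusteredLogit,
    X: pd.DataFrame,
    over: str,
    grid,
    at: dict | None = None,
    products: dict[str, tuple[str, str]] | None = None,
    sample_weight=None,
) -> pd.DataFrame:
    """Model-implied probabilities over a covariate grid, other covariates
    at (weighted) sample means, with delta-method CIs from the fitted
    (cluster-robust) covariance.

    ``products`` names interaction columns to recompute as elementwise
    products after the grid/at values are set, e.g.
    ``{"smoker_x_anti": ("established_smoker", "anti_index")}``.
    """
    check_is_fitted(model, "params_")
    at = at or {}
    products = products or {}
    grid = np.asarray(grid, dtype=float)
    lo, hi = X[over].min(), X[over].max()
    if grid.min() < lo or grid.max() > hi:
        warnings.warn(
            f"grid extends beyond the observed range of {over!r} "
            f"[{lo:.3g}, {hi:.3g}]: predictions are extrapolations"
        )
    w = _check_weights(sample_weight, len(X))
    base = {c: float(np.average(X[c], weights=w)) for c in X.columns}
    rows = []
    for g in grid:
        vals = dict(base)
        vals.update(at)
        vals[over] = float(g)
        for prod, (a, b) in products.items():
            vals[prod] = vals[a] * vals[b]
        x = np.array([vals[c] for c in X.columns])
        if model.fit_intercept:
            x = np.r_[1.0, x]
        eta = float(x @ model.params_)
        p = float(expit(eta))
        gradient = p * (1 - p) * x
        var = float(gradient @ model.cov_params_ @ gradient)
        se = np.sqrt(max(var, 0.0))
        row = {over: float(g), "predicted": p,
               "ci_low": p - Z95 * se, "ci_high": p + Z95 * se}
        row.update({k: v for k, v in at.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survey-side statistics


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of an n x k item matrix (reverse-coding already done)."""
    M = np.asarray(items, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("alpha requires at least two items")
    k = M.shape[1]
    item_var = M.var(axis=0, ddof=1)
    total_var = M.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float((k / (k - 1)) * (1 - item_var.sum() / total_var))


def predictive_validity(groups, outcomes) -> dict:
    """Per-group outcome proportions and a two-proportion z-test.

    ``groups`` is a binary baseline split (e.g. intention yes/no among the
    recontacted) and ``outcomes`` the follow-up behavior flags.  Returns the
    group sizes/proportions plus the two-sided z statistic and p-value.
    """
    groups = np.asarray(groups)
    outcomes = np.asarray(outcomes, dtype=float)
    if len(groups) != len(outcomes):
        raise ValueError("groups and outcomes must align")
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("predictive validity needs exactly two non-empty groups")
    counts, nobs, props = [], [], {}
    for lev in levels:
        sel = groups == lev
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"group {lev!r} is empty")
        c = int(outcomes[sel].sum())
        counts.append(c)
        nobs.append(n)
        props[str(lev)] = {"n": n, "proportion": c / n}
    z, p = proportions_ztest(counts, nobs, alternative="two-sided")
    return {"groups": props, "z": float(z), "p": float(p)}


def derive_established_smoker(ever_tried, smoked_100, days_smoked_30) -> np.ndarray:
    """Established current smoker: ever tried AND 100+ lifetime cigarettes
    AND smoked on more than zero of the past 30 days."""
    ever = np.asarray(ever_tried).astype(bool)
    hundred = np.asarray(smoked_100).astype(bool)
    days = np.asarray(days_smoked_30, dtype=float)
    return (ever & hundred & (days > 0)).astype(int)


#: 4-point answer scale used by the intention items.
INTENT_ANSWERS = ("definitely will not", "probably will not", "probably will", "definitely will")


def derive_intention(established_smoker, initiation_answer, quit_answer) -> np.ndarray:
    """Open-to-smoking indicator combining the initiation and quit items.

    Nonsmokers are open unless they *definitely will not* smoke; smokers
    are open (i.e., not intending to quit) unless they *definitely will*
    quit.
    """
    smoker = np.asarray(established_smoker).astype(bool)
    init = np.asarray(initiation_answer, dtype=object)
    quit_ = np.asarray(quit_answer, dtype=object)
    for arr, who in ((init[~smoker], "initiation"), (quit_[smoker], "quit")):
        bad = set(arr) - set(INTENT_ANSWERS)
        if bad:
            raise ValueError(f"unknown {who} answers: {sorted(bad)[:3]}")
    out = np.where(smoker, quit_ != "definitely will", init != "definitely will not")
    return out.astype(int)


def belief_scale(items: pd.DataFrame, reverse: list[str]) -> pd.Series:
    """Mean of the 1-4 belief items after flipping the reverse-scored ones."""
    M = items.astype(float).copy()
    for c in reverse:
        M[c] = 5.0 - M[c]
    if ((M < 1) | (M > 4)).any().any():
        raise ValueError("belief items must lie in 1..4")
    return M.mean(axis=1)
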