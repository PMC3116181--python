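"""NIPALS partial-least-squares regression for a single response (PLS1).

Components are extracted one at a time: the weight vector for component
``a`` is the covariance direction between the current X residual and the
current y residual (for a single response this is exact in one step — no
inner iteration), scores are the projection of X onto the weights, and
both blocks are deflated before the next component. Coefficients are
recomposed as ``b = W (PᵀW)⁻¹ c`` so that prediction through ``b`` equals
prediction through the scores.

Sign indeterminacy of each latent vector is fixed by requiring the
largest-magnitude element of every weight vector to be positive, which
makes weights, scores and loadings reproducible across platforms
(predictions are invariant either way).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin


def _as_2d(X) -> tuple[np.ndarray, list[str] | None, object]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns], X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"X must be 2-dimensional, got shape {arr.shape}")
    return arr, None, None


def _as_1d(y) -> np.ndarray:
    if isinstance(y, pd.Series):
        y = y.to_numpy()
    arr = np.asarray(y, dtype=float).ravel()
    return arr


class PLSRegressionNIPALS(RegressorMixin, BaseEstimator):
    """PLS1 regression via NIPALS with X- and y-deflation.

    Parameters
    ----------
    n_components : int, default 1
        Number of latent components A. Must not exceed the rank of the
        (scaled) descriptor matrix.
    scale : bool, default True
        Autoscale X columns and y to zero mean, unit sample standard
        deviation (n−1 denominator) before extraction, and fold the
        transform into prediction. With ``scale=False`` the data are used
        exactly as given (callers supply pre-centered/scaled blocks).

    Attributes
    ----------
    x_weights_ : ndarray (p, A) — unit-norm weight vectors W.
    x_loadings_ : ndarray (p, A) — loadings P.
    y_loadings_ : ndarray (A,) — inner coefficients c.
    x_scores_ : ndarray (n, A) — scores T (mutually orthogonal).
    y_scores_ : ndarray (n, A) — y-block scores U; column a is the y
        residual entering component a (the inner-relation partner of t_a).
    coef_ : ndarray (p,) — regression vector on the scaled/centered data.
    r2_ : ndarray (A,) — cumulative fraction of (scaled) response sum of
        squares explained after each component; non-decreasing.
    """

    def __init__(self, n_components: int = 1, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "PLSRegressionNIPALS":
        Xa, names, _ = _as_2d(X)
        ya = _as_1d(y)
        n, p = Xa.shape
        if len(ya) != n:
            raise ValueError(f"X has {n} rows but y has {len(ya)}")
        if n < 2:
            raise ValueError("need at least 2 samples")
        a = int(self.n_components)
        if a < 1:
            raise ValueError("n_components must be >= 1")

        if self.scale:
            self.x_mean_ = Xa.mean(axis=0)
            self.x_std_ = Xa.std(axis=0, ddof=1)
            if np.any(self.x_std_ <= 0):
                bad = [i for i, s in enumerate(self.x_std_) if s <= 0]
                labels = [names[i] for i in bad] if names else bad
                raise ValueError(f"constant column(s) in X: {labels}")
            self.y_mean_ = ya.mean()
            self.y_std_ = ya.std(ddof=1)
            if self.y_std_ <= 0:
                raise ValueError("y has zero variance")
        else:
            self.x_mean_ = np.zeros(p)
            self.x_std_ = np.ones(p)
            self.y_mean_ = 0.0
            self.y_std_ = 1.0
        Xs = (Xa - self.x_mean_) / self.x_std_
        ys = (ya - self.y_mean_) / self.y_std_
        ss_tot = float(ys @ ys)
        if ss_tot <= 0:
            raise ValueError("y has zero variance")

        rank = np.linalg.matrix_rank(Xs)
        if a > rank:
            raise ValueError(
                f"n_components={a} exceeds the rank of the descriptor matrix ({rank})"
            )

        W = np.empty((p, a))
        P = np.empty((p, a))
        T = np.empty((n, a))
        U = np.empty((n, a))
        c = np.empty(a)
        r2 = np.empty(a)
        Xr, yr = Xs.copy(), ys.copy()
        for k in range(a):
            w = Xr.T @ yr
            norm = np.linalg.norm(w)
            if norm == 0.0:  # y exactly orthogonal to the residual block
                w = np.zeros(p)
                w[int(np.argmax(np.linalg.norm(Xr, axis=0)))] = 1.0
            else:
                w /= norm
            if w[int(np.argmax(np.abs(w)))] < 0:
                w = -w
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 0:
                raise ValueError(f"degenerate component {k + 1}: zero score variance")
            U[:, k] = yr
            ck = float(yr @ t) / tt
            pk = Xr.T @ t / tt
            Xr = Xr - np.outer(t, pk)
            yr = yr - ck * t
            W[:, k], P[:, k], T[:, k], c[k] = w, pk, t, ck
            r2[k] = 1.0 - float(yr @ yr) / ss_tot

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = c
        self.x_scores_ = T
        self.y_scores_ = U
        self.r2_ = r2
        self.coef_ = W @ np.linalg.solve(P.T @ W, c)
        self.n_features_in_ = p
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self.rank_ = int(rank)
        return self

    def _check_columns(self, names: list[str] | None) -> None:
        trained = getattr(self, "feature_names_in_", None)
        if trained is None or names is None:
            return
        if list(trained) != list(names):
            extra = sorted(set(names) - set(trained))
            missing = sorted(set(trained) - set(names))
            raise ValueError(
                "descriptor columns do not match training columns"
                + (f"; missing: {missing}" if missing else "")
                + (f"; unexpected: {extra}" if extra else "")
            )

    def predict(self, X):
        """Predict the response in original units (applies the stored
        centering/scaling, the latent projection, and back-transform)."""
        Xa, names, index = _as_2d(X)
        self._check_columns(names)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} columns, model was fit with {self.n_features_in_}"
            )
        Xs = (Xa - self.x_mean_) / self.x_std_
        yhat = (Xs @ self.coef_) * self.y_std_ + self.y_mean_
        if index is not None:
            return pd.Series(yhat, index=index)
        return yhat

    def predict_components(self, X) -> np.ndarray:
        """Predictions (original units) of every truncated model a = 1..A,
        returned as an (n, A) array. Used by cross-validation to score all
        component counts from one fit."""
        Xa, names, _ = _as_2d(X)
        self._check_columns(names)
        Xs = (Xa - self.x_mean_) / self.x_std_
        W, P, c = self.x_weights_, self.x_loadings_, self.y_loadings_
        A = W.shape[1]
        out = np.empty((Xa.shape[0], A))
        for a in range(1, A + 1):
            b = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], c[:a])
            out[:, a - 1] = (Xs @ b) * self.y_std_ + self.y_mean_
        return out


def fit_pls1(x_scaled, y_scaled, a: int) -> PLSRegressionNIPALS:
    """Fit a PLS1 model on already autoscaled blocks (no re-scaling)."""
    return PLSRegressionNIPALS(n_components=a, scale=False).fit(x_scaled, y_scaled)


def coefficients(model: PLSRegressionNIPALS):
    """Regression vector on the scaled/centered data, labeled when the
    model was fit from a DataFrame."""
    names = getattr(model, "feature_names_in_", None)
    if names is not None:
        return pd.Series(model.coef_, index=list(names), name="coefficient")
    return model.coef_.copy()


def scores_tu(model: PLSRegressionNIPALS) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-component (t, u) score pairs for inner-relation plots."""
    A = model.x_scores_.shape[1]
    return [(model.x_scores_[:, a].copy(), model.y_scores_[:, a].copy())
            for a in range(A)]
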