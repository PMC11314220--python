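"""From-scratch PLS1 regression (NIPALS) with VIP, Q2 and back-transformation.

This is the package's core numerical engine. Predictors and response are
autoscaled ("coded in units of variance": column mean 0, SD 1 with the n-1
denominator); components are extracted by the NIPALS algorithm for a single
response:

    w_a  = X' y / ||X' y||        (unit weight vector)
    t_a  = X w_a                  (score)
    p_a  = X' t_a / (t_a' t_a)    (X loading)
    q_a  = y' t_a / (t_a' t_a)    (y loading)
    X   <- X - t_a p_a'           (deflation; y deflated by q_a t_a)

Standardized coefficients are reconstructed as b = W (P'W)^{-1} q and
back-transformed to the original units (b_j * sd_y / sd_xj, intercept
ybar - sum b_j xbar_j) so coefficient tables read in phenotype units.

Variable importance in the projection (VIP) summarises each predictor's
contribution across components; it is normalised so that the mean squared
VIP equals 1.

Predictive ability is measured by Q2 = 1 - PRESS/SS_y with PRESS
accumulated over held-out folds of a venetian-blind K-fold scheme (fold
membership by position modulo K after a seeded shuffle); fold models are
recentred on their training rows. The number of components is chosen by
the same cross-validation: a component is adopted while it improves the
cumulative Q2 by more than 0.01 (at least one component is always kept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Scaling",
    "PLSModel",
    "ModelFitStats",
    "autoscale",
    "fit_pls",
    "fold_assignments",
    "press_from_folds",
    "q_squared",
    "select_components",
    "vip",
    "adjusted_r2",
    "unstandardized_coefficients",
    "pls_fit",
]

#: Incremental-Q2 threshold for adopting one more component (tunable).
COMPONENT_Q2_GAIN = 0.01


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaling:
    """Column means/SDs used to autoscale X and y (for exact inversion)."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    columns: tuple[str, ...] = ()

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def inverse_x(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.x_sd + self.x_mean

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def inverse_y(self, ys: np.ndarray) -> np.ndarray:
        return np.asarray(ys, dtype=float) * self.y_sd + self.y_mean


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"x{j}" for j in range(X.shape[1]))


def autoscale(X, y) -> tuple[np.ndarray, np.ndarray, Scaling]:
    """Scale every predictor column and the response to mean 0, SD 1.

    Raises ``ValueError`` naming the offending column when a column is
    constant (zero SD); missing values must be imputed upstream.
    """
    Xm, columns = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if np.isnan(Xm).any() or np.isnan(yv).any():
        raise ValueError("autoscale requires complete data; impute missing first")
    x_mean = Xm.mean(axis=0)
    x_sd = Xm.std(axis=0, ddof=1)
    zero = np.flatnonzero(x_sd == 0)
    if zero.size:
        raise ValueError(f"constant predictor column: {columns[zero[0]]!r}")
    y_sd = yv.std(ddof=1)
    if y_sd == 0:
        raise ValueError("constant response")
    scaling = Scaling(x_mean, x_sd, float(yv.mean()), float(y_sd), columns)
    return (Xm - x_mean) / x_sd, (yv - yv.mean()) / y_sd, scaling


# ---------------------------------------------------------------------------
# NIPALS core
# ---------------------------------------------------------------------------

def _nipals(Xs: np.ndarray, ys: np.ndarray, A: int, tol: float = 1e-12):
    """Extract up to A components; returns (W, P, q, T, tt, A_used)."""
    X = Xs.copy()
    y = ys.copy().astype(float)
    n, p = X.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    used = 0
    scale0 = np.linalg.norm(Xs) * np.linalg.norm(ys) + tol
    for a in range(A):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= tol * scale0:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= tol * max(1.0, float(np.linalg.norm(Xs) ** 2)):
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t / tt)
        X -= np.outer(t, p_a)
        y -= q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        used = a + 1
    return W[:, :used], P[:, :used], q[:used], T[:, :used], (T[:, :used] ** 2).sum(0), used


@dataclass
class PLSModel:
    """Fitted PLS1 model on autoscaled data.

    Attributes hold the NIPALS factors (weights ``W``, X-loadings ``P``,
    y-loadings ``q``, scores ``T``), the standardized coefficient vector,
    the training R2 and the VIP vector; ``scaling`` (when present) allows
    prediction and coefficient reporting on the original units, and
    ``q2_cum`` stores the cumulative cross-validated Q2 per component when
    the model was fitted through :func:`pls_fit`.
    """

    columns: tuple[str, ...]
    A: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    tt: np.ndarray
    coef_std: np.ndarray
    r2: float
    scaling: Scaling | None = None
    q2_cum: np.ndarray | None = None
    vips: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n(self) -> int:
        return self.T.shape[0]

    @property
    def k(self) -> int:
        return len(self.columns)

    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) @ self.coef_std

    def predict(self, X) -> np.ndarray:
        """Predict the response in original units from raw predictors."""
        if self.scaling is None:
            raise ValueError("model has no scaling information")
        Xm, _ = _as_matrix(X)
        return self.scaling.inverse_y(self.predict_scaled(self.scaling.transform_x(Xm)))


def fit_pls(Xs: np.ndarray, ys: np.ndarray, A: int,
            columns: tuple[str, ...] | None = None,
            scaling: Scaling | None = None) -> PLSModel:
    """Fit a PLS1 model with ``A`` components on autoscaled data.

    ``A`` exceeding the effective rank is truncated with a warning.
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    n, p = Xs.shape
    if A < 1:
        raise ValueError("need at least one component")
    A = min(A, n - 1 if n > 1 else 1, p)
    W, P, q, T, tt, used = _nipals(Xs, ys, A)
    if used < A:
        warnings.warn(
            f"requested {A} components but rank supports only {used}; truncated",
            stacklevel=2,
        )
        A = max(used, 1)
        if used == 0:
            raise ValueError("X carries no covariance with y; cannot fit")
    coef = W @ np.linalg.solve(P.T @ W, q)
    residual = ys - Xs @ coef
    ss_y = float(ys @ ys)
    r2 = 1.0 - float(residual @ residual) / ss_y if ss_y > 0 else 0.0
    if columns is None:
        columns = tuple(f"x{j}" for j in range(p))
    model = PLSModel(tuple(columns), A, W, P, q, T, tt, coef, r2, scaling)
    model.vips = vip(model)
    return model


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def fold_assignments(n: int, folds: int, seed: int = 0) -> np.ndarray:
    """Venetian-blind fold labels after a seeded shuffle of the row order."""
    if not 2 <= folds <= n:
        raise ValueError("need 2 <= folds <= n")
    order = np.random.default_rng(seed).permutation(n)
    assign = np.empty(n, dtype=int)
    assign[order] = np.arange(n) % folds
    return assign


def press_from_folds(Xs: np.ndarray, ys: np.ndarray, A: int,
                     assign: np.ndarray) -> float:
    """PRESS over held-out folds; fold models recentre on their training rows."""
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    press = 0.0
    for f in np.unique(assign):
        test = assign == f
        train = ~test
        Xt, yt = Xs[train], ys[train]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, P, q, _, _, used = _nipals(Xt - xm, yt - ym, min(A, Xt.shape[0] - 1))
        if used == 0:
            pred = np.full(test.sum(), ym)
        else:
            coef = W @ np.linalg.solve(P.T @ W, q)
            pred = ym + (Xs[test] - xm) @ coef
        press += float(((ys[test] - pred) ** 2).sum())
    return press


def q_squared(Xs: np.ndarray, ys: np.ndarray, A: int,
              folds: int = 7, seed: int = 0,
              assign: np.ndarray | None = None) -> float:
    """Cross-validated Q2 = 1 - PRESS / SS_y on autoscaled data."""
    ys = np.asarray(ys, dtype=float).ravel()
    if assign is None:
        assign = fold_assignments(len(ys), min(folds, len(ys)), seed)
    press = press_from_folds(Xs, ys, A, assign)
    ss_y = float(((ys - ys.mean()) ** 2).sum())
    return 1.0 - press / ss_y


def select_components(Xs: np.ndarray, ys: np.ndarray,
                      folds: int = 7, seed: int = 0,
                      max_a: int | None = None,
                      min_gain: float = COMPONENT_Q2_GAIN) -> int:
    """Pick the number of components by incremental cross-validated Q2.

    Component a is adopted while its incremental Q2 exceeds ``min_gain``
    (cumulative Q2 strictly improving); at least one component is kept.
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    n, p = Xs.shape
    if max_a is None:
        max_a = min(n - 1, p)
    assign = fold_assignments(n, min(folds, n), seed)
    best_a = 1
    q2_prev = q_squared(Xs, ys, 1, assign=assign)
    for a in range(2, max_a + 1):
        q2_a = q_squared(Xs, ys, a, assign=assign)
        if q2_a - q2_prev > min_gain:
            best_a, q2_prev = a, q2_a
        else:
            break
    return best_a


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in the projection; mean squared VIP is 1.

    VIP_j = sqrt( p * sum_a s_a (w_ja/||w_a||)^2 / sum_a s_a ) with
    s_a = q_a^2 t_a' t_a the y-variance explained by component a.
    """
    p = model.W.shape[0]
    norms = np.linalg.norm(model.W, axis=0)
    norms[norms == 0] = 1.0
    w2 = (model.W / norms) ** 2
    s = model.q**2 * model.tt
    total = s.sum()
    if total == 0:
        return np.full(p, 1.0)
    return np.sqrt(p * (w2 @ s) / total)


@dataclass(frozen=True)
class ModelFitStats:
    """Sample size, predictor count (excluding constant) and fit R2."""

    n: int
    k: int
    r2: float

    @property
    def adjusted(self) -> float:
        return adjusted_r2(self.r2, self.n, self.k)


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """R2 penalized for model size: 1 - (1 - R2)(n - 1)/(n - k - 1).

    Undefined (raises) when n - k - 1 < 1: with that many predictors the
    training R2 is positively biased beyond repair.
    """
    if n - k - 1 < 1:
        raise ValueError(f"adjusted R2 undefined for n={n}, k={k}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def unstandardized_coefficients(model: PLSModel) -> tuple[np.ndarray, float]:
    """Back-transform standardized coefficients to original units.

    b_j = b_j^std * sd_y / sd_xj and intercept ybar - sum_j b_j xbar_j;
    predictions through this parametrization are identical to the
    standardized pathway.
    """
    if model.scaling is None:
        raise ValueError("model has no scaling information")
    sc = model.scaling
    b = model.coef_std * sc.y_sd / sc.x_sd
    intercept = sc.y_mean - float(b @ sc.x_mean)
    return b, intercept


# ---------------------------------------------------------------------------
# Convenience front-end
# ---------------------------------------------------------------------------

def pls_fit(X, y, A: int | None = None, folds: int = 7, seed: int = 0) -> PLSModel:
    """Autoscale, choose components by cross-validation (unless ``A`` given),
    and fit; the returned model carries scaling and cumulative Q2."""
    Xs, ys, scaling = autoscale(X, y)
    n = len(ys)
    folds_eff = min(folds, n)
    if A is None:
        A = select_components(Xs, ys, folds=folds_eff, seed=seed)
    model = fit_pls(Xs, ys, A, columns=scaling.columns, scaling=scaling)
    assign = fold_assignments(n, folds_eff, seed)
    model.q2_cum = np.array(
        [q_squared(Xs, ys, a, assign=assign) for a in range(1, model.A + 1)]
    )
    return model
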