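"""PLSR (NIPALS) and LASSO (cyclic coordinate descent) for spectra.

Both models relate the ``N x K`` treated spectra matrix ``X`` to the scalar
response ``y`` (the 6-gingerol : 6-shogaol ratio).  Predictors and response
are mean-centred internally; no unit-variance scaling is applied by default
(the pre-treatments already normalise scale where intended), though an
opt-in flag is available.

PLSR decomposes ``X = T P' + E`` and ``y = T q + f`` over ``J`` shared
latent variables, each component's weight vector chosen to maximise the
covariance between its score and the response (the classical NIPALS
recursion for a single response).  ``J`` is picked by leave-one-out
cross-validation, minimising RMSECV.

LASSO minimises the objective on its printed scale,

    sum_i (y_i - x_i' beta)^2  +  alpha * sum_j |beta_j|,

i.e. a plain residual sum of squares plus an L1 penalty with *no* ``1/(2N)``
factor.  Users translating grids from libraries that scale the RSS by
``1/(2N)`` should use ``alpha_here = 2 * N * alpha_there``.  The solver is
cyclic coordinate descent with soft-thresholding on the Gram matrix,
compiled with numba; ``alpha`` is picked by the same leave-one-out
criterion, walking the regularisation path warm-started from the fully
sparse end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .preprocessing import SpectraMatrix

__all__ = [
    "SplitSpec",
    "split_indices",
    "split_dataset",
    "PLSRModel",
    "fit_plsr",
    "select_lvs_loocv",
    "LassoModel",
    "fit_lasso",
    "default_alpha_grid",
    "AlphaSearch",
    "select_alpha_cv",
    "predict",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within the sweep budget."""


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Seeded random train/test partition.

    ``|test| = round(test_fraction * N)``.  The seed fixes this package's
    own permutation; other toolchains given the same seed produce different
    memberships, since permutation algorithms are not portable across RNG
    implementations.
    """

    test_fraction: float = 0.2
    seed: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must lie in (0, 1), got {self.test_fraction}")


def split_indices(n: int, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Return sorted (train_indices, test_indices) for ``n`` samples."""
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    n_test = int(np.floor(spec.test_fraction * n + 0.5))
    n_test = max(1, min(n - 1, n_test))
    perm = np.random.default_rng(spec.seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def split_dataset(dataset, spec: SplitSpec = SplitSpec()):
    """Split a :class:`~gingerspec.dataset.SpectralDataset` into (train, test)."""
    train_idx, test_idx = split_indices(dataset.n_samples, spec)
    return dataset.subset(train_idx), dataset.subset(test_idx)


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """State of a fitted NIPALS PLSR decomposition (single response)."""

    n_lvs: int
    weights: np.ndarray       # W, K x J, unit-norm columns
    x_scores: np.ndarray      # T, N x J, mutually orthogonal columns
    x_loadings: np.ndarray    # P, K x J
    y_loadings: np.ndarray    # q, length J
    coef: np.ndarray          # beta on centred data, length K
    x_mean: np.ndarray
    y_mean: float
    x_residual: np.ndarray    # E, N x K
    y_residual: np.ndarray    # f, length N
    rmsecv_curve: np.ndarray | None = None

    @property
    def n_bands(self) -> int:
        return self.coef.size


def _as_xy(X, y):
    if isinstance(X, SpectraMatrix):
        X = X.X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    return X, y


def fit_plsr(X, y, n_lvs: int, scale: bool = False) -> PLSRModel:
    """Fit a single-response PLSR with ``n_lvs`` latent variables.

    Per component: weight ``w ∝ X'y`` (unit norm), score ``t = X w``,
    loadings ``p = X't / t't`` and ``q = y't / t't``, then rank-one
    deflation of both blocks.  The regression vector on centred data is
    ``beta = W (P'W)^{-1} q``, so prediction via ``beta`` coincides with the
    sequential scores pathway.  If a component's score norm collapses below
    1e-12 the fit stops early with a warning and returns the components
    achieved.
    """
    X, y = _as_xy(X, y)
    n, k = X.shape
    if n_lvs < 1:
        raise ValueError("n_lvs must be >= 1")
    if n_lvs > min(n - 1, k):
        raise ValueError(f"n_lvs={n_lvs} exceeds min(N-1, K) = {min(n - 1, k)}")
    if np.std(y) == 0:
        raise ValueError("response has zero variance; PLSR undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    x_scale = X.std(axis=0, ddof=1) if scale else None
    if x_scale is not None:
        x_scale[x_scale == 0] = 1.0
    Xc = (X - x_mean) / x_scale if scale else X - x_mean
    yc = y - y_mean

    W = np.zeros((k, n_lvs))
    T = np.zeros((n, n_lvs))
    P = np.zeros((k, n_lvs))
    q = np.zeros(n_lvs)
    achieved = 0
    for a in range(n_lvs):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn < 1e-12:
            warnings.warn(f"PLSR: response fully deflated after {a} components; stopping early")
            break
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if np.sqrt(tt) < 1e-12:
            warnings.warn(f"PLSR: degenerate score at component {a + 1}; stopping early")
            break
        p = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p, qa
        achieved = a + 1
    if achieved == 0:
        raise ValueError("no PLSR component could be extracted")
    W, T, P, q = W[:, :achieved], T[:, :achieved], P[:, :achieved], q[:achieved]

    beta = W @ np.linalg.solve(P.T @ W, q)
    if scale:
        beta = beta / x_scale
    return PLSRModel(
        n_lvs=achieved, weights=W, x_scores=T, x_loadings=P, y_loadings=q,
        coef=beta, x_mean=x_mean, y_mean=y_mean, x_residual=Xc, y_residual=yc,
    )


def predict_scores_pathway(model: PLSRModel, X_new) -> np.ndarray:
    """Predict via sequential score projection (``t_a = x w_a``, deflate,
    accumulate ``t_a q_a``) — numerically independent of ``model.coef``."""
    if isinstance(X_new, SpectraMatrix):
        X_new = X_new.X
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xc = X_new - model.x_mean
    yhat = np.full(Xc.shape[0], model.y_mean)
    for a in range(model.n_lvs):
        t = Xc @ model.weights[:, a]
        yhat += t * model.y_loadings[a]
        Xc = Xc - np.outer(t, model.x_loadings[:, a])
    return yhat


def predict(model, X_new) -> np.ndarray:
    """Predict the response: ``y_hat = (X_new - x_mean) beta + y_mean``.

    Works for both :class:`PLSRModel` and :class:`LassoModel`.
    """
    if isinstance(X_new, SpectraMatrix):
        X_new = X_new.X
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.size:
        raise ValueError(f"X_new has {X_new.shape[1]} bands, model expects {model.coef.size}")
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def select_lvs_loocv(X, y, max_lvs: int = 20) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by leave-one-out cross-validation.

    For every candidate ``J`` in ``1..max_lvs``, each training sample is held
    out in turn, the model refitted, and the held-out sample predicted; the
    RMSE of those predictions is RMSECV(J).  Returns ``(J*, curve)`` with
    ``J* = argmin`` (ties break to the smallest ``J``).  Each fold's NIPALS
    run is performed once up to ``max_lvs``, collecting nested predictions.
    """
    X, y = _as_xy(X, y)
    n, k = X.shape
    max_lvs = int(min(max_lvs, n - 2, k))
    if max_lvs < 1:
        raise ValueError("max_lvs reduced below 1 by the data dimensions")
    preds = np.empty((n, max_lvs))
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsr(X[mask], y[mask], max_lvs)
        # nested predictions for the held-out sample at each J
        xc = X[i] - model.x_mean
        yhat = model.y_mean
        for a in range(max_lvs):
            if a < model.n_lvs:
                t = float(xc @ model.weights[:, a])
                yhat += t * model.y_loadings[a]
                xc = xc - t * model.x_loadings[:, a]
            preds[i, a] = yhat
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return int(np.argmin(rmsecv)) + 1, rmsecv


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_sweeps(G, Xty, beta, alpha_half, yty, tol, obj_thresh, kkt_tol, max_iter):  # pragma: no cover - numba
    """Cyclic coordinate descent on the Gram system; returns sweeps used
    (-1 if no stopping rule fired).  ``beta`` is updated in place.

    Three stopping rules, whichever fires first (a zero threshold disables
    its rule):

    * strict: the largest per-sweep coefficient change drops below ``tol``;
    * stationarity: the largest KKT violation (computable exactly from the
      maintained gradient ``Xty - z``) drops below ``kkt_tol``;
    * progress: the largest single-coordinate objective decrease
      (``G_jj * delta_j**2``) drops below ``obj_thresh * yty`` — the
      scale-invariant rule that handles heavily collinear spectra, where
      coefficient changes along near-null directions of the Gram matrix
      decay too slowly for the other two rules.
    """
    k = beta.size
    z = G @ beta  # z_j = sum_l G[j, l] * beta[l], maintained incrementally
    dec_tol = obj_thresh * yty
    for it in range(max_iter):
        max_delta = 0.0
        max_dec = 0.0
        for j in range(k):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            bj = beta[j]
            rho = Xty[j] - z[j] + gjj * bj
            if rho > alpha_half:
                bnew = (rho - alpha_half) / gjj
            elif rho < -alpha_half:
                bnew = (rho + alpha_half) / gjj
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                beta[j] = bnew
                for l in range(k):
                    z[l] += d * G[l, j]
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
                dec = gjj * d * d
                if dec > max_dec:
                    max_dec = dec
        if max_delta < tol:
            return it + 1
        if obj_thresh > 0.0 and max_dec < dec_tol:
            return it + 1
        if kkt_tol > 0.0:
            kkt = 0.0
            for j in range(k):
                g = Xty[j] - z[j]
                if beta[j] > 0.0:
                    v = abs(g - alpha_half)
                elif beta[j] < 0.0:
                    v = abs(g + alpha_half)
                else:
                    v = abs(g) - alpha_half
                    if v < 0.0:
                        v = 0.0
                if v > kkt:
                    kkt = v
            if kkt < kkt_tol:
                return it + 1
    return -1


@dataclass
class LassoModel:
    """L1-penalised linear model on the printed objective scale."""

    alpha: float
    coef: np.ndarray
    intercept: float          # = y_mean; prediction goes through x_mean as well
    x_mean: np.ndarray
    y_mean: float
    n_sweeps: int = 0
    alpha_grid: np.ndarray | None = None
    cv_rmse: np.ndarray | None = None

    @property
    def active_set(self) -> np.ndarray:
        return np.flatnonzero(self.coef)


def lasso_objective(X, y, coef, alpha: float, x_mean=None, y_mean=None) -> float:
    """RSS + alpha * ||beta||_1 on centred data (the printed objective)."""
    X, y = _as_xy(X, y)
    xm = X.mean(axis=0) if x_mean is None else x_mean
    ym = y.mean() if y_mean is None else y_mean
    r = (y - ym) - (X - xm) @ coef
    return float(r @ r + alpha * np.sum(np.abs(coef)))


def _duality_gap(Xc, yc, beta, alpha: float) -> float:
    """Duality gap of the equivalent half-scale problem, doubled back."""
    r = yc - Xc @ beta
    lam = alpha / 2.0
    corr = np.max(np.abs(Xc.T @ r)) if Xc.size else 0.0
    s = 1.0 if corr <= lam or corr == 0 else lam / corr
    theta = s * r
    primal_half = 0.5 * float(r @ r) + lam * float(np.sum(np.abs(beta)))
    dual_half = float(theta @ yc) - 0.5 * float(theta @ theta)
    return 2.0 * (primal_half - dual_half)


def fit_lasso(X, y, alpha: float, tol: float = 1e-8, obj_thresh: float = 1e-9,
              kkt_tol: float = 1e-7, polish_sweeps: int = 2_000,
              max_iter: int = 100_000) -> LassoModel:
    """Minimise ``||y - X beta||^2 + alpha ||beta||_1`` by coordinate descent.

    ``X`` and ``y`` are centred internally; the coordinate update is the
    soft-threshold ``beta_j = S(rho_j, alpha/2) / (X_j' X_j)``.  ``alpha = 0``
    returns the least-squares solution (minimum-norm when rank-deficient).

    Convergence is two-phase.  Phase one stops on the strict rule (largest
    per-sweep coefficient change below ``tol``), on stationarity (largest
    KKT violation below ``kkt_tol``), or on the scale-invariant progress
    rule (largest single-coordinate objective decrease below
    ``obj_thresh * ||y_c||^2``) — the last is what terminates heavily
    collinear spectral problems, where the first two decay too slowly to be
    practical.  If only the progress rule fired, a bounded polish phase (at
    most ``polish_sweeps`` further sweeps, progress rule disabled) pushes
    towards certified stationarity: on well-conditioned designs it reaches
    ``kkt_tol``; on near-singular ones it spends its budget and keeps the
    best iterate.  Exceeding ``max_iter`` sweeps in phase one raises
    :class:`ConvergenceError` carrying the duality gap.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    X, y = _as_xy(X, y)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    if alpha == 0.0:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        return LassoModel(0.0, beta, y_mean, x_mean, y_mean, n_sweeps=0)

    G = Xc.T @ Xc
    Xty = Xc.T @ yc
    yty = float(yc @ yc)
    beta = np.zeros(X.shape[1])
    sweeps = _cd_sweeps(G, Xty, beta, alpha / 2.0, yty, tol, obj_thresh, kkt_tol, max_iter)
    if sweeps < 0:
        gap = _duality_gap(Xc, yc, beta, alpha)
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(alpha={alpha:g}, duality gap={gap:.3e})"
        )
    model = LassoModel(float(alpha), beta, y_mean, x_mean, y_mean, n_sweeps=sweeps)
    if polish_sweeps > 0 and kkt_residual(model, X, y) >= kkt_tol:
        extra = _cd_sweeps(G, Xty, beta, alpha / 2.0, yty, tol, 0.0, kkt_tol, polish_sweeps)
        model.n_sweeps = sweeps + (extra if extra > 0 else polish_sweeps)
    return model


def kkt_residual(model: LassoModel, X, y) -> float:
    """Largest violation of the stationarity conditions at ``model.coef``.

    Active coordinates must satisfy ``X_j'(y - X beta) = (alpha/2) sign(beta_j)``;
    inactive ones ``|X_j'(y - X beta)| <= alpha/2`` (centred data).
    """
    X, y = _as_xy(X, y)
    Xc = X - model.x_mean
    yc = y - model.y_mean
    g = Xc.T @ (yc - Xc @ model.coef)
    lam = model.alpha / 2.0
    active = model.coef != 0
    viol_active = np.abs(g[active] - lam * np.sign(model.coef[active]))
    viol_inactive = np.maximum(np.abs(g[~active]) - lam, 0.0)
    pieces = np.concatenate([viol_active, viol_inactive])
    return float(pieces.max()) if pieces.size else 0.0


def default_alpha_grid(X, y, n_alphas: int = 50, min_ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from ``alpha_max`` (the smallest penalty
    that zeroes every coefficient, ``2 max_j |X_j' y|`` on centred data)
    down to ``alpha_max * min_ratio``."""
    X, y = _as_xy(X, y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = 2.0 * float(np.max(np.abs(Xc.T @ yc)))
    if alpha_max == 0.0:
        raise ValueError("X'y is identically zero; the LASSO path is trivial")
    return np.geomspace(alpha_max, alpha_max * min_ratio, n_alphas)


@dataclass
class AlphaSearch:
    """Result of cross-validated penalty selection."""

    alpha: float
    alpha_grid: np.ndarray   # descending
    cv_rmse: np.ndarray      # aligned with alpha_grid


def select_alpha_cv(X, y, alpha_grid=None, n_alphas: int = 50, min_ratio: float = 1e-4,
                    tol: float = 1e-8, obj_thresh: float = 1e-9,
                    max_iter: int = 100_000) -> AlphaSearch:
    """Choose ``alpha`` by leave-one-out cross-validation over a grid.

    The grid (descending) is walked with warm starts within each fold.
    ``alpha* = argmin`` of the LOO RMSE; ties break to the *largest* alpha,
    i.e. the sparser model.
    """
    X, y = _as_xy(X, y)
    n = X.shape[0]
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(X, y, n_alphas, min_ratio)
    alpha_grid = np.sort(np.asarray(alpha_grid, dtype=float))[::-1]
    if alpha_grid.size == 0:
        raise ValueError("alpha grid is empty")
    if np.any(alpha_grid < 0):
        raise ValueError("alpha grid must be non-negative")

    preds = np.empty((n, alpha_grid.size))
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        Xi, yi = X[mask], y[mask]
        xm = Xi.mean(axis=0)
        ym = yi.mean()
        Xc = Xi - xm
        yc = yi - ym
        G = Xc.T @ Xc
        Xty = Xc.T @ yc
        yty = float(yc @ yc)
        beta = np.zeros(X.shape[1])
        xheld = X[i] - xm
        for a, alpha in enumerate(alpha_grid):
            if alpha == 0.0:
                beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
            else:
                sweeps = _cd_sweeps(G, Xty, beta, alpha / 2.0, yty, tol, obj_thresh, 0.0, max_iter)
                if sweeps < 0:
                    raise ConvergenceError(
                        f"LOO fold {i}, alpha={alpha:g}: no convergence in {max_iter} sweeps"
                    )
            preds[i, a] = xheld @ beta + ym
    cv_rmse = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    best = int(np.argmin(cv_rmse))  # first minimum = largest alpha in descending grid
    return AlphaSearch(float(alpha_grid[best]), alpha_grid, cv_rmse)
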