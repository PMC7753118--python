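"""Elastic-net linear regression solved by cyclic coordinate descent.

The solver minimizes, for a Gaussian outcome,

    (1/2n) * sum_i (y_i - b0 - x_i' b)^2
        + lam * sum_j pf_j * ( l1_ratio * |b_j| + (1 - l1_ratio)/2 * b_j^2 )

where ``pf`` are per-feature penalty factors (0 leaves a feature — e.g. a
nuisance covariate — unpenalized) and the intercept is never penalized.
Each coordinate update is the classic soft-threshold step on the partial
residual; data are centered internally so the intercept drops out of the
iteration, and unpenalized features are profiled out exactly before the
iteration starts.  Convergence is declared when the largest per-sweep
coefficient change, measured as squared change on the
standardized-predictor scale relative to the outcome variance, falls below
``tol`` (glmnet's criterion; an absolute coefficient-change criterion
stalls on near-singular bootstrap training folds).  A warm-started path over a geometric lambda grid and
K-fold cross-validation by minimum held-out Gaussian deviance (mean squared
error) are provided on top of the solver.

The inner loop is compiled with numba; ``debug=True`` switches to a pure
Python mirror of the same update that asserts the penalized objective is
non-increasing after every sweep.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

NONZERO_TOL = 1e-8  # |coef| above this counts as "included" for VIP


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within ``max_sweeps``."""


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Column-wise min-max normalization, x -> (x - min) / (max - min).

    Fitted attributes record the per-column minimum and range so the mapping
    can be inverted.  A constant column is an error (its range is zero) and
    is reported by name.
    """

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(float)
        else:
            values = np.asarray(X, float)
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(values.shape[1])], dtype=object
            )
        self.data_min_ = values.min(axis=0)
        self.data_range_ = values.max(axis=0) - self.data_min_
        bad = np.where(self.data_range_ <= 0)[0]
        if bad.size:
            names = ", ".join(str(self.feature_names_in_[j]) for j in bad)
            raise ValueError(f"constant column(s) cannot be normalized: {names}")
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X):
        frame = isinstance(X, pd.DataFrame)
        values = X.to_numpy(float) if frame else np.asarray(X, float)
        out = (values - self.data_min_) / self.data_range_
        if frame:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def inverse_transform(self, X):
        frame = isinstance(X, pd.DataFrame)
        values = X.to_numpy(float) if frame else np.asarray(X, float)
        out = values * self.data_range_ + self.data_min_
        if frame:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def minmax_normalize(X):
    """Min-max normalize; returns ``(normalized, fitted MinMaxNormalizer)``."""
    norm = MinMaxNormalizer().fit(X)
    return norm.transform(X), norm


# ---------------------------------------------------------------------------
# coordinate-descent kernels (Gram formulation, centered data)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_path_kernel(G, c, nobs, lambdas, l1_ratio, pf, scale2, tol, max_sweeps):
    """Warm-started cyclic coordinate descent along a descending lambda path.

    G = Xc'Xc, c = Xc'yc on centered data. Convergence per sweep is judged
    on the fit scale: ``max_j scale2_j * (delta beta_j)^2 < tol`` where
    ``scale2_j = var(x_j) / var(y)`` — the criterion glmnet uses, robust to
    near-singular designs where raw coefficient changes stall in a null
    space without affecting the fit.
    Returns the (n_lambda, p) coefficient matrix, per-lambda sweep counts
    (-1 marks non-convergence) and the last scaled max change.
    """
    p = G.shape[0]
    nl = lambdas.shape[0]
    B = np.zeros((nl, p))
    beta = np.zeros(p)
    sweeps = np.zeros(nl, np.int64)
    last_delta = 0.0
    for li in range(nl):
        lam = lambdas[li]
        converged = False
        for sweep in range(max_sweeps):
            max_delta = 0.0
            for j in range(p):
                gj = c[j]
                for k in range(p):
                    gj -= G[j, k] * beta[k]
                gj += G[j, j] * beta[j]
                rho = gj / nobs
                thr = lam * l1_ratio * pf[j]
                denom = G[j, j] / nobs + lam * (1.0 - l1_ratio) * pf[j]
                if denom <= 0.0:
                    new = 0.0  # constant column: coefficient pinned at zero
                elif rho > thr:
                    new = (rho - thr) / denom
                elif rho < -thr:
                    new = (rho + thr) / denom
                else:
                    new = 0.0
                d = scale2[j] * (new - beta[j]) ** 2
                if d > max_delta:
                    max_delta = d
                beta[j] = new
            last_delta = max_delta
            if max_delta < tol:
                sweeps[li] = sweep + 1
                converged = True
                break
        if not converged:
            sweeps[li] = -1
        for j in range(p):
            B[li, j] = beta[j]
    return B, sweeps, last_delta


def _objective(G, c, yss, nobs, beta, lam, l1_ratio, pf):
    """Penalized objective on centered data (up to the constant in y)."""
    quad = 0.5 * (yss - 2.0 * c @ beta + beta @ G @ beta) / nobs
    pen = lam * np.sum(pf * (l1_ratio * np.abs(beta) + 0.5 * (1 - l1_ratio) * beta**2))
    return quad + pen


def _cd_path_debug(G, c, yss, nobs, lambdas, l1_ratio, pf, scale2, tol, max_sweeps):
    """Pure-Python mirror of the kernel asserting objective monotonicity."""
    p = G.shape[0]
    B = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    sweeps = np.zeros(len(lambdas), dtype=np.int64)
    last_delta = 0.0
    for li, lam in enumerate(lambdas):
        obj = _objective(G, c, yss, nobs, beta, lam, l1_ratio, pf)
        converged = False
        for sweep in range(max_sweeps):
            max_delta = 0.0
            for j in range(p):
                rho = (c[j] - G[j] @ beta + G[j, j] * beta[j]) / nobs
                thr = lam * l1_ratio * pf[j]
                denom = G[j, j] / nobs + lam * (1.0 - l1_ratio) * pf[j]
                if denom <= 0:
                    new = 0.0
                else:
                    new = np.sign(rho) * max(abs(rho) - thr, 0.0) / denom
                max_delta = max(max_delta, scale2[j] * (new - beta[j]) ** 2)
                beta[j] = new
            new_obj = _objective(G, c, yss, nobs, beta, lam, l1_ratio, pf)
            assert new_obj <= obj + 1e-10 * (1 + abs(obj)), (
                f"objective increased: {obj} -> {new_obj}"
            )
            obj = new_obj
            last_delta = max_delta
            if max_delta < tol:
                sweeps[li] = sweep + 1
                converged = True
                break
        if not converged:
            sweeps[li] = -1
        B[li] = beta
    return B, sweeps, last_delta


def _center(X, y):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm = X.mean(axis=0)
    ym = y.mean()
    return X - xm, y - ym, xm, ym


def enet_path(X, y, lambdas, l1_ratio=0.5, penalty_factor=None,
              tol=1e-7, max_sweeps=10_000, debug=False):
    """Coefficients and intercepts along a descending lambda path.

    Returns ``(coefs, intercepts)`` with ``coefs`` of shape
    ``(n_lambda, p)``. Raises :class:`ConvergenceError` if any path point
    fails to converge.
    """
    Xc, yc, xm, ym = _center(X, y)
    n, p = Xc.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    if pf.shape != (p,) or np.any(pf < 0):
        raise ValueError("penalty_factor must be a nonnegative vector of length p")
    lambdas = np.asarray(lambdas, float)
    if np.any(lambdas < 0):
        raise ValueError("lambda must be >= 0")

    # Unpenalized columns are profiled out exactly (Frisch–Waugh): CD runs
    # on the residualized penalized block, and the unpenalized coefficients
    # are recovered by least squares at each lambda. This keeps the
    # iteration well-conditioned even when a resample makes an unpenalized
    # column nearly constant.
    pen = pf > 0
    if (~pen).any():
        Zc = Xc[:, ~pen]
        Pc = Xc[:, pen]
        Zpinv = np.linalg.pinv(Zc)
        Pt = Pc - Zc @ (Zpinv @ Pc)
        yt = yc - Zc @ (Zpinv @ yc)
    else:
        Pt, yt = Xc, yc
    G = Pt.T @ Pt
    c = Pt.T @ yt
    # convergence scale: var(x_j) / var(y), so tol is in fraction-of-
    # outcome-variance units (glmnet's convention, default 1e-7)
    var_y = max(yt @ yt / n, np.finfo(float).tiny)
    scale2 = (np.diag(G) / n) / var_y
    if debug:
        Bpen, sweeps, last_delta = _cd_path_debug(
            G, c, float(yt @ yt), n, lambdas, l1_ratio, pf[pen], scale2, tol, max_sweeps
        )
    else:
        Bpen, sweeps, last_delta = _cd_path_kernel(
            G, c, n, lambdas, float(l1_ratio), pf[pen], scale2, float(tol), max_sweeps
        )
    if np.any(sweeps < 0):
        raise ConvergenceError(
            f"coordinate descent did not converge within {max_sweeps} sweeps "
            f"(last max coefficient change {last_delta:.3e})"
        )
    if (~pen).any():
        B = np.zeros((len(lambdas), p))
        B[:, pen] = Bpen
        B[:, ~pen] = (Zpinv @ (yc[:, None] - Pc @ Bpen.T)).T
    else:
        B = Bpen
    intercepts = ym - B @ xm
    return B, intercepts


def enet_fit(X, y, lam, l1_ratio=0.5, penalty_factor=None,
             tol=1e-7, max_sweeps=10_000, debug=False):
    """Solve the elastic net at a single penalty; returns ``(coef, intercept)``."""
    B, b0 = enet_path(
        X, y, np.array([float(lam)]), l1_ratio=l1_ratio,
        penalty_factor=penalty_factor, tol=tol, max_sweeps=max_sweeps,
        debug=debug,
    )
    return B[0], float(b0[0])


def lambda_max(X, y, l1_ratio=0.5, penalty_factor=None):
    """Smallest penalty at which every penalized coefficient is exactly zero.

    With unpenalized features present, the KKT bound is evaluated on the
    residual of the OLS fit of y on the intercept plus the unpenalized
    features: ``lambda_max = max_j |x_j' r| / (n * l1_ratio * pf_j)`` over
    features with ``pf_j > 0``.
    """
    Xc, yc, _, _ = _center(X, y)
    n, p = Xc.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    if l1_ratio <= 0:
        raise ValueError("l1_ratio must be positive for a finite lambda_max")
    unpen = pf == 0
    r = yc
    if unpen.any():
        U = Xc[:, unpen]
        coef, *_ = np.linalg.lstsq(U, yc, rcond=None)
        r = yc - U @ coef
    pen = np.where(pf > 0)[0]
    if pen.size == 0:
        raise ValueError("no penalized features")
    scores = np.abs(Xc[:, pen].T @ r) / (n * l1_ratio * pf[pen])
    # round-off guard so the KKT inequality holds exactly at lambda_max
    return float(max(scores.max() * (1.0 + 1e-10), np.finfo(float).tiny))


def lambda_grid(lmax, n_lambda=100, min_ratio=1e-4):
    """Geometric grid of ``n_lambda`` points from ``lmax`` down to ``lmax*min_ratio``."""
    if not 0 < min_ratio < 1:
        raise ValueError("min_ratio must be in (0, 1)")
    return lmax * np.geomspace(1.0, min_ratio, n_lambda)


def _fold_ids(n, n_folds, rng):
    # round-robin keeps every fold non-empty for any n >= n_folds
    ids = np.arange(n) % n_folds
    return ids[rng.permutation(n)] if rng is not None else ids


def cv_select_lambda(X, y, l1_ratio=0.5, penalty_factor=None, n_folds=5,
                     n_lambda=100, lambda_min_ratio=1e-4, rng=None,
                     lambdas=None, tol=1e-7, max_sweeps=10_000, groups=None):
    """Select the penalty by K-fold CV, minimum mean held-out deviance.

    For a Gaussian outcome the deviance is the held-out mean squared error.
    The grid is geometric from lambda_max of the supplied data; ties in the
    mean deviance resolve toward the larger (more parsimonious) lambda.

    ``groups`` (optional, one label per row) makes fold assignment
    group-aware: rows sharing a label never straddle a train/test split.
    Inside a bootstrap resample the labels are the original subject indices,
    so duplicated subjects cannot leak from a training fold into its test
    fold — without this the held-out deviance rewards overfit (small)
    penalties.

    Returns ``(lambda_star, lambdas, mean_deviance)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} rows, got {n}")
    if lambdas is None:
        lmax = lambda_max(X, y, l1_ratio=l1_ratio, penalty_factor=penalty_factor)
        lambdas = lambda_grid(lmax, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, float)
    if groups is not None:
        groups = np.asarray(groups)
        uniq, inverse = np.unique(groups, return_inverse=True)
        if len(uniq) < n_folds:
            raise ValueError(
                f"need at least n_folds={n_folds} distinct groups, got {len(uniq)}"
            )
        fold = _fold_ids(len(uniq), n_folds, rng)[inverse]
    else:
        fold = _fold_ids(n, n_folds, rng)
    # expected deviance pooled over all held-out observations (each row is
    # held out exactly once); with group-aware folds of uneven size this is
    # less noisy than a mean of per-fold MSEs and matches the cv.glmnet
    # convention
    sse = np.zeros(len(lambdas))
    for k in range(n_folds):
        test = fold == k
        B, b0 = enet_path(
            X[~test], y[~test], lambdas, l1_ratio=l1_ratio,
            penalty_factor=penalty_factor, tol=tol, max_sweeps=max_sweeps,
        )
        resid = y[test][None, :] - (B @ X[test].T + b0[:, None])
        sse += np.sum(resid**2, axis=1)
    mean_dev = sse / n
    best = int(np.argmin(mean_dev))  # first minimum = largest lambda on tie
    return float(lambdas[best]), lambdas, mean_dev


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ElasticNetCD(RegressorMixin, BaseEstimator):
    """Elastic-net regressor backed by the coordinate-descent solver.

    Parameters follow scikit-learn conventions: ``alpha`` is the overall
    penalty strength (lambda above) and ``l1_ratio`` the L1 mixing fraction.
    ``penalty_factor`` holds per-feature weights; zero leaves a feature
    unpenalized.
    """

    def __init__(self, alpha=1.0, l1_ratio=0.5, penalty_factor=None,
                 tol=1e-7, max_iter=10_000):
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.penalty_factor = penalty_factor
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D and row-aligned with y")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite")
        coef, intercept = enet_fit(
            X, y, self.alpha, l1_ratio=self.l1_ratio,
            penalty_factor=self.penalty_factor, tol=self.tol,
            max_sweeps=self.max_iter,
        )
        self.coef_ = coef
        self.intercept_ = intercept
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_ + self.intercept_
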