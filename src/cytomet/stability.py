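"""Bootstrap-stabilized elastic-net variable selection.

Penalized regression yields no asymptotically valid p-values, so predictor
relevance is assessed by stability under resampling: the data are resampled
with replacement B times; at each resample the elastic-net penalty is chosen
by K-fold cross-validation (minimum held-out deviance) and the model refit;
a predictor's variable inclusion probability (VIP) is the fraction of
resamples in which its coefficient is nonzero.  Predictors with VIP at or
above a threshold (0.75 by default) are "selected".  Bootstrap coefficient
means and percentile confidence intervals accompany the VIPs.

Nuisance covariates participate in every model with penalty factor 0 (never
shrunk, never dropped) and are excluded from VIP reporting and selection.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .enet import (
    NONZERO_TOL,
    cv_select_lambda,
    enet_fit,
)

logger = logging.getLogger(__name__)


@dataclass
class EnetConfig:
    """Configuration of the stability-selection procedure.

    Defaults are the published procedure: 5-fold CV per bootstrap, 5,000
    resamples, VIP threshold 0.75, 95% percentile intervals.  ``l1_ratio``
    (the L1/L2 mix) is not stated in the source procedure; 0.5 is the
    neutral equal-mix default.
    """

    l1_ratio: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    n_folds: int = 5
    n_bootstrap: int = 5000
    vip_threshold: float = 0.75
    ci_level: float = 0.95
    penalty_factors: np.ndarray | None = None
    standardize: bool = True
    convergence_tol: float = 1e-7
    max_sweeps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.l1_ratio <= 1:
            raise ValueError("l1_ratio must be in (0, 1]")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.vip_threshold < 1:
            raise ValueError("vip_threshold must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class StabilityResult:
    """Per-predictor stability summary plus the per-bootstrap lambda trace."""

    table: pd.DataFrame  # predictor, vip, boot_mean_coef, ci_low, ci_high, selected
    lambda_trace: np.ndarray
    vip_threshold: float
    nuisance_names: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return list(sel.sort_values("vip", ascending=False)["predictor"])


class StabilityElasticNet(BaseEstimator):
    """Bootstrap stability selection around the elastic net (estimator form).

    Parameters
    ----------
    l1_ratio : float
        L1 mixing fraction of the elastic-net penalty, in (0, 1].
    n_lambda, lambda_min_ratio : int, float
        Geometric penalty grid, from lambda_max down to
        ``lambda_max * lambda_min_ratio``.
    n_folds : int
        Folds of the per-bootstrap cross-validation that picks the penalty
        by minimum held-out deviance.
    n_bootstrap : int
        Number of with-replacement resamples (B).
    vip_threshold : float
        Selection threshold on the variable inclusion probability.
    ci_level : float
        Level of the percentile bootstrap interval on the coefficients.
    standardize : bool
        Standardize predictor columns within each resample before
        penalization (the glmnet / MATLAB-lasso default, making the penalty
        scale-equivariant); coefficients are reported on the input scale.
    random_state : int
        Seed; the whole procedure is deterministic given it.

    Fitted attributes (penalized predictors only, in input column order):
    ``vip_``, ``boot_coef_mean_``, ``ci_low_``, ``ci_high_``, ``selected_``,
    plus ``lambda_trace_`` (selected penalty per bootstrap) and
    ``feature_names_``.
    """

    def __init__(self, l1_ratio=0.5, n_lambda=100, lambda_min_ratio=1e-4,
                 n_folds=5, n_bootstrap=5000, vip_threshold=0.75,
                 ci_level=0.95, standardize=True, tol=1e-7, max_iter=10_000,
                 random_state=0):
        self.l1_ratio = l1_ratio
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.n_folds = n_folds
        self.n_bootstrap = n_bootstrap
        self.vip_threshold = vip_threshold
        self.ci_level = ci_level
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, penalty_factor=None, feature_names=None):
        """Run the bootstrap; X holds penalized predictors and (optionally)
        unpenalized nuisance columns, distinguished by ``penalty_factor``."""
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = list(X.columns)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y must be row-aligned")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
        if pf.shape != (p,):
            raise ValueError("penalty_factor must have one entry per column")
        penalized = pf > 0

        rng = np.random.default_rng(self.random_state)
        B = int(self.n_bootstrap)
        coefs = np.empty((B, p))
        lam_trace = np.empty(B)
        n_degenerate = 0
        for b in range(B):
            idx = rng.integers(0, n, n)
            Xb, yb = X[idx], y[idx]
            sd = Xb.std(axis=0)
            if np.any((sd == 0) & penalized):
                n_degenerate += 1  # kernel pins such coefficients at zero
            if self.standardize:
                # per-resample scale-equivariant penalty; coefficients are
                # mapped back to the input scale below
                sd_safe = np.where(sd > 0, sd, 1.0)
                Xb = Xb / sd_safe
            else:
                sd_safe = np.ones_like(sd)
            lam_b, _, _ = cv_select_lambda(
                Xb, yb, l1_ratio=self.l1_ratio, penalty_factor=pf,
                n_folds=self.n_folds, n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio, rng=rng,
                tol=self.tol, max_sweeps=self.max_iter,
                groups=idx,  # duplicated subjects share a fold
            )
            coef_b, _ = enet_fit(
                Xb, yb, lam_b, l1_ratio=self.l1_ratio, penalty_factor=pf,
                tol=self.tol, max_sweeps=self.max_iter,
            )
            coefs[b] = coef_b / sd_safe
            lam_trace[b] = lam_b
        if n_degenerate:
            logger.info(
                "%d bootstrap resample(s) had a constant penalized column "
                "(coefficient pinned at zero, counted as non-inclusion)",
                n_degenerate,
            )

        lo = (1.0 - self.ci_level) / 2.0
        pen_idx = np.where(penalized)[0]
        pen_coefs = coefs[:, pen_idx]
        self.feature_names_ = [feature_names[j] for j in pen_idx]
        self.nuisance_names_ = [feature_names[j] for j in np.where(~penalized)[0]]
        self.vip_ = np.mean(np.abs(pen_coefs) > NONZERO_TOL, axis=0)
        self.boot_coef_mean_ = pen_coefs.mean(axis=0)
        self.ci_low_ = np.quantile(pen_coefs, lo, axis=0)
        self.ci_high_ = np.quantile(pen_coefs, 1.0 - lo, axis=0)
        self.selected_ = self.vip_ >= self.vip_threshold
        self.lambda_trace_ = lam_trace
        self.boot_coefs_ = pen_coefs
        return self

    def results_(self) -> StabilityResult:
        """Fitted results as a :class:`StabilityResult`."""
        table = pd.DataFrame(
            dict(
                predictor=self.feature_names_,
                vip=self.vip_,
                boot_mean_coef=self.boot_coef_mean_,
                ci_low=self.ci_low_,
                ci_high=self.ci_high_,
                selected=self.selected_,
            )
        )
        return StabilityResult(
            table=table,
            lambda_trace=self.lambda_trace_,
            vip_threshold=self.vip_threshold,
            nuisance_names=list(self.nuisance_names_),
        )


def bootstrap_vip(X, y, nuisance=None, config: EnetConfig | None = None) -> StabilityResult:
    """Functional wrapper over :class:`StabilityElasticNet`.

    ``X`` holds the penalized predictors; ``nuisance`` (optional) holds
    unpenalized covariates that join every model but never compete for
    selection.  DataFrames contribute their column names to the report.
    """
    config = config or EnetConfig()

    def _names(M, prefix):
        if isinstance(M, pd.DataFrame):
            return list(M.columns), M.to_numpy(float)
        M = np.asarray(M, float)
        return [f"{prefix}{j}" for j in range(M.shape[1])], M

    xnames, Xv = _names(X, "x")
    if config.penalty_factors is not None:
        pf_pen = np.asarray(config.penalty_factors, float)
    else:
        pf_pen = np.ones(Xv.shape[1])
    if nuisance is not None:
        znames, Zv = _names(nuisance, "z")
        full = np.column_stack([Xv, Zv])
        names = xnames + znames
        pf = np.concatenate([pf_pen, np.zeros(Zv.shape[1])])
    else:
        full, names, pf = Xv, xnames, pf_pen
    est = StabilityElasticNet(
        l1_ratio=config.l1_ratio, n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio, n_folds=config.n_folds,
        n_bootstrap=config.n_bootstrap, vip_threshold=config.vip_threshold,
        ci_level=config.ci_level, standardize=config.standardize,
        tol=config.convergence_tol, max_iter=config.max_sweeps,
        random_state=config.seed,
    )
    est.fit(full, y, penalty_factor=pf, feature_names=names)
    return est.results_()


def l1_ratio_sweep(X, y, nuisance=None, config: EnetConfig | None = None,
                   l1_ratios=(0.25, 0.5, 0.75, 1.0)) -> pd.DataFrame:
    """Sensitivity of the VIPs to the (unstated) L1/L2 mixing fraction.

    Re-runs the bootstrap at each ``l1_ratio`` with the same seed; returns a
    long frame (l1_ratio, predictor, vip, selected) for comparing the
    selected sets across mixes.
    """
    config = config or EnetConfig()
    frames = []
    for l1 in l1_ratios:
        cfg = dataclasses.replace(config, l1_ratio=float(l1))
        res = bootstrap_vip(X, y, nuisance=nuisance, config=cfg)
        t = res.table[["predictor", "vip", "selected"]].copy()
        t.insert(0, "l1_ratio", float(l1))
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def threshold_vip(result: StabilityResult, threshold: float = 0.75) -> list[str]:
    """Predictors with VIP >= threshold, sorted by VIP descending.

    Nuisance covariates are never part of the result table and so are never
    returned.
    """
    t = result.table
    sel = t[t["vip"] >= threshold].sort_values("vip", ascending=False)
    return list(sel["predictor"])
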