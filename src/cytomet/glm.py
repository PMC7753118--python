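"""Confirmatory generalized-linear-model fits.

After stability selection, the surviving predictors' effects on a metabolite
are re-estimated on the raw (unnormalized) scale in a Gaussian identity-link
GLM together with all nuisance covariates, reporting per-term coefficient,
standard error, Wald statistic (b/se)^2 and its chi-square(1) p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class GlmResult:
    """Per-term Wald table plus model log-likelihood and sample size."""

    table: pd.DataFrame  # term, b, se, wald, p
    llf: float
    n: int

    def term(self, name: str) -> pd.Series:
        rows = self.table[self.table["term"] == name]
        if rows.empty:
            raise KeyError(f"no term named {name!r}")
        return rows.iloc[0]


def _as_frame(M, prefix: str) -> pd.DataFrame:
    if M is None:
        return pd.DataFrame()
    if isinstance(M, pd.Series):
        M = M.to_frame()
    if isinstance(M, pd.DataFrame):
        return M.reset_index(drop=True).astype(float)
    M = np.atleast_2d(np.asarray(M, float))
    if M.shape[0] == 1:
        M = M.T
    return pd.DataFrame(M, columns=[f"{prefix}{j}" for j in range(M.shape[1])])


def fit_glm(outcome, predictors, covariates=None) -> GlmResult:
    """Gaussian identity-link GLM of an outcome on predictors + covariates.

    Wald = (b/se)^2 per term, with a two-sided p from chi-square(1) — the
    square of the usual z test.  Raises on rank-deficient designs (listing
    the collinear columns) and on n too small for the design.
    """
    y = np.asarray(outcome, float)
    Xp = _as_frame(predictors, "x")
    Xc = _as_frame(covariates, "z")
    design = pd.concat([Xp, Xc], axis=1)
    design.insert(0, "intercept", 1.0)
    if len(y) != len(design):
        raise ValueError("outcome and design must be row-aligned")
    if len(y) <= design.shape[1] + 1:
        raise ValueError(
            f"n={len(y)} too small for {design.shape[1]} design columns"
        )
    Xmat = design.to_numpy(float)
    if not (np.all(np.isfinite(Xmat)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in the design/outcome")
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        _, R = np.linalg.qr(Xmat)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xmat.shape) * np.finfo(float).eps
        bad = [design.columns[j] for j in range(Xmat.shape[1]) if diag[j] < tol]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    fit = sm.GLM(y, Xmat, family=sm.families.Gaussian()).fit()
    b = fit.params
    se = fit.bse
    wald = (b / se) ** 2
    p = sps.chi2.sf(wald, df=1)
    table = pd.DataFrame(
        dict(term=list(design.columns), b=b, se=se, wald=wald, p=p)
    )
    return GlmResult(table=table, llf=float(fit.llf), n=len(y))


def step1_glu_model(data: pd.DataFrame, covariate_names=()) -> GlmResult:
    """A-priori model: IL-9 and TNF-a as joint predictors of glutamate.

    ``data`` must contain columns ``IL-9``, ``TNF-a`` and ``Glu``; any
    ``covariate_names`` present are entered unpenalized alongside. Pure
    delegation to :func:`fit_glm`.
    """
    needed = ["IL-9", "TNF-a", "Glu"]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks column(s): {missing}")
    cov = data[list(covariate_names)] if covariate_names else None
    return fit_glm(data["Glu"], data[["IL-9", "TNF-a"]], cov)
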