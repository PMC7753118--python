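"""Analyte QC and the univariate statistical layer.

Implements the limit-of-detection exclusion rule for multiplex immunoassay
panels (analytes with more than a given fraction of non-detected values are
dropped; remaining non-detects are imputed at a fraction of the LOD),
two-sample pooled-variance t tests, 2x2 Pearson chi-square, covariate-
adjusted group comparison (ANCOVA partial F for the group term), Pearson
correlation, and Benjamini–Hochberg FDR adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AnalytePanel:
    """Subjects x analytes concentration matrix with censoring metadata.

    ``values`` holds NaN wherever ``nd_mask`` is True (a non-detected entry
    has no observed value until imputation).  ``lod`` is the per-analyte
    limit of detection; ``retained`` is the per-analyte QC flag.
    """

    values: pd.DataFrame
    nd_mask: pd.DataFrame
    lod: pd.Series
    retained: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.retained is None:
            self.retained = pd.Series(True, index=self.values.columns)
        if list(self.values.columns) != list(self.nd_mask.columns):
            raise ValueError("values and nd_mask must share columns")

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def nd_fraction(self) -> pd.Series:
        return self.nd_mask.mean(axis=0)

    def retained_values(self) -> pd.DataFrame:
        """Values of retained analytes only."""
        keep = [a for a in self.values.columns if self.retained[a]]
        return self.values[keep]


@dataclass
class TestResult:
    """One univariate test: statistic, df, raw p and (optionally) FDR q."""

    label: str
    stat_name: str  # "t" | "chi2" | "F" | "r"
    statistic: float
    df: object
    p: float
    q: float | None = None


def nd_exclusion(
    panel: AnalytePanel, threshold: float = 0.20, impute_factor: float = 0.5
) -> AnalytePanel:
    """Apply the non-detected-fraction exclusion rule.

    An analyte is retained iff its ND fraction is <= ``threshold`` (strict
    ``>`` excludes). Non-detected cells of retained analytes are imputed at
    ``impute_factor * LOD`` (LOD/2 by default). Excluded analytes keep their
    (censored) values but are flagged not retained.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    frac = panel.nd_fraction
    retained = frac <= threshold
    excluded = [a for a in panel.analyte_names if not retained[a]]
    if excluded:
        logger.info(
            "excluding %d analyte(s) with ND fraction > %.0f%%: %s",
            len(excluded), 100 * threshold, ", ".join(excluded),
        )
    values = panel.values.copy()
    for a in panel.analyte_names:
        if retained[a]:
            values.loc[panel.nd_mask[a], a] = impute_factor * panel.lod[a]
    return replace(panel, values=values, retained=retained)


def pooled_t(mean1, sd1, n1, mean2, sd2, n2, label: str = "") -> TestResult:
    """Two-sample pooled-variance (Student) t test from summary statistics.

    ``t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2))`` with
    ``sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)`` and a two-tailed
    p from the t distribution with ``n1 + n2 - 2`` df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(label, "t", float(t), df, float(p))


def pooled_t_vectors(x1, x2, label: str = "") -> TestResult:
    """Pooled-variance t test from raw per-subject vectors."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    return pooled_t(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2),
        label=label,
    )


def chi_square_2x2(a, b, c, d, label: str = "") -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum() <= 0:
        raise ValueError("empty table")
    for axis, name in ((0, "column"), (1, "row")):
        margins = table.sum(axis=axis)
        if np.any(margins == 0):
            idx = int(np.where(margins == 0)[0][0])
            raise ValueError(f"{name} {idx} has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(label, "chi2", float(chi2), int(df), float(p))


def _design_matrix(group, covariates) -> tuple[np.ndarray, list[str]]:
    labels = pd.Series(group).astype(str)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    indicator = (labels == levels[1]).to_numpy(float)
    logger.debug("group coding: %s=0 (reference), %s=1", levels[0], levels[1])
    cols = [np.ones_like(indicator), indicator]
    names = ["intercept", f"group[{levels[1]}]"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for name in cov.columns:
            cols.append(cov[name].to_numpy(float))
            names.append(str(name))
    X = np.column_stack(cols)
    return X, names


def ancova_group_effect(outcome, group, covariates=None, label: str = "") -> TestResult:
    """Partial F (1 numerator df) for the group term, adjusting for covariates.

    OLS of outcome on intercept + group indicator + covariates; the group
    partial F equals the squared t of the group coefficient.
    """
    y = np.asarray(outcome, float)
    X, names = _design_matrix(group, covariates)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in outcome or design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    t_group = fit.tvalues[1]
    F = float(t_group**2)
    df = (1, int(fit.df_resid))
    p = float(sps.f.sf(F, *df))
    return TestResult(label, "F", F, df, p)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns whose removal restores full rank (QR pivot heuristic)."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in range(X.shape[1]) if diag[j] < tol]


def pearson_r(x, y, label: str = "") -> TestResult:
    """Pearson correlation with two-tailed p via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return TestResult(label, "r", float(r), len(x) - 2, float(p))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def attach_fdr(results: list[TestResult]) -> list[TestResult]:
    """Fill the ``q`` field of a family of test results (one BH pass)."""
    q = fdr_adjust([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def group_stats_table(
    subjects: pd.DataFrame,
    metabolites_wide: pd.DataFrame,
    tissue: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group-comparison table (one FDR family across all rows).

    Rows: age (t), sex (chi-square on the 2x2 sex-by-group table), the three
    voxel tissue percentages if given (t), and each metabolite column (t).
    Column layout mirrors the conventional cohort table: per-group mean/SD,
    statistic, raw p and BH q.
    """
    groups = sorted(subjects["group"].astype(str).unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups expected")
    g1, g2 = groups  # alphabetical: BD, HC
    in1 = subjects["group"].astype(str) == g1
    rows: list[dict] = []
    results: list[TestResult] = []

    def add_t(label, series):
        x1 = series[in1.to_numpy()].dropna().to_numpy(float)
        x2 = series[~in1.to_numpy()].dropna().to_numpy(float)
        res = pooled_t_vectors(x1, x2, label=label)
        results.append(res)
        rows.append(
            dict(label=label, mean_bd=x1.mean(), sd_bd=x1.std(ddof=1),
                 mean_hc=x2.mean(), sd_hc=x2.std(ddof=1),
                 stat_name="t", statistic=res.statistic, p=res.p)
        )

    add_t("age", subjects["age"])
    sex = subjects["sex"].astype(str)
    a = int(((sex == "M") & in1).sum())
    b = int(((sex == "F") & in1).sum())
    c = int(((sex == "M") & ~in1).sum())
    d = int(((sex == "F") & ~in1).sum())
    res = chi_square_2x2(a, b, c, d, label="sex")
    results.append(res)
    rows.append(
        dict(label="sex", mean_bd=np.nan, sd_bd=np.nan, mean_hc=np.nan,
             sd_hc=np.nan, stat_name="chi2", statistic=res.statistic, p=res.p)
    )
    if tissue is not None:
        aligned = tissue.reindex(subjects["subject_id"])
        for col in ("gm_pct", "wm_pct", "csf_pct"):
            add_t(col, aligned[col].reset_index(drop=True))
    met = metabolites_wide.reindex(subjects["subject_id"]).reset_index(drop=True)
    for col in met.columns:
        add_t(col, met[col])

    attach_fdr(results)
    table = pd.DataFrame(rows)
    table["q"] = [r.q for r in results]
    return table


def ancova_table(
    subjects: pd.DataFrame, metabolites_wide: pd.DataFrame
) -> pd.DataFrame:
    """Age- and sex-adjusted group comparison per metabolite (partial F)."""
    met = metabolites_wide.reindex(subjects["subject_id"]).reset_index(drop=True)
    sex01 = (subjects["sex"].astype(str) == "F").astype(float)
    results = []
    for col in met.columns:
        ok = met[col].notna().to_numpy()
        cov = pd.DataFrame(
            {"age": subjects["age"].to_numpy(float)[ok], "sex": sex01.to_numpy()[ok]}
        )
        res = ancova_group_effect(
            met[col].to_numpy(float)[ok],
            subjects["group"].astype(str).to_numpy()[ok],
            cov,
            label=col,
        )
        results.append(res)
    attach_fdr(results)
    return pd.DataFrame(
        [
            dict(label=r.label, stat_name="F", statistic=r.statistic,
                 df_num=r.df[0], df_den=r.df[1], p=r.p, q=r.q)
            for r in results
        ]
    )


def correlation_table(
    metabolites_wide: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of each metabolite against each clinical variable.

    One BH pass over this family (separate from the group-comparison table).
    """
    results = []
    pairs = []
    for met in metabolites_wide.columns:
        for var in clinical.columns:
            x = clinical[var]
            y = metabolites_wide[met]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            res = pearson_r(x[ok], y[ok], label=f"{met}~{var}")
            results.append(res)
            pairs.append((met, var, int(ok.sum())))
    attach_fdr(results)
    return pd.DataFrame(
        [
            dict(metabolite=m, variable=v, n=n, r=r.statistic, p=r.p, q=r.q)
            for (m, v, n), r in zip(pairs, results)
        ]
    )
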