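"""Synthetic cohort generator.

Emulates the structure of a case–control MRS/immunoassay study: a bipolar
(BD) and a healthy-control (HC) group with an age and sex imbalance, a
27-analyte cytokine/chemokine/growth-factor panel drawn multivariate
log-normal with limit-of-detection censoring, and per-subject metabolite
concentrations generated from a sparse linear model on the (uncensored)
analytes plus demographic covariates plus Gaussian noise.  Voxel tissue
fractions and CRLB values are attached so the MRS post-processing layer can
be exercised end to end.  The ground truth (effect map, covariate effects,
latent analyte values) is returned for parameter-recovery scoring.

All randomness flows from a single seed through one named generator; the
same seed yields byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import AnalytePanel

# 27-analyte multiplex panel: 16 cytokines, 6 chemokines, 5 growth factors
CYTOKINES = [
    "IL-1b", "IL-1ra", "IL-2", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8",
    "IL-9", "IL-10", "IL-12", "IL-13", "IL-15", "IL-17", "IFN-g", "TNF-a",
]
CHEMOKINES = ["CCL2", "CCL3", "CCL4", "CCL5", "CCL11", "CXCL10"]
GROWTH_FACTORS = ["bFGF", "G-CSF", "GM-CSF", "PDGF-bb", "VEGF"]
ANALYTES = CYTOKINES + CHEMOKINES + GROWTH_FACTORS

METABOLITES = ["Glu", "Glx", "NAA", "GSH", "mI"]

#: analytes given heavy censoring by default (they fail the >20% ND rule)
HEAVY_CENSORED = ["IL-10", "IL-15", "GM-CSF", "VEGF"]

# plausible plasma medians (pg/mL) for a bead-based 27-plex panel
_MEDIAN_PG_ML = {
    "IL-1b": 2.0, "IL-1ra": 150.0, "IL-2": 5.0, "IL-4": 3.0, "IL-5": 5.0,
    "IL-6": 8.0, "IL-7": 10.0, "IL-8": 12.0, "IL-9": 40.0, "IL-10": 5.0,
    "IL-12": 10.0, "IL-13": 5.0, "IL-15": 8.0, "IL-17": 30.0, "IFN-g": 60.0,
    "TNF-a": 25.0, "CCL2": 40.0, "CCL3": 5.0, "CCL4": 80.0, "CCL5": 2.0e4,
    "CCL11": 90.0, "CXCL10": 500.0, "bFGF": 30.0, "G-CSF": 40.0,
    "GM-CSF": 10.0, "PDGF-bb": 3.0e3, "VEGF": 50.0,
}

# group means/SDs mirrored from the motivating cohort (BD n=63 / HC n=49)
_T1 = {
    "Glu": (8.11, 7.68), "Glx": (9.90, 9.20), "NAA": (6.62, 7.14),
    "GSH": (1.70, 1.54), "mI": (5.24, 4.29),
}
_NOISE_SD = {"Glu": 0.60, "Glx": 0.75, "NAA": 0.29, "GSH": 0.13, "mI": 0.58}

# sparse true effects, as standardized strengths (SD of contribution per
# noise SD); converted to concentration-scale slopes in default_config()
_EFFECT_STRENGTH = {
    ("IL-9", "Glu"): 0.8,
    ("IL-1b", "mI"): 0.8,
    ("IL-4", "mI"): 0.5,
    ("bFGF", "mI"): 0.5,
    ("TNF-a", "GSH"): 0.8,
    ("CCL4", "GSH"): 0.5,
    ("CCL5", "NAA"): 0.8,
}


def lognormal_moments(log_mean, log_sd):
    """Mean and SD of exp(N(log_mean, log_sd^2))."""
    m = np.exp(np.asarray(log_mean) + np.asarray(log_sd) ** 2 / 2.0)
    s = m * np.sqrt(np.expm1(np.asarray(log_sd) ** 2))
    return m, s


def block_correlation(names, families, within=0.6, between=0.3):
    """Family-block exchangeable correlation (within/between block values)."""
    p = len(names)
    fam = {}
    for fid, members in enumerate(families):
        for m in members:
            fam[m] = fid
    R = np.full((p, p), between)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if fam[a] == fam[b]:
                R[i, j] = within
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class SimConfig:
    """Stated world of the synthetic cohort.

    Group sizes, age/sex imbalance, metabolite group means, voxel tissue
    magnitudes and the heavy-censoring pattern mirror the motivating study;
    analyte distribution parameters are stipulated (none were published).
    """

    n_bd: int = 63
    n_hc: int = 49
    analyte_names: list[str] = field(default_factory=lambda: list(ANALYTES))
    metabolite_names: list[str] = field(default_factory=lambda: list(METABOLITES))
    analyte_log_mean: np.ndarray = None  # type: ignore[assignment]
    analyte_log_sd: np.ndarray = None  # type: ignore[assignment]
    analyte_corr: np.ndarray = None  # type: ignore[assignment]
    lod_quantile_per_analyte: np.ndarray = None  # type: ignore[assignment]
    effect_map: dict = field(default_factory=dict)  # (analyte, metabolite) -> slope
    covariate_effects: dict = field(default_factory=dict)  # (covariate, met) -> slope
    noise_sd_per_metabolite: dict = None  # type: ignore[assignment]
    baseline_per_metabolite: dict = None  # type: ignore[assignment]  # met -> (bd, hc)
    crlb_range: tuple = (3.0, 18.0)
    tissue_dirichlet_means: tuple = (21.0, 77.5, 1.5)  # GM, WM, CSF (%)
    tissue_concentration: float = 60.0
    age_mean_bd: float = 46.81
    age_sd_bd: float = 11.94
    age_mean_hc: float = 33.70
    age_sd_hc: float = 11.14
    female_rate_bd: float = 46 / 63
    female_rate_hc: float = 21 / 49
    seed: int = 0

    def validate(self):
        p = len(self.analyte_names)
        R = np.asarray(self.analyte_corr, float)
        if R.shape != (p, p) or not np.allclose(R, R.T):
            raise ValueError("analyte_corr must be a symmetric p x p matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("analyte_corr must have unit diagonal")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ValueError("analyte_corr is not positive definite") from None
        if np.any(np.asarray(self.analyte_log_sd) <= 0):
            raise ValueError("analyte_log_sd must be positive")
        if any(v <= 0 for v in self.noise_sd_per_metabolite.values()):
            raise ValueError("noise SDs must be positive")
        q = np.asarray(self.lod_quantile_per_analyte, float)
        if np.any(q < 0) or np.any(q >= 1):
            raise ValueError("lod_quantile must lie in [0, 1)")
        t = np.asarray(self.tissue_dirichlet_means, float)
        if np.any(t <= 0) or abs(t.sum() - 100.0) > 1e-9:
            raise ValueError("tissue means must be positive and sum to 100")
        return self


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default stated world: 63 BD + 49 HC, 27 analytes, 4 heavily
    censored, sparse analyte->metabolite effects, an age->mI association,
    and the BD-older/more-female confound."""
    names = list(ANALYTES)
    log_mean = np.log([_MEDIAN_PG_ML[a] for a in names])
    log_sd = np.full(len(names), 0.6)
    corr = block_correlation(names, [CYTOKINES, CHEMOKINES, GROWTH_FACTORS])
    lod_q = np.array([0.35 if a in HEAVY_CENSORED else 0.05 for a in names])

    _, analyte_sd = lognormal_moments(log_mean, log_sd)
    sd_of = dict(zip(names, analyte_sd))
    effect_map = {
        (a, m): strength * _NOISE_SD[m] / sd_of[a]
        for (a, m), strength in _EFFECT_STRENGTH.items()
    }
    covariate_effects = {("age", "mI"): 0.03}

    analyte_mean, _ = lognormal_moments(log_mean, log_sd)
    mean_of = dict(zip(names, analyte_mean))
    cfg = SimConfig(
        analyte_log_mean=log_mean,
        analyte_log_sd=log_sd,
        analyte_corr=corr,
        lod_quantile_per_analyte=lod_q,
        effect_map=effect_map,
        covariate_effects=covariate_effects,
        noise_sd_per_metabolite=dict(_NOISE_SD),
        baseline_per_metabolite={},
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    # baselines chosen so generated group means land near the mirrored ones
    baselines = {}
    for met in cfg.metabolite_names:
        eff = sum(
            slope * mean_of[a]
            for (a, m), slope in cfg.effect_map.items()
            if m == met and a in mean_of
        )
        cov_bd = cov_hc = 0.0
        for (cov, m), slope in cfg.covariate_effects.items():
            if m == met and cov == "age":
                cov_bd += slope * cfg.age_mean_bd
                cov_hc += slope * cfg.age_mean_hc
        bd, hc = _T1.get(met, (0.0, 0.0))
        baselines[met] = (bd - eff - cov_bd, hc - eff - cov_hc)
    if not cfg.baseline_per_metabolite:
        cfg.baseline_per_metabolite = baselines
    return cfg.validate()


@dataclass
class GroundTruth:
    """What the generator knows: the sparse effect map, covariate effects
    and the latent (uncensored) analyte values."""

    true_effect_map: dict
    true_covariate_effects: dict
    latent: pd.DataFrame

    def __post_init__(self):
        for analyte, _ in self.true_effect_map:
            if analyte not in self.latent.columns:
                raise ValueError(f"effect on unknown analyte {analyte!r}")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draw clipped into [lo, hi] by redrawing (vectorized)."""
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def generate_cohort(config: SimConfig):
    """Draw one synthetic cohort.

    Returns ``(subjects, panel, metabolites, truth)``: the subjects table,
    the censored :class:`~cytomet.stats.AnalytePanel`, the long-format
    metabolite table (raw concentrations on the water-referenced scale,
    CRLBs, voxel tissue percentages), and the :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_bd + config.n_hc
    ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array(["BD"] * config.n_bd + ["HC"] * config.n_hc)
    is_bd = group == "BD"

    age = np.empty(n)
    age[is_bd] = _truncated_normal(rng, config.age_mean_bd, config.age_sd_bd, 18, 65, config.n_bd)
    age[~is_bd] = _truncated_normal(rng, config.age_mean_hc, config.age_sd_hc, 18, 65, config.n_hc)
    female = np.empty(n, bool)
    female[is_bd] = rng.random(config.n_bd) < config.female_rate_bd
    female[~is_bd] = rng.random(config.n_hc) < config.female_rate_hc
    sex = np.where(female, "F", "M")

    nan_hc = np.full(n, np.nan)
    duration = _truncated_normal(rng, 17.8, 11.9, 0.5, 47.0, config.n_bd)
    onset = nan_hc.copy()
    onset[is_bd] = np.maximum(age[is_bd] - duration, 12.0)
    n_depressive = nan_hc.copy()
    n_depressive[is_bd] = rng.negative_binomial(2, 2 / (2 + 6.24), config.n_bd)
    n_manic = nan_hc.copy()
    n_manic[is_bd] = rng.negative_binomial(1.5, 1.5 / (1.5 + 3.54), config.n_bd)
    bmi = np.empty(n)
    bmi[is_bd] = _truncated_normal(rng, 26.25, 5.34, 16, 50, config.n_bd)
    bmi[~is_bd] = _truncated_normal(rng, 23.5, 3.5, 16, 50, config.n_hc)
    lithium = nan_hc.copy()
    on_li = rng.random(config.n_bd) < 32 / 63
    li_level = np.where(on_li, _truncated_normal(rng, 0.60, 0.15, 0.2, 1.2, config.n_bd), 0.0)
    lithium[is_bd] = li_level
    hdrs = nan_hc.copy()
    hdrs[is_bd] = np.round(_truncated_normal(rng, 16.86, 9.24, 0, 52, config.n_bd))

    subjects = pd.DataFrame(
        dict(subject_id=ids, group=group, age=age, sex=sex, onset=onset,
             n_depressive=n_depressive, n_manic=n_manic, bmi=bmi,
             lithium=lithium, hdrs=hdrs)
    )

    # latent analytes: multivariate log-normal with the requested correlation
    p = len(config.analyte_names)
    L = np.linalg.cholesky(np.asarray(config.analyte_corr, float))
    Z = rng.standard_normal((n, p)) @ L.T
    log_vals = np.asarray(config.analyte_log_mean) + Z * np.asarray(config.analyte_log_sd)
    latent = pd.DataFrame(
        np.exp(log_vals),
        index=pd.Index(ids, name="subject_id"),
        columns=config.analyte_names,
    )

    # LOD = the stated quantile of each analyte's marginal distribution
    q = np.asarray(config.lod_quantile_per_analyte, float)
    with np.errstate(divide="ignore"):
        lod_vals = np.where(
            q > 0,
            np.exp(np.asarray(config.analyte_log_mean)
                   + np.asarray(config.analyte_log_sd) * sps.norm.ppf(q)),
            0.0,
        )
    lod = pd.Series(lod_vals, index=config.analyte_names, name="lod")
    nd_mask = latent.lt(lod, axis=1)
    values = latent.mask(nd_mask)
    panel = AnalytePanel(values=values, nd_mask=nd_mask, lod=lod)

    # metabolites: sparse linear model on the latent analytes + covariates
    cov_values = {"age": age, "sex": female.astype(float)}
    met_rows = []
    tissue = rng.dirichlet(
        np.asarray(config.tissue_dirichlet_means) / 100.0 * config.tissue_concentration,
        size=n,
    ) * 100.0
    fcsf = tissue[:, 2] / tissue.sum(axis=1)
    lo, hi = config.crlb_range
    for met in config.metabolite_names:
        base_bd, base_hc = config.baseline_per_metabolite[met]
        y = np.where(is_bd, base_bd, base_hc).astype(float)
        for (a, m), slope in config.effect_map.items():
            if m == met:
                y = y + slope * latent[a].to_numpy()
        for (cov, m), slope in config.covariate_effects.items():
            if m == met:
                if cov not in cov_values:
                    raise ValueError(f"covariate effect on unavailable covariate {cov!r}")
                y = y + slope * cov_values[cov]
        y = y + rng.normal(0.0, config.noise_sd_per_metabolite[met], n)
        crlb = rng.uniform(lo, hi, n)
        met_rows.append(pd.DataFrame(dict(
            subject_id=ids, metabolite=met,
            raw_conc=y * (1.0 - fcsf),  # generated value is on the corrected scale
            crlb_pct=crlb,
            gm_pct=tissue[:, 0], wm_pct=tissue[:, 1], csf_pct=tissue[:, 2],
        )))
    metabolites = pd.concat(met_rows, ignore_index=True)

    truth = GroundTruth(
        true_effect_map=dict(config.effect_map),
        true_covariate_effects=dict(config.covariate_effects),
        latent=latent,
    )
    return subjects, panel, metabolites, truth


# ---------------------------------------------------------------------------
# fixture I/O (delimited text, lossless round trip)
# ---------------------------------------------------------------------------

def write_fixture(tables, directory) -> list[Path]:
    """Write a generated cohort to CSV files plus a ground-truth sidecar."""
    subjects, panel, metabolites, truth = tables
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df, name, **kw):
        path = directory / name
        df.to_csv(path, index=False, **kw)
        written.append(path)

    _w(subjects, "subjects.csv")
    analytes = panel.values.copy()
    analytes.insert(0, "subject_id", analytes.index)
    _w(analytes, "analytes.csv")
    _w(panel.lod.rename_axis("analyte").reset_index(), "analyte_lod.csv")
    _w(metabolites, "metabolites.csv")
    if truth is not None:
        latent = truth.latent.copy()
        latent.insert(0, "subject_id", latent.index)
        _w(latent, "analytes_latent.csv")
        sidecar = directory / "ground_truth.json"
        sidecar.write_text(json.dumps(dict(
            effect_map=[
                dict(analyte=a, metabolite=m, slope=s)
                for (a, m), s in truth.true_effect_map.items()
            ],
            covariate_effects=[
                dict(covariate=c, metabolite=m, slope=s)
                for (c, m), s in truth.true_covariate_effects.items()
            ],
            latent_file="analytes_latent.csv",
        ), indent=2) + "\n")
        written.append(sidecar)
    return written


def read_fixture(directory):
    """Read a fixture directory back to ``(subjects, panel, metabolites, truth)``.

    The ground-truth sidecar is optional (real data would not have one).
    """
    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv")
    _require(subjects, "subjects.csv",
             ["subject_id", "group", "age", "sex", "onset", "n_depressive",
              "n_manic", "bmi", "lithium", "hdrs"])
    analytes = pd.read_csv(directory / "analytes.csv")
    _require(analytes, "analytes.csv", ["subject_id"])
    values = analytes.set_index("subject_id")
    lod_df = pd.read_csv(directory / "analyte_lod.csv")
    _require(lod_df, "analyte_lod.csv", ["analyte", "lod"])
    lod = lod_df.set_index("analyte")["lod"].reindex(values.columns)
    nd_mask = values.isna()
    panel = AnalytePanel(values=values, nd_mask=nd_mask, lod=lod)
    metabolites = pd.read_csv(directory / "metabolites.csv")
    _require(metabolites, "metabolites.csv",
             ["subject_id", "metabolite", "raw_conc", "crlb_pct",
              "gm_pct", "wm_pct", "csf_pct"])
    truth = None
    sidecar = directory / "ground_truth.json"
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        latent = pd.read_csv(directory / doc["latent_file"]).set_index("subject_id")
        truth = GroundTruth(
            true_effect_map={
                (e["analyte"], e["metabolite"]): e["slope"] for e in doc["effect_map"]
            },
            true_covariate_effects={
                (e["covariate"], e["metabolite"]): e["slope"]
                for e in doc["covariate_effects"]
            },
            latent=latent,
        )
    return subjects, panel, metabolites, truth


def _require(df: pd.DataFrame, fname: str, cols: list[str]):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing column(s) {missing}")
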