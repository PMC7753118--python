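"""End-to-end orchestration: QC -> MRS correction -> univariate statistics
-> per-metabolite stability selection -> GLM confirmation.

The selection and confirmation stages run on the patient (BD) group only,
because the nuisance covariates (onset, episode count, lithium level) are
defined only for patients.  Min–max normalization of predictors and
covariates is fitted once on the full patient sample before bootstrap
resampling; the resulting (mild) leakage is a property of the emulated
procedure and a warning is emitted once per run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enet import MinMaxNormalizer
from .glm import fit_glm
from .mrs import process_metabolites
from .simulate import default_config, generate_cohort, read_fixture, write_fixture
from .stability import EnetConfig, bootstrap_vip
from .stats import (
    ancova_table,
    correlation_table,
    group_stats_table,
    nd_exclusion,
)

logger = logging.getLogger(__name__)

NUISANCE_COVARIATES = ["age", "sex", "onset", "n_episodes", "bmi", "lithium"]
STEP1_PREDICTORS = ["IL-9", "TNF-a"]
STEP1_OUTCOME = "Glu"
SELECTION_OUTCOMES = ["mI", "GSH", "NAA"]


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the published procedure's values."""

    input_dir: str = "."
    output_dir: str = "results"
    nd_threshold: float = 0.20
    crlb_threshold: float = 20.0
    fdr_level: float = 0.05
    l1_ratio: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    n_folds: int = 5
    n_bootstrap: int = 5000
    vip_threshold: float = 0.75
    ci_level: float = 0.95
    outcome_metabolites: list[str] = field(default_factory=lambda: list(SELECTION_OUTCOMES))
    covariates: list[str] = field(default_factory=lambda: list(NUISANCE_COVARIATES))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def enet_config(self) -> EnetConfig:
        return EnetConfig(
            l1_ratio=self.l1_ratio, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio, n_folds=self.n_folds,
            n_bootstrap=self.n_bootstrap, vip_threshold=self.vip_threshold,
            ci_level=self.ci_level, seed=self.seed,
        )


def make_demo(seed: int = 0, directory=None, **overrides):
    """Generate the demo fixture: 63 BD + 49 HC, 27 analytes, 4 heavily
    censored. Returns the tables; writes them if a directory is given."""
    cfg = default_config(seed=seed, **overrides)
    tables = generate_cohort(cfg)
    if directory is not None:
        write_fixture(tables, directory)
    return tables


def _covariate_frame(subjects: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate matrix indexed by subject_id (sex coded M=0, F=1)."""
    out = pd.DataFrame(index=subjects["subject_id"])
    for cov in covariates:
        if cov == "sex":
            out["sex"] = (subjects["sex"].astype(str) == "F").astype(float).to_numpy()
        elif cov == "n_episodes":
            out["n_episodes"] = (
                subjects["n_depressive"].to_numpy(float)
                + subjects["n_manic"].to_numpy(float)
            )
        else:
            out[cov] = subjects[cov].to_numpy(float)
    return out


def _metabolite_wide(processed: pd.DataFrame) -> pd.DataFrame:
    """Reliable, CSF-corrected concentrations, subjects x metabolites."""
    reliable = processed[processed["reliable"]]
    return reliable.pivot(index="subject_id", columns="metabolite",
                          values="corrected_conc")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle.

    Returns the in-memory results keyed by output name. Writes
    ``group_stats.csv``, ``ancova_stats.csv``, ``correlations.csv``,
    ``stability_results.csv``, ``lambda_trace.csv``, ``glm_results.csv``,
    ``metabolites_processed.csv`` and ``manifest.yaml`` under
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"cytomet": __version__},
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    for mod in ("numpy", "pandas", "scipy", "statsmodels", "sklearn"):
        manifest["package"][mod] = __import__(mod).__version__

    subjects, panel, metabolites, _ = read_fixture(config.input_dir)
    manifest["stages"]["input"] = {
        "n_subjects": int(len(subjects)),
        "n_analytes": int(len(panel.analyte_names)),
        "n_metabolite_rows": int(len(metabolites)),
    }

    # --- analyte QC -------------------------------------------------------
    panel = nd_exclusion(panel, threshold=config.nd_threshold)
    excluded = [a for a in panel.analyte_names if not panel.retained[a]]
    manifest["stages"]["nd_exclusion"] = {
        "threshold": config.nd_threshold,
        "excluded_analytes": excluded,
        "n_retained": int(panel.retained.sum()),
    }

    # --- MRS post-processing ---------------------------------------------
    processed = process_metabolites(metabolites, config.crlb_threshold)
    processed.to_csv(outdir / "metabolites_processed.csv", index=False)
    wide = _metabolite_wide(processed)
    manifest["stages"]["mrs"] = {
        "crlb_threshold": config.crlb_threshold,
        "n_unreliable_rows": int((~processed["reliable"]).sum()),
    }

    # --- univariate layer -------------------------------------------------
    tissue = (
        processed.drop_duplicates("subject_id")
        .set_index("subject_id")[["gm_pct", "wm_pct", "csf_pct"]]
    )
    group_stats = group_stats_table(subjects, wide, tissue)
    group_stats.to_csv(outdir / "group_stats.csv", index=False)
    ancova = ancova_table(subjects, wide)
    ancova.to_csv(outdir / "ancova_stats.csv", index=False)
    bd = subjects[subjects["group"].astype(str) == "BD"].reset_index(drop=True)
    clinical_cols = ["age", "onset", "n_depressive", "n_manic", "bmi", "lithium", "hdrs"]
    clinical = bd[clinical_cols].astype(float)
    clinical.index = bd["subject_id"]
    correlations = correlation_table(wide.reindex(bd["subject_id"]), clinical)
    correlations.to_csv(outdir / "correlations.csv", index=False)
    manifest["stages"]["univariate"] = {
        "n_group_rows": int(len(group_stats)),
        "n_correlations": int(len(correlations)),
    }

    # --- selection + confirmation (patients only) -------------------------
    logger.warning(
        "min-max normalization is fitted once on the full patient sample "
        "before bootstrap resampling (emulated procedure); out-of-sample "
        "generalization estimates would need per-resample refitting"
    )
    analyte_values = panel.retained_values().reindex(bd["subject_id"])
    covariate_values = _covariate_frame(bd, config.covariates)
    wide_bd = wide.reindex(bd["subject_id"])

    base_complete = analyte_values.notna().all(axis=1) & covariate_values.notna().all(axis=1)
    enet_cfg = config.enet_config()

    stability_frames = []
    lambda_frames = []
    glm_rows = []

    # step 1: a-priori IL-9 / TNF-a model of glutamate
    step1_rows = base_complete & wide_bd[STEP1_OUTCOME].notna()
    manifest["stages"]["step1"] = {"n": int(step1_rows.sum())}
    res1 = fit_glm(
        wide_bd.loc[step1_rows, STEP1_OUTCOME],
        analyte_values.loc[step1_rows, STEP1_PREDICTORS],
        covariate_values.loc[step1_rows],
    )
    for _, row in res1.table.iterrows():
        glm_rows.append(dict(outcome=STEP1_OUTCOME, step="step1", **row))

    # steps 2 + 3 per outcome metabolite
    norm_X = MinMaxNormalizer().fit(analyte_values.loc[base_complete])
    norm_Z = MinMaxNormalizer().fit(covariate_values.loc[base_complete])
    for met in config.outcome_metabolites:
        rows = base_complete & wide_bd[met].notna()
        y = wide_bd.loc[rows, met].to_numpy(float)
        Xn = norm_X.transform(analyte_values.loc[rows])
        Zn = norm_Z.transform(covariate_values.loc[rows])
        result = bootstrap_vip(Xn, y, nuisance=Zn, config=enet_cfg)
        tab = result.table.copy()
        tab.insert(0, "outcome", met)
        stability_frames.append(tab)
        lambda_frames.append(pd.DataFrame(dict(
            outcome=met,
            bootstrap=np.arange(len(result.lambda_trace)),
            selected_lambda=result.lambda_trace,
        )))
        survivors = result.selected
        manifest["stages"][f"select[{met}]"] = {
            "n": int(rows.sum()), "selected": survivors,
        }
        if survivors:
            res = fit_glm(
                wide_bd.loc[rows, met],
                analyte_values.loc[rows, survivors],
                covariate_values.loc[rows],
            )
            for _, row in res.table.iterrows():
                glm_rows.append(dict(outcome=met, step="confirm", **row))
        else:
            logger.info("no predictors selected for %s", met)
            glm_rows.append(dict(outcome=met, step="confirm",
                                 term="(no predictors selected)",
                                 b=np.nan, se=np.nan, wald=np.nan, p=np.nan))

    stability = pd.concat(stability_frames, ignore_index=True)
    stability.to_csv(outdir / "stability_results.csv", index=False)
    lambda_trace = pd.concat(lambda_frames, ignore_index=True)
    lambda_trace.to_csv(outdir / "lambda_trace.csv", index=False)
    glm_results = pd.DataFrame(glm_rows)
    glm_results.to_csv(outdir / "glm_results.csv", index=False)

    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False)
    )
    return dict(
        group_stats=group_stats, ancova_stats=ancova, correlations=correlations,
        stability_results=stability, lambda_trace=lambda_trace,
        glm_results=glm_results, metabolites_processed=processed,
        manifest=manifest,
    )
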