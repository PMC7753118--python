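"""Post-processing of single-voxel MRS metabolite quantifications.

Spectral fitting (LCModel-style) reports, per subject and metabolite, a
water-referenced concentration and its Cramér–Rao lower bound (CRLB, in %),
and tissue segmentation reports the voxel composition in gray matter, white
matter and CSF. CSF contributes essentially no metabolite signal, so the
apparent concentration is diluted by the CSF fraction of the voxel

    fCSF = %CSF / (%GM + %WM + %CSF)

and the partial-volume–corrected concentration is

    corrected = raw / (1 - fCSF).

Quantifications with CRLB >= 20% are conventionally considered unreliable
and excluded from statistics; they are flagged here, never dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns expected in a metabolite table (long format, one row per
#: subject x metabolite)
METABOLITE_COLUMNS = [
    "subject_id",
    "metabolite",
    "raw_conc",
    "crlb_pct",
    "gm_pct",
    "wm_pct",
    "csf_pct",
]


def csf_fraction(gm_pct, wm_pct, csf_pct):
    """CSF fraction of the voxel, ``csf / (gm + wm + csf)``.

    Parameters may be scalars or arrays, in percent (summing ~100) or in
    fractions (summing ~1) — the fraction is scale-invariant so both
    conventions give the same result.

    Raises
    ------
    ValueError
        If any tissue value is negative or all three sum to zero.
    """
    gm = np.asarray(gm_pct, dtype=float)
    wm = np.asarray(wm_pct, dtype=float)
    csf = np.asarray(csf_pct, dtype=float)
    if np.any(gm < 0) or np.any(wm < 0) or np.any(csf < 0):
        raise ValueError("tissue percentages must be non-negative")
    total = gm + wm + csf
    if np.any(total <= 0):
        raise ValueError(
            "CSF fraction undefined: gm + wm + csf must be positive"
        )
    out = csf / total
    if out.ndim == 0:
        return float(out)
    return out


def correct_concentration(raw_conc, fcsf):
    """Partial-volume correction ``raw / (1 - fCSF)``.

    Raises
    ------
    ValueError
        If ``fcsf`` is outside ``[0, 1)`` or ``raw_conc`` is negative.
    """
    raw = np.asarray(raw_conc, dtype=float)
    f = np.asarray(fcsf, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw concentration must be non-negative")
    if np.any(f < 0) or np.any(f >= 1):
        raise ValueError("fCSF must lie in [0, 1)")
    out = raw / (1.0 - f)
    if out.ndim == 0:
        return float(out)
    return out


def crlb_filter(records: pd.DataFrame, threshold_pct: float = 20.0) -> pd.DataFrame:
    """Flag records as reliable iff CRLB is strictly below ``threshold_pct``.

    Records with a missing CRLB are flagged unreliable with a logged
    warning.  Returns a copy with a boolean ``reliable`` column; rows are
    never dropped.
    """
    if "crlb_pct" not in records.columns:
        raise ValueError("records table lacks a 'crlb_pct' column")
    crlb = pd.to_numeric(records["crlb_pct"], errors="coerce")
    if np.any(crlb.dropna() < 0):
        raise ValueError("crlb_pct must be non-negative")
    missing = crlb.isna()
    if missing.any():
        logger.warning(
            "%d record(s) with missing CRLB flagged unreliable", int(missing.sum())
        )
    out = records.copy()
    out["reliable"] = (crlb < threshold_pct).fillna(False).to_numpy(bool)
    return out


def _tissue_scale(gm, wm, csf) -> str:
    """Detect percent vs fraction convention from the typical tissue sum."""
    total = np.median(np.asarray(gm, float) + np.asarray(wm, float) + np.asarray(csf, float))
    if total > 50:  # percentages summing ~100
        return "percent"
    return "fraction"


def process_metabolites(
    records: pd.DataFrame, crlb_threshold_pct: float = 20.0
) -> pd.DataFrame:
    """Add ``fcsf``, ``corrected_conc`` and ``reliable`` columns.

    ``records`` must follow :data:`METABOLITE_COLUMNS`. Tissue columns are
    accepted either as percentages (summing ~100) or fractions (summing ~1);
    the convention is auto-detected from the sums and logged.
    """
    missing = [c for c in METABOLITE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"metabolite table missing column(s): {missing}")
    scale = _tissue_scale(records["gm_pct"], records["wm_pct"], records["csf_pct"])
    logger.info("tissue columns interpreted as %s", scale)
    out = crlb_filter(records, crlb_threshold_pct)
    out["fcsf"] = csf_fraction(
        out["gm_pct"].to_numpy(float),
        out["wm_pct"].to_numpy(float),
        out["csf_pct"].to_numpy(float),
    )
    out["corrected_conc"] = correct_concentration(
        out["raw_conc"].to_numpy(float), out["fcsf"].to_numpy(float)
    )
    return out
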