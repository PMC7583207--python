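"""Epigenetic age acceleration: the analysis phenotype and descriptives.

DNAm age is an age estimate predicted from methylation; its informative part
is the residual after removing the chronological-age trend.  This module
computes those residuals (per regression stratum), optionally standardizes
multi-tissue measurements first, adjusts the residuals for sex and cell
composition, and produces per-study descriptive statistics.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

CELL_TYPES = [
    "cd8_naive", "cd8_exhausted", "plasmablast", "cd4t", "nk", "mono", "gran",
]


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def compute_age_acceleration(
    df: pd.DataFrame,
    strata: Optional[Sequence[str]] = None,
    dnam_col: str = "dnam_age",
    out_col: str = "raw_acceleration",
) -> pd.DataFrame:
    """Per-stratum OLS residuals of DNAm age on chronological age.

    ``strata`` names the grouping columns (default: ``study_id``); each
    stratum gets its own intercept and slope, so residuals have exactly zero
    mean and zero age-correlation within strata.  A stratum whose ages are
    all equal (or with fewer than 3 members) falls back to intercept-only
    centering with a warning.
    """
    strata = list(strata) if strata is not None else ["study_id"]
    out = df.copy()
    out[out_col] = np.nan
    out["stratum_id"] = out[strata].astype(str).agg("|".join, axis=1)
    for key, grp in out.groupby("stratum_id", sort=False):
        y = grp[dnam_col].to_numpy(dtype=float)
        age = grp["age"].to_numpy(dtype=float)
        degenerate = len(grp) < 3 or np.var(age) < 1e-12
        if degenerate:
            warnings.warn(
                f"stratum {key}: degenerate age variance or n < 3; "
                "intercept-only residualization"
            )
            res = y - y.mean()
        else:
            X = np.column_stack([np.ones_like(age), age])
            res = _ols_residuals(y, X)
        out.loc[grp.index, out_col] = res
    return out


def standardize_multitissue(
    df: pd.DataFrame,
    dnam_col: str = "dnam_age",
    tissue_col: str = "tissue",
) -> pd.DataFrame:
    """Average per-tissue z-scores of DNAm age into one value per individual.

    Each tissue's measurements are standardized to zero mean and unit sample
    (n-1) variance, then averaged over the tissues available for each
    individual.  Tissues with zero variance are rejected.  Returns one row
    per individual with the averaged standardized value in ``dnam_col``.
    """
    work = df.copy()
    zs = np.full(len(work), np.nan)
    for tissue, grp in work.groupby(tissue_col, sort=False):
        if len(grp) < 2:
            raise ValueError(f"tissue {tissue!r}: needs >= 2 individuals")
        v = grp[dnam_col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"tissue {tissue!r}: zero within-tissue variance")
        zs[work.index.get_indexer(grp.index)] = (v - v.mean()) / sd
    work["_z"] = zs
    keep = [c for c in work.columns
            if c not in (dnam_col, tissue_col, "_z")]
    agg = work.groupby("individual_id", as_index=False).agg(
        {**{c: "first" for c in keep if c != "individual_id"}, "_z": "mean"}
    )
    agg = agg.rename(columns={"_z": dnam_col})
    return agg


def adjust_covariates(
    df: pd.DataFrame,
    covariates: Sequence[str] = ("sex",),
    in_col: str = "raw_acceleration",
    out_col: str = "phenotype",
    per_stratum: bool = True,
) -> pd.DataFrame:
    """Residualize acceleration on sex (and optionally cell proportions).

    ``covariates`` may contain ``"sex"`` and/or ``"cells"`` (the 7 estimated
    blood-cell proportions).  When all 7 cell fractions are present they are
    collinear with the intercept (they sum to ~1), so the last one is
    dropped automatically.  Adjustment is per regression stratum by default.
    """
    out = df.copy()
    out[out_col] = np.nan
    group_col = "stratum_id" if (per_stratum and "stratum_id" in out.columns) else None
    groups = out.groupby(group_col, sort=False) if group_col else [(None, out)]
    for key, grp in groups:
        cols: List[np.ndarray] = [np.ones(len(grp))]
        if "sex" in covariates:
            cols.append((grp["sex"].to_numpy() == "male").astype(float))
        if "cells" in covariates:
            present = [c for c in CELL_TYPES if c in grp.columns]
            if not present:
                raise ValueError("cell adjustment requested but no cell columns found")
            use = present
            frac = grp[present].to_numpy(dtype=float)
            if len(present) == len(CELL_TYPES) and np.allclose(frac.sum(axis=1), 1.0, atol=0.05):
                use = present[:-1]
                log.info("dropping collinear cell fraction %s", present[-1])
            for c in use:
                cols.append(grp[c].to_numpy(dtype=float))
        X = np.column_stack(cols)
        y = grp[in_col].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"stratum {key}: missing acceleration values")
        model = sm.OLS(y, X).fit()
        out.loc[grp.index, out_col] = model.resid
    return out


def descriptives(
    df: pd.DataFrame,
    dnam_col: str = "dnam_age",
    age_bin_width: float = 10.0,
    min_bin_n: int = 5,
) -> Dict[str, pd.DataFrame]:
    """Per-study descriptive statistics of DNAm age versus chronological age.

    Returns two tables: ``by_study`` with the Pearson correlation between age
    and DNAm age plus the mean/SD of their absolute deviation, and
    ``variance_by_age`` with the variance of age-adjusted DNAm age within
    decade bins (bins with fewer than ``min_bin_n`` observations skipped).
    """
    rows = []
    for s, grp in df.groupby("study_id", sort=True):
        if len(grp) < 2:
            warnings.warn(f"study {s}: fewer than 2 individuals; skipped")
            continue
        age = grp["age"].to_numpy(dtype=float)
        dnam = grp[dnam_col].to_numpy(dtype=float)
        dev = np.abs(dnam - age)
        if np.var(age) < 1e-12 or np.var(dnam) < 1e-12:
            r = np.nan
        else:
            r = stats.pearsonr(age, dnam)[0]
        rows.append({
            "study_id": s, "n": len(grp), "r_age_dnam": r,
            "abs_dev_mean": float(dev.mean()),
            "abs_dev_sd": float(dev.std(ddof=1)) if len(grp) > 1 else np.nan,
        })
    by_study = pd.DataFrame(rows)

    adj = compute_age_acceleration(df, dnam_col=dnam_col, out_col="_age_adj")
    bins = np.floor(adj["age"] / age_bin_width) * age_bin_width
    var_rows = []
    for b, grp in adj.groupby(bins):
        if len(grp) < min_bin_n:
            continue
        var_rows.append({
            "age_bin": float(b), "n": len(grp),
            "var_age_adjusted": float(grp["_age_adj"].var(ddof=1)),
        })
    return {"by_study": by_study, "variance_by_age": pd.DataFrame(var_rows)}
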