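"""Familial correlation models: within-study pair correlations (Table-2-style
estimates) and the pooled cohabitation-dependent correlation model.

The lifespan model writes the correlation of a relative pair as a function of
its cohabitation clock (t, t0):

    rho(t) = theta - exp(-lambda * t)                      while cohabiting,
    rho(t) = (theta - exp(-lambda * t0)) * exp(-nu*(t-t0)) after separation,

with 0 <= theta <= 2 and lambda, nu >= 0.  At the start of cohabitation the
correlation is theta - 1; lambda is the rate at which similarity builds while
living together and nu the rate at which it dissipates afterwards.  theta,
lambda may differ by pair group ({MZ}, {DZ+SIB}, {PO}, {SPOUSE} by default);
nu is shared unless freed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import FamilyDataset
from .likelihood import (
    LOG2PI,
    FitResult,
    Parameter,
    ParameterSpec,
    lrt,
    maximize,
)

REPORT_RHO_BOUND = 0.99  # reporting clamp only, never applied inside the likelihood


def rho(t, t0, theta, lam, nu):
    """Cohabitation-dependent correlation kernel (vectorized)."""
    t = np.asarray(t, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    cohab = theta - np.exp(-lam * t)
    # separated branch only read where t > t0; clamp so infinite t0 stays finite
    t0s = np.minimum(t0, t)
    dt = np.maximum(t - t0, 0.0)
    sep = (theta - np.exp(-lam * t0s)) * np.exp(-np.asarray(nu) * dt)
    return np.where(t <= t0, cohab, sep)


# ---------------------------------------------------------------------------
# within-study pair correlations
# ---------------------------------------------------------------------------

@dataclass
class PairTypeCorrelation:
    """One row of a within-study familial-correlation table."""

    study_id: str
    pair_type: str
    n_pairs: int
    mean_age: float
    rho_hat: float
    ci: Tuple[float, float]
    p_vs_zero: float
    p_mz_vs_dz: Optional[float] = None
    boundary: bool = False


def _pair_loglik(y1, y2, rho_val, var):
    """Bivariate normal loglik of mean-zero pairs with equal variances."""
    det = var * var * (1.0 - rho_val * rho_val)
    if det <= 0 or var <= 0:
        return -math.inf
    quad = (var * y1 * y1 - 2 * rho_val * var * y1 * y2 + var * y2 * y2) / det
    return float(np.sum(-LOG2PI - 0.5 * math.log(det) - 0.5 * quad))


def fit_pair_correlation(
    y1: np.ndarray,
    y2: np.ndarray,
    seed: int = 0,
    n_starts: int = 3,
) -> FitResult:
    """ML estimate of a single pair correlation with a free common variance.

    The correlation is parameterized on a logistic(-1, 1) scale, so the Wald
    interval reported for it is the Fisher-z interval.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    v0 = float(np.var(np.concatenate([y1, y2]), ddof=1))
    r0 = float(np.clip(np.corrcoef(y1, y2)[0, 1], -0.9, 0.9)) if y1.size > 2 else 0.0
    spec = ParameterSpec([
        Parameter("rho", r0, transform="interval", lo=-REPORT_RHO_BOUND, hi=REPORT_RHO_BOUND),
        Parameter("var", max(v0, 1e-6), transform="log"),
    ])
    fit = maximize(
        lambda p: _pair_loglik(y1, y2, p["rho"], p["var"]),
        spec, n_starts=n_starts, seed=seed,
        n_families=y1.size, n_individuals=2 * y1.size,
    )
    return fit


def _null_pair_fit(y1: np.ndarray, y2: np.ndarray) -> FitResult:
    """Closed-form fit with rho = 0 (variance MLE = mean square)."""
    yy = np.concatenate([y1, y2])
    var = float(np.mean(yy**2))
    ll = _pair_loglik(np.asarray(y1, float), np.asarray(y2, float), 0.0, var)
    return FitResult(
        loglik=ll, n_params=1, estimates={"rho": 0.0, "var": var},
        standard_errors={}, cis={}, converged=True,
        n_families=y1.size, n_individuals=2 * y1.size,
    )


def fit_within_study(
    dataset: FamilyDataset,
    study_id: str,
    min_pairs: int = 3,
    pool_mz_dz: bool = True,
    seed: int = 0,
) -> List[PairTypeCorrelation]:
    """Estimate one correlation per pair type within one study.

    Pair types with fewer than ``min_pairs`` pairs are suppressed.  When both
    MZ and DZ estimates exist, a pooled "MZ and DZ" row and a likelihood-ratio
    p-value for MZ-versus-DZ equality are added.
    """
    mask_study = dataset.edge_study_label == study_id
    rows: List[PairTypeCorrelation] = []
    per_type: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for pt in ("MZ", "DZ", "SIB", "PO", "SPOUSE"):
        m = mask_study & (dataset.edge_rel == pt)
        if m.sum() == 0:
            continue
        per_type[pt] = (dataset.edge_y1[m], dataset.edge_y2[m], dataset.edge_mean_age[m])

    def one(pt: str, y1, y2, ages) -> Optional[PairTypeCorrelation]:
        if y1.size < min_pairs:
            import warnings

            warnings.warn(
                f"study {study_id}: {pt} has {y1.size} pairs (<{min_pairs}); suppressed"
            )
            return None
        fit = fit_pair_correlation(y1, y2, seed=seed)
        null = _null_pair_fit(y1, y2)
        _, p = lrt(null, fit, df=1)
        r = fit.estimates["rho"]
        boundary = abs(r) >= REPORT_RHO_BOUND - 1e-6
        return PairTypeCorrelation(
            study_id=study_id, pair_type=pt, n_pairs=int(y1.size),
            mean_age=float(np.mean(ages)), rho_hat=float(r),
            ci=fit.cis.get("rho", (math.nan, math.nan)),
            p_vs_zero=float(p), boundary=boundary,
        )

    for pt, (y1, y2, ages) in per_type.items():
        row = one(pt, y1, y2, ages)
        if row is not None:
            rows.append(row)

    have = {r.pair_type: r for r in rows}
    if "MZ" in have and "DZ" in have:
        p_eq = test_mz_vs_dz(
            per_type["MZ"][0], per_type["MZ"][1],
            per_type["DZ"][0], per_type["DZ"][1], seed=seed,
        )
        have["MZ"].p_mz_vs_dz = p_eq
        if pool_mz_dz:
            y1 = np.concatenate([per_type["MZ"][0], per_type["DZ"][0]])
            y2 = np.concatenate([per_type["MZ"][1], per_type["DZ"][1]])
            ages = np.concatenate([per_type["MZ"][2], per_type["DZ"][2]])
            row = one("MZ and DZ", y1, y2, ages)
            if row is not None:
                rows.append(row)
    return rows


def test_mz_vs_dz(y1_mz, y2_mz, y1_dz, y2_dz, seed: int = 0) -> float:
    """LRT p-value for equality of the MZ and DZ correlations (df = 1).

    Both zygosities share the study variance; the null constrains a single
    common correlation.
    """

    def ll_free(p):
        return _pair_loglik(y1_mz, y2_mz, p["rho_mz"], p["var"]) + _pair_loglik(
            y1_dz, y2_dz, p["rho_dz"], p["var"]
        )

    def ll_null(p):
        return _pair_loglik(y1_mz, y2_mz, p["rho"], p["var"]) + _pair_loglik(
            y1_dz, y2_dz, p["rho"], p["var"]
        )

    v0 = float(np.var(np.concatenate([y1_mz, y2_mz, y1_dz, y2_dz]), ddof=1))
    b = REPORT_RHO_BOUND
    alt = maximize(
        ll_free,
        ParameterSpec([
            Parameter("rho_mz", 0.2, transform="interval", lo=-b, hi=b),
            Parameter("rho_dz", 0.2, transform="interval", lo=-b, hi=b),
            Parameter("var", max(v0, 1e-6), transform="log"),
        ]),
        n_starts=2, seed=seed, compute_se=False,
    )
    null = maximize(
        ll_null,
        ParameterSpec([
            Parameter("rho", 0.2, transform="interval", lo=-b, hi=b),
            Parameter("var", max(v0, 1e-6), transform="log"),
        ]),
        n_starts=2, seed=seed + 1, compute_se=False,
    )
    _, p = lrt(null, alt, df=1)
    return float(p)


def within_study_table(dataset: FamilyDataset, seed: int = 0) -> "pd.DataFrame":
    """Table-shaped summary of within-study correlations for all studies."""
    import pandas as pd

    rows = []
    for s in sorted(set(dataset.edge_study_label.tolist())):
        for r in fit_within_study(dataset, s, seed=seed):
            rows.append({
                "study_id": r.study_id, "pair_type": r.pair_type,
                "n_pairs": r.n_pairs, "mean_age": round(r.mean_age, 1),
                "rho": r.rho_hat, "ci_lo": r.ci[0], "ci_hi": r.ci[1],
                "p": r.p_vs_zero, "p_mz_vs_dz": r.p_mz_vs_dz,
                "boundary": r.boundary,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pooled lifespan model
# ---------------------------------------------------------------------------

def build_lifespan_spec(
    dataset: FamilyDataset,
    theta_mode: str = "fixed1",       # "fixed1" | "free"
    lambda_mode: str = "per_group",   # "per_group" | "shared"
    nu_mode: str = "shared",          # "shared" | "per_group"
    theta_init: float = 1.0,
    lam_init: float = 0.03,
    nu_init: float = 0.01,
) -> ParameterSpec:
    groups = dataset.groups_present
    params: List[Parameter] = []
    for g in groups:
        params.append(Parameter(
            f"theta_{g}", theta_init, free=(theta_mode == "free"),
            transform="interval", lo=0.0, hi=2.0,
        ))
    lam_groups = groups if lambda_mode == "per_group" else ["ALL"]
    for g in lam_groups:
        params.append(Parameter(f"lam_{g}", lam_init, transform="log"))
    nu_groups = groups if nu_mode == "per_group" else ["ALL"]
    for g in nu_groups:
        params.append(Parameter(f"nu_{g}", nu_init, transform="log"))
    for s, v0 in zip(dataset.studies, dataset.study_var_init):
        params.append(Parameter(f"var_{s}", float(v0), transform="log"))
    return ParameterSpec(params)


def lifespan_edge_rho(values: Dict[str, float], dataset: FamilyDataset) -> np.ndarray:
    """Per-edge model correlation under the lifespan kernel."""
    out = np.empty(dataset.n_edges)
    for g in dataset.groups_present:
        m = dataset.edge_group == g
        theta = values[f"theta_{g}"]
        lam = values.get(f"lam_{g}", values.get("lam_ALL"))
        nu = values.get(f"nu_{g}", values.get("nu_ALL"))
        out[m] = rho(dataset.edge_t[m], dataset.edge_t0[m], theta, lam, nu)
    return out


def fit_lifespan_correlation_model(
    dataset: FamilyDataset,
    theta_mode: str = "fixed1",
    lambda_mode: str = "per_group",
    nu_mode: str = "shared",
    seed: int = 0,
    n_starts: int = 5,
    compute_se: bool = True,
) -> FitResult:
    """Joint ML fit of the cohabitation-dependent correlation model.

    All pairs are pooled; the pairwise correlation follows the kernel with
    the requested theta/lambda/nu sharing, and study residual variances are
    estimated jointly.
    """
    if len(dataset.groups_present) < 2:
        raise ValueError("lifespan model needs pairs from >= 2 relationship groups")

    def objective(values: Dict[str, float]) -> float:
        rho_e = lifespan_edge_rho(values, dataset)
        sv = np.array([values[f"var_{s}"] for s in dataset.studies])
        sd = np.sqrt(sv)
        cov = rho_e * sd[dataset.edge_study_a] * sd[dataset.edge_study_b]
        return dataset.packed.loglik(dataset.full_edge_cov(cov), sv)

    # shrink rate start values until the starting point is feasible
    lam0, nu0 = 0.03, 0.01
    for _ in range(10):
        spec = build_lifespan_spec(dataset, theta_mode, lambda_mode, nu_mode,
                                   lam_init=lam0, nu_init=nu0)
        if math.isfinite(objective(spec.unpack(spec.pack()))):
            break
        lam0 *= 0.4
        nu0 *= 0.4

    fit = maximize(
        objective, spec, n_starts=n_starts, seed=seed, compute_se=compute_se,
        n_families=dataset.packed.n_families,
        n_individuals=dataset.packed.n_individuals,
    )
    fit.extras["model"] = {
        "kind": "lifespan_correlation",
        "theta_mode": theta_mode, "lambda_mode": lambda_mode, "nu_mode": nu_mode,
    }
    fit.extras["data_fingerprint"] = dataset.fingerprint
    return fit


def predicted_rho_curve(
    fit: FitResult,
    group: str,
    ages: Sequence[float],
    t0: float = 18.0,
) -> np.ndarray:
    """Predicted rho(t) for one pair group on an age grid (reporting clamp)."""
    v = fit.estimates
    lam = v.get(f"lam_{group}", v.get("lam_ALL"))
    nu = v.get(f"nu_{group}", v.get("nu_ALL"))
    theta = v.get(f"theta_{group}", 1.0)
    r = rho(np.asarray(ages, float), t0, theta, lam, nu)
    return np.clip(r, -REPORT_RHO_BOUND, REPORT_RHO_BOUND)
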