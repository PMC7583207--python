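"""Cohabitation-dependent variance-components models for relative pairs.

The covariance of relatives i and j is modelled as

    COV_ij = alpha*sigma_A^2 + beta_A*(1 - exp(-lambda_A*t))
                             + beta_C*(1 - exp(-lambda_C*t))      (cohabiting)
    COV_ij = alpha*sigma_A^2 + beta_A*(1 - exp(-lambda_A*t0))*exp(-nu_A*(t-t0))
                             + beta_C*(1 - exp(-lambda_C*t0))*exp(-nu_C*(t-t0))
                                                                   (separated)

where A denotes additive genetic effects, C environmental effects shared
while cohabiting, and E (individual-specific environment) absorbs the rest
of each study's residual variance.  Five variants are fitted and compared by
AIC:

* ``AE``            — constant genetic effects: alpha = doubled kinship,
                      sigma_A^2 free; no cohabitation terms.
* ``COHAB_AE``      — genetic effects build with cohabitation:
                      beta_A = doubled kinship, shared lambda_A/nu_A for
                      non-spouse pairs (spouses carry no genetic term).
* ``COHAB_ACE``     — cohabitation-dependent A and C; beta_C = 1 for all
                      pairs, shared lambda_C/nu_C.
* ``COHAB_CE``      — C and E only; beta_C = 1 for DZ/sibling/spouse pairs
                      and free for MZ and parent-offspring pairs, shared
                      lambda_C/nu_C.  The free multipliers quantify how far
                      the equal-environment assumption is violated.
* ``COHAB_CE_PLUS_A`` — the CE model plus a constant genetic component
                      (alpha = doubled kinship, sigma_A^2 free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import FamilyDataset
from .likelihood import FitResult, Parameter, ParameterSpec, lrt, maximize


class Variant(str, Enum):
    AE = "AE"
    COHAB_AE = "COHAB_AE"
    COHAB_ACE = "COHAB_ACE"
    COHAB_CE = "COHAB_CE"
    COHAB_CE_PLUS_A = "COHAB_CE_PLUS_A"


@dataclass
class VarianceModelSpec:
    """Which variant to fit, with optional overrides of start values."""

    variant: Variant
    init: Optional[Dict[str, float]] = None

    def parameter_names(self) -> List[str]:
        v = self.variant
        if v == Variant.AE:
            return ["sigmaA2"]
        if v == Variant.COHAB_AE:
            return ["lamA", "nuA"]
        if v == Variant.COHAB_ACE:
            return ["lamA", "nuA", "lamC", "nuC"]
        if v == Variant.COHAB_CE:
            return ["betaC_MZ", "betaC_PO", "lamC", "nuC"]
        if v == Variant.COHAB_CE_PLUS_A:
            return ["sigmaA2", "betaC_MZ", "betaC_PO", "lamC", "nuC"]
        raise ValueError(v)

    def build_params(self, dataset: FamilyDataset, shrink: float = 1.0) -> ParameterSpec:
        defaults = {
            "sigmaA2": 0.2, "betaC_MZ": 1.2, "betaC_PO": 0.8,
            "lamA": 0.01, "nuA": 0.005, "lamC": 0.01, "nuC": 0.005,
        }
        if self.init:
            defaults.update(self.init)
        params = [
            Parameter(name, defaults[name] * shrink, transform="log")
            for name in self.parameter_names()
        ]
        for s, v0 in zip(dataset.studies, dataset.study_var_init):
            params.append(Parameter(f"var_{s}", float(v0), transform="log"))
        return ParameterSpec(params)


def cov_kernel(
    t,
    t0,
    const,
    betaA,
    lamA,
    nuA,
    betaC,
    lamC,
    nuC,
):
    """The pairwise covariance kernel (vectorized over edges).

    ``const`` is the constant genetic term alpha*sigma_A^2 already multiplied
    by the pair's doubled kinship; ``betaA``/``betaC`` are the per-edge
    multipliers of the cohabitation kernels.
    """
    t = np.asarray(t, float)
    t0 = np.asarray(t0, float)
    cohab = const + betaA * (1.0 - np.exp(-lamA * t)) + betaC * (1.0 - np.exp(-lamC * t))
    # the separated branch is only read where t > t0; clamp its arguments so
    # infinite t0 (never separated) stays finite
    t0s = np.minimum(t0, t)
    dt = np.maximum(t - t0, 0.0)
    sep = (
        const
        + betaA * (1.0 - np.exp(-lamA * t0s)) * np.exp(-nuA * dt)
        + betaC * (1.0 - np.exp(-lamC * t0s)) * np.exp(-nuC * dt)
    )
    return np.where(t <= t0, cohab, sep)


def cov_pair(
    t: float,
    t0: float,
    kinship2: float,
    variant: Variant,
    values: Dict[str, float],
    group: str = "MZ",
) -> float:
    """Scalar model covariance of one pair under a variant's constraints."""
    const, betaA, betaC = _edge_multipliers(
        variant, values,
        k2=np.array([kinship2]),
        group=np.array([group]),
        rel_is_spouse=np.array([group == "SPOUSE"]),
    )
    val = cov_kernel(
        np.array([t]), np.array([t0]), const, betaA,
        values.get("lamA", 0.0), values.get("nuA", 0.0),
        betaC, values.get("lamC", 0.0), values.get("nuC", 0.0),
    )
    return float(val[0])


def _edge_multipliers(
    variant: Variant,
    values: Dict[str, float],
    k2: np.ndarray,
    group: np.ndarray,
    rel_is_spouse: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-edge (constant-A term, beta_A, beta_C) under a variant."""
    zero = np.zeros_like(k2, dtype=float)
    const, betaA, betaC = zero.copy(), zero.copy(), zero.copy()
    if variant in (Variant.AE, Variant.COHAB_CE_PLUS_A):
        const = k2 * values["sigmaA2"]
    if variant in (Variant.COHAB_AE, Variant.COHAB_ACE):
        betaA = np.where(rel_is_spouse, 0.0, k2)
    if variant == Variant.COHAB_ACE:
        betaC = np.ones_like(zero)
    if variant in (Variant.COHAB_CE, Variant.COHAB_CE_PLUS_A):
        betaC = np.ones_like(zero)
        betaC = np.where(group == "MZ", values["betaC_MZ"], betaC)
        betaC = np.where(group == "PO", values["betaC_PO"], betaC)
    return const, betaA, betaC


def variance_edge_cov(
    variant: Variant,
    values: Dict[str, float],
    dataset: FamilyDataset,
) -> np.ndarray:
    const, betaA, betaC = _edge_multipliers(
        variant, values, dataset.edge_k2, dataset.edge_group,
        dataset.edge_rel == "SPOUSE",
    )
    return cov_kernel(
        dataset.edge_t, dataset.edge_t0, const, betaA,
        values.get("lamA", 0.0), values.get("nuA", 0.0),
        betaC, values.get("lamC", 0.0), values.get("nuC", 0.0),
    )


def reference_variance(values: Dict[str, float], studies: Sequence[str]) -> float:
    """Inverse-variance-weighted mean of the study residual variances."""
    v = np.array([values[f"var_{s}"] for s in studies])
    w = 1.0 / v
    return float(np.sum(w * v) / np.sum(w))


def fit_variance_model(
    spec: VarianceModelSpec,
    dataset: FamilyDataset,
    seed: int = 0,
    n_starts: int = 5,
    compute_se: bool = True,
) -> FitResult:
    """ML fit of one variance-components variant on pooled family data."""
    needed = {
        Variant.COHAB_CE: ["MZ"],
        Variant.COHAB_CE_PLUS_A: ["MZ"],
    }.get(spec.variant, [])
    for g in needed:
        if g not in dataset.groups_present:
            raise ValueError(
                f"{spec.variant.value} requires {g} pairs; dataset has "
                f"{dataset.groups_present}"
            )
    def objective(values: Dict[str, float]) -> float:
        cov = variance_edge_cov(spec.variant, values, dataset)
        sv = np.array([values[f"var_{s}"] for s in dataset.studies])
        return dataset.packed.loglik(dataset.full_edge_cov(cov), sv)

    # shrink kernel start values until the starting point is feasible
    # (a small study's empirical variance can sit below the initial kernel
    # covariance, which the likelihood rejects as non-PSD)
    shrink = 1.0
    for _ in range(10):
        pspec = spec.build_params(dataset, shrink=shrink)
        if math.isfinite(objective(pspec.unpack(pspec.pack()))):
            break
        shrink *= 0.4

    fit = maximize(
        objective, pspec, n_starts=n_starts, seed=seed, compute_se=compute_se,
        n_families=dataset.packed.n_families,
        n_individuals=dataset.packed.n_individuals,
    )
    ref = reference_variance(fit.estimates, dataset.studies)
    derived: Dict[str, float] = {"reference_variance": ref}
    est = fit.estimates
    if spec.variant in (Variant.AE, Variant.COHAB_CE_PLUS_A):
        derived["genetic_share"] = est["sigmaA2"] / ref
    if spec.variant in (Variant.COHAB_CE, Variant.COHAB_CE_PLUS_A):
        derived["mz_dzsib_ratio"] = est["betaC_MZ"]
        derived["dzsib_po_ratio"] = 1.0 / est["betaC_PO"]
    fit.extras["variant"] = spec.variant.value
    fit.extras["derived"] = derived
    fit.extras["data_fingerprint"] = dataset.fingerprint
    return fit


def compare_variants(
    fits: Sequence[FitResult],
    nestings: Optional[Sequence[Tuple[str, str, int]]] = None,
) -> pd.DataFrame:
    """Rank variant fits by AIC (ties broken by fewer parameters).

    ``nestings`` lists (null_variant, alt_variant, df) pairs for which a
    likelihood-ratio p-value is added.  All fits must be on identical data.
    """
    prints = {f.extras.get("data_fingerprint") for f in fits}
    if len(prints) > 1:
        raise ValueError(f"fits are not on identical data: fingerprints {prints}")
    rows = []
    best_aic = min(f.aic for f in fits)
    by_variant = {f.extras.get("variant", f"fit{i}"): f for i, f in enumerate(fits)}
    lrt_p: Dict[str, float] = {}
    if nestings:
        for null_v, alt_v, df in nestings:
            if null_v in by_variant and alt_v in by_variant:
                _, p = lrt(by_variant[null_v], by_variant[alt_v], df=df)
                lrt_p[alt_v] = p
    for name, f in by_variant.items():
        rows.append({
            "variant": name,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "aic": f.aic,
            "delta_aic": f.aic - best_aic,
            "lrt_p_vs_null": lrt_p.get(name, math.nan),
            "converged": f.converged,
        })
    out = pd.DataFrame(rows).sort_values(
        ["aic", "n_params"], kind="stable"
    ).reset_index(drop=True)
    return out


def variance_proportion_curves(
    fit: FitResult,
    spec: VarianceModelSpec,
    ages: Sequence[float],
    groups: Sequence[str] = ("MZ", "DZSIB", "PO", "SPOUSE"),
    t0: float = 18.0,
    ref_var: Optional[float] = None,
) -> pd.DataFrame:
    """Per-age shares of variance attributed to A, C, and E by pair group.

    The A and C shares at age t are that group's kernel contributions
    divided by the reference variance; E is the remainder.  Shares outside
    [0, 1] are clamped and flagged.
    """
    values = fit.estimates
    studies = [k[len("var_"):] for k in values if k.startswith("var_")]
    if ref_var is None:
        ref_var = reference_variance(values, studies)
    if ref_var <= 0:
        raise ValueError("reference variance must be positive")
    ages = np.asarray(ages, float)
    rows = []
    for g in groups:
        k2 = {"MZ": 1.0, "DZSIB": 0.5, "PO": 0.5, "SPOUSE": 0.0}[g]
        const, betaA, betaC = _edge_multipliers(
            spec.variant, values,
            k2=np.full(ages.size, k2),
            group=np.full(ages.size, g, dtype=object),
            rel_is_spouse=np.full(ages.size, g == "SPOUSE"),
        )
        g_t0 = np.inf if g == "SPOUSE" else t0
        a_part = cov_kernel(
            ages, g_t0, const, betaA,
            values.get("lamA", 0.0), values.get("nuA", 0.0),
            np.zeros_like(ages), 0.0, 0.0,
        )
        c_part = cov_kernel(
            ages, g_t0, np.zeros_like(ages), np.zeros_like(ages), 0.0, 0.0,
            betaC, values.get("lamC", 0.0), values.get("nuC", 0.0),
        )
        a_share = a_part / ref_var
        c_share = c_part / ref_var
        e_share = 1.0 - a_share - c_share
        clamped = (
            (a_share < 0) | (a_share > 1) | (c_share < 0) | (c_share > 1)
            | (e_share < 0) | (e_share > 1)
        )
        for i, t in enumerate(ages):
            rows.append({
                "group": g, "age": float(t),
                "A": float(np.clip(a_share[i], 0, 1)),
                "C": float(np.clip(c_share[i], 0, 1)),
                "E": float(np.clip(e_share[i], 0, 1)),
                "clamped": bool(clamped[i]),
            })
    return pd.DataFrame(rows)
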