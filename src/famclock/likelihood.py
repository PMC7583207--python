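"""Multivariate-normal pedigree likelihood, constrained ML, AIC and LRT.

Families are modelled as draws from a zero-mean multivariate normal whose
diagonal holds study-specific residual variances and whose off-diagonals come
from a pairwise covariance rule (a correlation kernel times the member
standard deviations, or a variance-components kernel).  This module provides

* :func:`family_loglik` — the per-family MVN log density (reference path);
* :class:`PackedFamilies` — a pre-indexed container that evaluates the total
  log-likelihood of many families fast (closed forms for 1- and 2-member
  families, batched Cholesky for larger blocks);
* :func:`maximize` — multi-start bound-constrained ML with smooth transforms
  (log for rates/variances, scaled logistic for interval parameters), Wald
  standard errors from the observed information on the transformed scale;
* :func:`lrt` — the likelihood-ratio test for nested fits.

A proposed parameter point whose family covariance matrix is not positive
definite scores ``-inf``; the optimizer simply moves away from it.  This is
deliberate: pairwise-specified covariances do not guarantee positive
definiteness for families of three or more.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# parameters and transforms
# ---------------------------------------------------------------------------

@dataclass
class Parameter:
    """One model parameter with its constraint-handling transform.

    transform:
        "identity"  — unconstrained;
        "log"       — positive (rates, variances): x = exp(u);
        "interval"  — x in (lo, hi) via scaled logistic.
    """

    name: str
    value: float
    free: bool = True
    transform: str = "identity"
    lo: float = 0.0
    hi: float = 1.0

    def to_unconstrained(self, x: float) -> float:
        if self.transform == "identity":
            return x
        if self.transform == "log":
            return math.log(max(x, 1e-12))
        if self.transform == "interval":
            p = (x - self.lo) / (self.hi - self.lo)
            p = min(max(p, 1e-10), 1.0 - 1e-10)
            return special.logit(p)
        raise ValueError(f"unknown transform {self.transform}")

    def to_natural(self, u: float) -> float:
        if self.transform == "identity":
            return u
        if self.transform == "log":
            # clamp: overflowing proposals are rejected by the objective anyway
            return math.exp(min(u, 700.0))
        if self.transform == "interval":
            return self.lo + (self.hi - self.lo) * special.expit(u)
        raise ValueError(f"unknown transform {self.transform}")

    def dnatural_du(self, u: float) -> float:
        """Jacobian dx/du for the delta method."""
        if self.transform == "identity":
            return 1.0
        if self.transform == "log":
            return math.exp(min(u, 700.0))
        if self.transform == "interval":
            p = special.expit(u)
            return (self.hi - self.lo) * p * (1.0 - p)
        raise ValueError(f"unknown transform {self.transform}")


class ParameterSpec:
    """Ordered collection of parameters; packs free ones into a vector."""

    def __init__(self, params: Sequence[Parameter]):
        self.params = list(params)
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self.free = [p for p in self.params if p.free]

    @property
    def n_free(self) -> int:
        return len(self.free)

    def pack(self) -> np.ndarray:
        return np.array([p.to_unconstrained(p.value) for p in self.free])

    def unpack(self, u: np.ndarray) -> Dict[str, float]:
        values = {p.name: p.value for p in self.params}
        for p, ui in zip(self.free, u):
            values[p.name] = p.to_natural(ui)
        return values


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    loglik: float
    n_params: int
    estimates: Dict[str, float]
    standard_errors: Dict[str, float]
    cis: Dict[str, Tuple[float, float]]
    converged: bool
    n_families: int = 0
    n_individuals: int = 0
    diagnostics: Dict[str, object] = field(default_factory=dict)
    extras: Dict[str, object] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def to_json(self) -> str:
        payload = {
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "cis": {k: list(v) for k, v in self.cis.items()},
            "converged": self.converged,
            "n_families": self.n_families,
            "n_individuals": self.n_individuals,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if _jsonable(v)
            },
        }
        return json.dumps(payload, indent=2, default=float)


def _jsonable(v) -> bool:
    try:
        json.dumps(v, default=float)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# family likelihood
# ---------------------------------------------------------------------------

@dataclass
class FamilyBlock:
    """One family's phenotype vector plus per-member metadata."""

    family_id: str
    y: np.ndarray  # analysis residuals, mean-zero by construction
    study_ids: Sequence[str]
    members: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.size < 1:
            raise ValueError(f"family {self.family_id}: needs >= 1 member")
        if not np.all(np.isfinite(self.y)):
            raise ValueError(f"family {self.family_id}: non-finite phenotype")


def family_loglik(
    block: FamilyBlock,
    covariance_fn: Callable[[int, int], float],
    study_vars: Dict[str, float],
) -> float:
    """MVN log density of one family; ``-inf`` if the covariance is not PD.

    ``covariance_fn(i, j)`` returns the modelled covariance between members
    ``i`` and ``j`` (local indices); the diagonal comes from ``study_vars``.
    """
    m = block.y.size
    sigma = np.empty((m, m))
    for i in range(m):
        sigma[i, i] = study_vars[block.study_ids[i]]
        for j in range(i + 1, m):
            sigma[i, j] = sigma[j, i] = covariance_fn(i, j)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -math.inf
    try:
        sol = np.linalg.solve(sigma, block.y)
    except np.linalg.LinAlgError:
        return -math.inf
    # slogdet can succeed for indefinite matrices with positive determinant;
    # check PD via Cholesky.
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return -math.inf
    quad = float(block.y @ sol)
    return -0.5 * (m * LOG2PI + logdet + quad)


class PackedFamilies:
    """Pre-indexed family data for fast repeated likelihood evaluation.

    Construction takes, per family, the member phenotypes, a per-member study
    index, and the list of within-family edges as (local_i, local_j,
    global_edge_row) triples.  ``loglik`` then accepts a vector of modelled
    covariances for *all* global edges plus per-study variances and returns
    the total log-likelihood.
    """

    def __init__(
        self,
        families: Sequence[Tuple[np.ndarray, np.ndarray, Sequence[Tuple[int, int, int]]]],
        n_studies: int,
        n_edges: int,
    ):
        self.n_studies = n_studies
        self.n_edges = n_edges
        self.n_families = len(families)
        self.n_individuals = sum(len(y) for y, _, _ in families)
        by_size: Dict[int, list] = {}
        for fam in families:
            by_size.setdefault(len(fam[0]), []).append(fam)
        self._classes = []
        for m, fams in sorted(by_size.items()):
            y = np.stack([f[0] for f in fams])                      # (k, m)
            sidx = np.stack([f[1] for f in fams]).astype(np.intp)   # (k, m)
            edges = [f[2] for f in fams]
            n_e = m * (m - 1) // 2
            ei = np.empty((len(fams), n_e), dtype=np.intp)
            ej = np.empty_like(ei)
            erow = np.empty_like(ei)
            for k, fam_edges in enumerate(edges):
                if len(fam_edges) != n_e:
                    raise ValueError("every within-family pair needs an edge entry")
                for c, (i, j, row) in enumerate(fam_edges):
                    ei[k, c], ej[k, c], erow[k, c] = i, j, row
            self._classes.append((m, y, sidx, ei, ej, erow))

    def loglik(self, edge_cov: np.ndarray, study_var: np.ndarray) -> float:
        """Total MVN log-likelihood; ``-inf`` on any invalid covariance."""
        if np.any(study_var <= 0) or not np.all(np.isfinite(edge_cov)):
            return -math.inf
        total = 0.0
        for m, y, sidx, ei, ej, erow in self._classes:
            v = study_var[sidx]  # (k, m)
            if m == 1:
                total += float(
                    -0.5 * np.sum(LOG2PI + np.log(v[:, 0]) + y[:, 0] ** 2 / v[:, 0])
                )
                continue
            if m == 2:
                c = edge_cov[erow[:, 0]]
                v1, v2 = v[:, 0], v[:, 1]
                det = v1 * v2 - c * c
                if np.any(det <= 0):
                    return -math.inf
                y1, y2 = y[:, 0], y[:, 1]
                quad = (v2 * y1 * y1 - 2.0 * c * y1 * y2 + v1 * y2 * y2) / det
                total += float(np.sum(-LOG2PI - 0.5 * np.log(det) - 0.5 * quad))
                continue
            k = y.shape[0]
            sigma = np.zeros((k, m, m))
            rows = np.arange(k)[:, None]
            sigma[rows, np.arange(m)[None, :], np.arange(m)[None, :]] = v
            cvals = edge_cov[erow]
            sigma[rows, ei, ej] = cvals
            sigma[rows, ej, ei] = cvals
            try:
                chol = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return -math.inf
            logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
            sol = np.linalg.solve(sigma, y[:, :, None])[:, :, 0]
            quad = np.einsum("km,km->k", y, sol)
            total += float(np.sum(-0.5 * (m * LOG2PI + logdet + quad)))
        if not np.isfinite(total):
            return -math.inf
        return total


# ---------------------------------------------------------------------------
# maximization
# ---------------------------------------------------------------------------

_PENALTY = 1e10


def maximize(
    objective: Callable[[Dict[str, float]], float],
    spec: ParameterSpec,
    n_starts: int = 5,
    seed: int = 0,
    jitter: float = 0.5,
    compute_se: bool = True,
    maxiter: int = 500,
    n_families: int = 0,
    n_individuals: int = 0,
) -> FitResult:
    """Maximize a log-likelihood over the constrained parameters of ``spec``.

    Optimization runs on the unconstrained (transformed) scale with L-BFGS-B
    from ``n_starts`` jittered starting points.  Standard errors come from
    the numerically differentiated observed information on the transformed
    scale, mapped back by the delta method; confidence intervals are Wald on
    the transformed scale, mapped back (so they respect the bounds).
    """
    rng = np.random.default_rng(seed)
    u0 = spec.pack()

    def neg(u: np.ndarray) -> float:
        val = objective(spec.unpack(u))
        if not np.isfinite(val):
            return _PENALTY
        return -val

    best = None
    start_log = []
    for s in range(n_starts):
        u_start = u0 if s == 0 else u0 + rng.normal(scale=jitter, size=u0.size)
        if u0.size == 0:
            ll = -neg(u0)
            best = (ll, u0, True, 0.0)
            start_log.append({"start": s, "loglik": ll, "nit": 0})
            break
        res = optimize.minimize(
            neg, u_start, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        ll = -res.fun if np.isfinite(res.fun) else -math.inf
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else math.nan
        start_log.append({"start": s, "loglik": ll, "nit": int(res.nit)})
        if ll > -_PENALTY / 2 and (best is None or ll > best[0]):
            best = (ll, res.x.copy(), bool(res.success), gnorm)

    if best is None:
        return FitResult(
            loglik=-math.inf, n_params=spec.n_free,
            estimates=spec.unpack(u0), standard_errors={}, cis={},
            converged=False, n_families=n_families, n_individuals=n_individuals,
            diagnostics={"starts": start_log, "reason": "all starts diverged"},
        )

    ll, u_hat, ok, gnorm = best
    estimates = spec.unpack(u_hat)
    ses: Dict[str, float] = {}
    cis: Dict[str, Tuple[float, float]] = {}
    if compute_se and spec.n_free > 0:
        se_u = _observed_info_se(neg, u_hat)
        z = stats.norm.ppf(0.975)
        for p, uh, su in zip(spec.free, u_hat, se_u):
            if np.isfinite(su):
                ses[p.name] = abs(p.dnatural_du(uh)) * su
                cis[p.name] = (p.to_natural(uh - z * su), p.to_natural(uh + z * su))
            else:
                ses[p.name] = math.nan
                cis[p.name] = (math.nan, math.nan)

    return FitResult(
        loglik=ll, n_params=spec.n_free, estimates=estimates,
        standard_errors=ses, cis=cis, converged=ok,
        n_families=n_families, n_individuals=n_individuals,
        diagnostics={"starts": start_log, "grad_norm": gnorm, "seed": seed},
    )


def _observed_info_se(neg: Callable[[np.ndarray], float], u: np.ndarray) -> np.ndarray:
    """SEs on the transformed scale from a central-difference Hessian."""
    p = u.size
    h = 1e-4 * np.maximum(1.0, np.abs(u))
    hess = np.empty((p, p))
    f0 = neg(u)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                hess[i, i] = (neg(u + ei) - 2.0 * f0 + neg(u - ei)) / h[i] ** 2
            else:
                val = (
                    neg(u + ei + ej) - neg(u + ei - ej)
                    - neg(u - ei + ej) + neg(u - ei - ej)
                ) / (4.0 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
    try:
        cov = np.linalg.pinv(hess)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def lrt(fit_null: FitResult, fit_alt: FitResult, df: int, tol: float = 1e-6):
    """Likelihood-ratio test of a null fit nested in an alternative fit.

    Returns ``(statistic, p_value)`` with the statistic clamped at zero and
    the p-value from the upper tail of chi-square with ``df`` degrees of
    freedom.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < -tol * max(1.0, abs(fit_alt.loglik)):
        raise ValueError(
            f"alternative loglik {fit_alt.loglik:.6f} below null "
            f"{fit_null.loglik:.6f}: fits not nested or not converged"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))
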