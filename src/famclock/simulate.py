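"""Synthetic family cohorts with the covariance structure the models assume.

The generator inverts the analysis models: it assembles each family's
covariance matrix from a chosen generating model (a cohabitation-dependent
correlation kernel or a variance-components kernel), draws the members'
phenotypes jointly from a zero-mean multivariate normal, and emits a DNAm-age
column as ``intercept + slope*age + sex_effect + residual`` so the
residualization stage reproduces the drawn residuals.  It emits exactly the
phenotype/pairs table dialects the pipeline consumes, plus a truth manifest
recording every generating parameter.

``multi_study_cohort`` builds a ready-made configuration mirroring a pooled
multi-study twin/family design: ~4200 people from newborn twin cohorts,
adolescent twin/sibling/parent households, an 18-year-old twin cohort, adult
and elderly twin cohorts, sister sibships, and spouse pairs, with
study-specific residual variances on a standardized scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data import DEFAULT_GROUPS, KINSHIP2, pair_clocks
from .correlation import rho as rho_kernel
from .varcomp import Variant, variance_edge_cov

# age distributions: ("fixed", v) | ("uniform", lo, hi) | ("normal", mu, sd[, lo, hi])
AgeDist = Tuple


def draw_ages(dist: AgeDist, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if kind == "normal":
        lo = dist[3] if len(dist) > 3 else 0.0
        hi = dist[4] if len(dist) > 4 else np.inf
        return np.clip(rng.normal(dist[1], dist[2], size=n), lo, hi)
    raise ValueError(f"unknown age distribution {dist!r}")


@dataclass
class PairBlock:
    """A block of independent two-member families of one relationship type."""

    study_id: str
    relationship: str  # MZ | DZ | SIB | PO | SPOUSE
    n_pairs: int
    age: AgeDist  # twins: both ages; SIB: younger; PO: offspring; SPOUSE: mean age
    sib_gap: AgeDist = ("normal", 2.5, 1.5, 0.5, 18.0)
    parent_offset: AgeDist = ("normal", 28.0, 4.0, 16.0, 50.0)
    separation_time: Optional[float] = None  # spouses: years married at separation


@dataclass
class NuclearFamilyBlock:
    """Two parents, a twin pair, and optional extra siblings per family."""

    study_id: str
    n_families: int
    zygosity: str  # "MZ" | "DZ"
    twin_age: AgeDist
    n_extra_sibs: int = 0
    sib_gap: AgeDist = ("normal", 2.5, 1.5, 0.5, 18.0)
    parent_offset: AgeDist = ("normal", 30.0, 4.0, 18.0, 50.0)


@dataclass
class SibshipBlock:
    """Families of ``n_sibs`` siblings (no parents), e.g. sister sibships."""

    study_id: str
    n_families: int
    n_sibs: int
    age: AgeDist  # youngest sibling's age
    sib_gap: AgeDist = ("normal", 2.5, 1.5, 0.5, 18.0)


Block = Union[PairBlock, NuclearFamilyBlock, SibshipBlock]


@dataclass
class CorrelationGenParams:
    """Generating parameters of the lifespan correlation kernel, per group."""

    theta: Dict[str, float]
    lam: Dict[str, float]
    nu: Dict[str, float]


@dataclass
class VarianceGenParams:
    """Generating parameters of a variance-components variant."""

    variant: Variant
    values: Dict[str, float]


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    studies: Dict[str, float]  # study_id -> residual variance
    blocks: List[Block]
    model: Union[CorrelationGenParams, VarianceGenParams]
    seed: int
    dnam_slope: float = 1.0
    dnam_intercept: float = 0.0
    sex_effect: float = 0.0
    adult_age: float = 18.0
    marriage_age: float = 24.0

    def __post_init__(self) -> None:
        for s, v in self.studies.items():
            if v <= 0:
                raise ValueError(f"study {s}: variance must be > 0")
        for b in self.blocks:
            n = b.n_pairs if isinstance(b, PairBlock) else b.n_families
            if n < 0:
                raise ValueError("block counts must be >= 0")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _members_and_edges(config: CohortConfig, rng: np.random.Generator):
    """Materialize all individuals and pair edges (ages drawn, no phenotypes)."""
    members: List[dict] = []
    edges: List[dict] = []
    fam_counter = 0

    def new_family(study):
        nonlocal fam_counter
        fam_counter += 1
        return f"F{fam_counter:06d}"

    def push(study, fam, idx, sex, age, role):
        iid = f"{fam}.{idx}"
        members.append({
            "study_id": study, "family_id": fam, "individual_id": iid,
            "sex": sex, "age": float(age), "role": role,
        })
        return iid

    def sexes_for_twins(zyg, n, rng):
        if zyg == "MZ":
            s = rng.choice(["female", "male"], size=n)
            return s, s.copy()
        return (
            rng.choice(["female", "male"], size=n),
            rng.choice(["female", "male"], size=n),
        )

    for block in config.blocks:
        if isinstance(block, PairBlock):
            n = block.n_pairs
            if n == 0:
                continue
            rel = block.relationship
            base = draw_ages(block.age, n, rng)
            if rel in ("MZ", "DZ"):
                age_a, age_b = base, base
                sex_a, sex_b = sexes_for_twins(rel, n, rng)
            elif rel == "SIB":
                gap = draw_ages(block.sib_gap, n, rng)
                age_a, age_b = base, base + gap
                sex_a = rng.choice(["female", "male"], size=n)
                sex_b = rng.choice(["female", "male"], size=n)
            elif rel == "PO":
                off = draw_ages(block.parent_offset, n, rng)
                age_a, age_b = base, base + off  # a = offspring
                sex_a = rng.choice(["female", "male"], size=n)
                sex_b = rng.choice(["female", "male"], size=n)
            elif rel == "SPOUSE":
                age_a, age_b = base, base
                sex_a = np.full(n, "female")
                sex_b = np.full(n, "male")
            else:
                raise ValueError(f"unknown relationship {rel}")
            for k in range(n):
                fam = new_family(block.study_id)
                ida = push(block.study_id, fam, 0, sex_a[k], age_a[k],
                           "offspring" if rel == "PO" else None)
                idb = push(block.study_id, fam, 1, sex_b[k], age_b[k],
                           "parent" if rel == "PO" else None)
                edges.append({
                    "family_id": fam, "id_a": ida, "id_b": idb,
                    "relationship": rel,
                    "offspring_member": "a" if rel == "PO" else None,
                    "separation_time": block.separation_time if rel == "SPOUSE" else None,
                })
        elif isinstance(block, NuclearFamilyBlock):
            n = block.n_families
            if n == 0:
                continue
            t_age = draw_ages(block.twin_age, n, rng)
            tw_sex_a, tw_sex_b = sexes_for_twins(block.zygosity, n, rng)
            for k in range(n):
                fam = new_family(block.study_id)
                twin1 = push(block.study_id, fam, 0, tw_sex_a[k], t_age[k], "twin")
                twin2 = push(block.study_id, fam, 1, tw_sex_b[k], t_age[k], "twin")
                kids = [(twin1, t_age[k]), (twin2, t_age[k])]
                for s in range(block.n_extra_sibs):
                    gap = draw_ages(block.sib_gap, 1, rng)[0]
                    age_s = max(0.0, t_age[k] + gap)
                    sib = push(block.study_id, fam, 2 + s,
                               rng.choice(["female", "male"]), age_s, "sibling")
                    kids.append((sib, age_s))
                off_m = draw_ages(block.parent_offset, 1, rng)[0]
                off_f = draw_ages(block.parent_offset, 1, rng)[0]
                mother = push(block.study_id, fam, 2 + block.n_extra_sibs, "female",
                              t_age[k] + off_m, "parent")
                father = push(block.study_id, fam, 3 + block.n_extra_sibs, "male",
                              t_age[k] + off_f, "parent")
                edges.append({"family_id": fam, "id_a": twin1, "id_b": twin2,
                              "relationship": block.zygosity,
                              "offspring_member": None, "separation_time": None})
                for a_i in range(len(kids)):
                    for b_i in range(a_i + 1, len(kids)):
                        if a_i == 0 and b_i == 1:
                            continue  # the twin edge
                        edges.append({"family_id": fam, "id_a": kids[a_i][0],
                                      "id_b": kids[b_i][0], "relationship": "SIB",
                                      "offspring_member": None, "separation_time": None})
                for kid, _ in kids:
                    for par in (mother, father):
                        edges.append({"family_id": fam, "id_a": kid, "id_b": par,
                                      "relationship": "PO", "offspring_member": "a",
                                      "separation_time": None})
                edges.append({"family_id": fam, "id_a": mother, "id_b": father,
                              "relationship": "SPOUSE",
                              "offspring_member": None, "separation_time": None})
        elif isinstance(block, SibshipBlock):
            n = block.n_families
            if n == 0:
                continue
            base = draw_ages(block.age, n, rng)
            for k in range(n):
                fam = new_family(block.study_id)
                ages = [base[k]]
                for s in range(1, block.n_sibs):
                    ages.append(ages[-1] + draw_ages(block.sib_gap, 1, rng)[0])
                ids = [
                    push(block.study_id, fam, i, rng.choice(["female", "male"]),
                         a, "sibling")
                    for i, a in enumerate(ages)
                ]
                for i in range(len(ids)):
                    for j in range(i + 1, len(ids)):
                        edges.append({"family_id": fam, "id_a": ids[i],
                                      "id_b": ids[j], "relationship": "SIB",
                                      "offspring_member": None,
                                      "separation_time": None})
        else:
            raise ValueError(f"unknown block type {type(block)}")
    return members, edges


def _model_edge_cov(
    config: CohortConfig,
    edges: pd.DataFrame,
    study_of: Dict[str, str],
) -> np.ndarray:
    """Generating covariance for each listed edge."""
    model = config.model
    t = edges["t"].to_numpy()
    t0 = edges["t0"].to_numpy()
    group = edges["relationship"].map(DEFAULT_GROUPS).to_numpy()
    sd_a = np.sqrt(edges["id_a"].map(study_of).map(config.studies).to_numpy(dtype=float))
    sd_b = np.sqrt(edges["id_b"].map(study_of).map(config.studies).to_numpy(dtype=float))
    if isinstance(model, CorrelationGenParams):
        r = np.empty(len(edges))
        for g in np.unique(group):
            m = group == g
            r[m] = rho_kernel(t[m], t0[m], model.theta[g], model.lam[g], model.nu[g])
        return r * sd_a * sd_b

    class _EdgeView:
        """Minimal dataset view for variance_edge_cov."""
        pass

    view = _EdgeView()
    view.edge_t = t
    view.edge_t0 = t0
    view.edge_k2 = edges["relationship"].map(KINSHIP2).to_numpy(dtype=float)
    view.edge_group = group
    view.edge_rel = edges["relationship"].to_numpy()
    return variance_edge_cov(model.variant, model.values, view)


def generate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict]:
    """Draw one cohort; returns (phenotype table, pairs table, truth manifest).

    Phenotypes are drawn jointly per family from the multivariate normal
    implied by the generating model; a non-positive-definite family
    covariance aborts with a message naming the offending block parameters.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    members, edges = _members_and_edges(config, rng)
    pheno = pd.DataFrame(members)
    pairs = pd.DataFrame(
        edges,
        columns=["family_id", "id_a", "id_b", "relationship",
                 "offspring_member", "separation_time"],
    )
    truth: Dict = {
        "seed": config.seed if seed is None else seed,
        "studies": dict(config.studies),
        "model": _manifest_model(config.model),
        "dnam_slope": config.dnam_slope,
        "dnam_intercept": config.dnam_intercept,
        "sex_effect": config.sex_effect,
        "n_individuals": len(pheno),
        "n_pairs": len(pairs),
    }
    if len(pheno) == 0:
        pheno = pd.DataFrame(
            columns=["study_id", "family_id", "individual_id", "sex", "age",
                     "dnam_age", "role"]
        )
        return pheno, pairs, truth

    age_by_id = pheno.set_index("individual_id")["age"].to_dict()
    study_of = pheno.set_index("individual_id")["study_id"].to_dict()
    if len(pairs):
        pairs_ck = pair_clocks(pairs, age_by_id, config.adult_age, config.marriage_age)
        cov = _model_edge_cov(config, pairs_ck, study_of)
    else:
        cov = np.zeros(0)

    # assemble and sample per family, batched by family size
    resid = _sample_family_residuals(pheno, pairs, cov, config, rng)
    pheno = pheno.copy()
    pheno["phenotype"] = resid
    sex_term = np.where(pheno["sex"].to_numpy() == "male", config.sex_effect, 0.0)
    pheno["dnam_age"] = (
        config.dnam_intercept + config.dnam_slope * pheno["age"].to_numpy()
        + sex_term + resid
    )
    pheno = pheno[["study_id", "family_id", "individual_id", "sex", "age",
                   "dnam_age", "role", "phenotype"]]
    return pheno, pairs, truth


def _sample_family_residuals(
    pheno: pd.DataFrame,
    pairs: pd.DataFrame,
    edge_cov: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    idx_of = {iid: i for i, iid in enumerate(pheno["individual_id"])}
    var_of = pheno["study_id"].map(config.studies).to_numpy(dtype=float)
    resid = np.empty(len(pheno))

    fam_rows: Dict[str, List[int]] = {}
    for i, fid in enumerate(pheno["family_id"]):
        fam_rows.setdefault(fid, []).append(i)
    fam_edges: Dict[str, List[int]] = {fid: [] for fid in fam_rows}
    for e, fid in enumerate(pairs["family_id"]):
        fam_edges[fid].append(e)
    id_a = pairs["id_a"].to_numpy() if len(pairs) else np.array([])
    id_b = pairs["id_b"].to_numpy() if len(pairs) else np.array([])

    by_size: Dict[int, List[str]] = {}
    for fid, rows in fam_rows.items():
        by_size.setdefault(len(rows), []).append(fid)

    for m, fids in by_size.items():
        k = len(fids)
        sigma = np.zeros((k, m, m))
        rows_arr = np.empty((k, m), dtype=np.intp)
        for fi, fid in enumerate(fids):
            rows = fam_rows[fid]
            rows_arr[fi] = rows
            local = {pheno["individual_id"].iat[r]: j for j, r in enumerate(rows)}
            sigma[fi][np.arange(m), np.arange(m)] = var_of[rows]
            for e in fam_edges[fid]:
                i, j = local[id_a[e]], local[id_b[e]]
                sigma[fi, i, j] = sigma[fi, j, i] = edge_cov[e]
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            # identify an offending family for the error message
            for fi, fid in enumerate(fids):
                try:
                    np.linalg.cholesky(sigma[fi])
                except np.linalg.LinAlgError:
                    raise ValueError(
                        f"family {fid}: generating covariance not positive "
                        f"definite (model {_manifest_model(config.model)})"
                    ) from None
            raise
        z = rng.standard_normal((k, m))
        y = np.einsum("kmn,kn->km", chol, z)
        for fi in range(k):
            resid[rows_arr[fi]] = y[fi]
    return resid


def _manifest_model(model) -> Dict:
    if isinstance(model, CorrelationGenParams):
        return {"kind": "correlation", "theta": model.theta,
                "lam": model.lam, "nu": model.nu}
    return {"kind": "variance", "variant": model.variant.value,
            "values": dict(model.values)}


# ---------------------------------------------------------------------------
# ready-made cohorts
# ---------------------------------------------------------------------------

#: final-model point estimates used as generator defaults for the
#: correlation kernel (theta = 1 for all groups; group-specific build-up
#: rates; a single slow decay rate shared by all groups)
DEFAULT_CORRELATION_PARAMS = CorrelationGenParams(
    theta={"MZ": 1.0, "DZSIB": 1.0, "PO": 1.0, "SPOUSE": 1.0},
    lam={"MZ": 0.041, "DZSIB": 0.026, "PO": 0.011, "SPOUSE": 0.011},
    nu={"MZ": 0.005, "DZSIB": 0.005, "PO": 0.005, "SPOUSE": 0.005},
)

#: cohabitation-dependent CE generator defaults: equal-environment violation
#: multipliers 1.41 (MZ : DZ/sib) and 2.03 (DZ/sib : parent-offspring)
DEFAULT_CE_PARAMS = VarianceGenParams(
    variant=Variant.COHAB_CE,
    values={"betaC_MZ": 1.41, "betaC_PO": 1.0 / 2.03, "lamC": 0.03, "nuC": 0.005},
)

DEFAULT_AE_PARAMS = VarianceGenParams(
    variant=Variant.AE, values={"sigmaA2": 0.52},
)

DEFAULT_CE_PLUS_A_PARAMS = VarianceGenParams(
    variant=Variant.COHAB_CE_PLUS_A,
    values={"sigmaA2": 0.13, "betaC_MZ": 1.41, "betaC_PO": 1.0 / 2.03,
            "lamC": 0.03, "nuC": 0.005},
)


def lifespan_pairs_cohort(
    n_per_group: int,
    model: Union[CorrelationGenParams, VarianceGenParams],
    seed: int,
    relationships: Sequence[str] = ("MZ", "DZ", "SIB", "PO", "SPOUSE"),
    age_range: Tuple[float, float] = (0.0, 90.0),
    study_variance: float = 1.0,
) -> CohortConfig:
    """A single-study cohort of independent pairs spanning the lifespan.

    Twin/sibling/offspring ages are uniform on ``age_range``; spouse mean
    ages are uniform on [marriage age, upper limit] so their cohabitation
    time spans 0 to upper-24 years.
    """
    lo, hi = age_range
    blocks: List[Block] = []
    for rel in relationships:
        age: AgeDist = ("uniform", max(lo, 24.0), hi) if rel == "SPOUSE" else ("uniform", lo, hi)
        blocks.append(PairBlock(study_id="SIM", relationship=rel,
                                n_pairs=n_per_group, age=age))
    return CohortConfig(
        studies={"SIM": study_variance}, blocks=blocks, model=model, seed=seed,
    )


def multi_study_cohort(
    scale: float = 1.0,
    model: Optional[Union[CorrelationGenParams, VarianceGenParams]] = None,
    seed: int = 0,
) -> CohortConfig:
    """A pooled multi-study cohort mirroring a realistic family design.

    At ``scale`` 1 the cohort holds 4217 individuals across 15 study blocks:
    newborn and 18-month twin cohorts, an adolescent twin/family study with
    two-parent households, a large 18-year-old twin cohort, adult and
    elderly twin cohorts, middle-aged sister sibships, and spouse pairs.
    All generated ages lie in [0, 92].  Study residual variances sit near 1
    (standardized-residual scale).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    n = lambda x: int(math.ceil(scale * x))
    B: List[Block] = []

    def twins(study, n_mz, n_dz, age):
        if n_mz:
            B.append(PairBlock(study, "MZ", n(n_mz), age))
        if n_dz:
            B.append(PairBlock(study, "DZ", n(n_dz), age))

    twins("PETS_EPIC", 23, 22, ("fixed", 0.0))
    twins("PETS_27K", 22, 11, ("fixed", 0.0))
    twins("PETS_450K_birth", 9, 5, ("fixed", 0.0))
    twins("PETS_450K_18m", 6, 4, ("fixed", 1.5))
    # adolescent twin/family study: households plus extra twin and sib pairs
    B.append(NuclearFamilyBlock("BSGS", n(22), "MZ", ("normal", 13.5, 2.0, 8.0, 20.0),
                                n_extra_sibs=1, parent_offset=("normal", 33.0, 5.0, 20.0, 55.0)))
    B.append(NuclearFamilyBlock("BSGS", n(37), "DZ", ("normal", 13.5, 2.0, 8.0, 20.0),
                                n_extra_sibs=1, parent_offset=("normal", 33.0, 5.0, 20.0, 55.0)))
    twins("BSGS", 45, 74, ("normal", 13.5, 2.0, 8.0, 20.0))
    B.append(PairBlock("BSGS", "SIB", n(40), ("normal", 14.0, 2.5, 8.0, 22.0)))
    twins("ERISK", 426, 306, ("fixed", 18.0))
    twins("DTR_YOUNG", 73, 0, ("normal", 33.1, 2.0, 25.0, 45.0))
    twins("AMDTSS", 66, 66, ("normal", 56.0, 8.0, 35.0, 80.0))
    B.append(SibshipBlock("AMDTSS", n(54), 4, ("normal", 53.0, 8.0, 35.0, 74.0),
                          sib_gap=("normal", 2.5, 1.5, 0.5, 6.0)))
    twins("TWINSUK", 33, 43, ("normal", 57.0, 8.0, 35.0, 80.0))
    twins("MUTHER", 93, 153, ("normal", 58.0, 9.0, 35.0, 85.0))
    twins("DTR_OLD", 77, 0, ("normal", 63.2, 4.0, 50.0, 80.0))
    twins("OATS", 108, 0, ("normal", 71.2, 6.0, 55.0, 90.0))
    twins("LSADT_1997", 18, 25, ("normal", 76.2, 2.0, 70.0, 85.0))
    twins("LSADT_2007", 18, 25, ("normal", 86.1, 2.0, 80.0, 92.0))
    B.append(PairBlock("MCCS", "SPOUSE", n(62), ("normal", 60.1, 6.0, 35.0, 85.0)))

    study_ids = sorted({b.study_id for b in B})
    # standardized-residual scale with mild between-study spread
    spread = np.linspace(0.8, 1.3, len(study_ids))
    studies = {s: float(v) for s, v in zip(study_ids, spread)}
    return CohortConfig(
        studies=studies, blocks=B,
        model=model if model is not None else DEFAULT_CE_PARAMS,
        seed=seed,
    )
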