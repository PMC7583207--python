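"""Table I/O and assembly of family-structured datasets for the likelihood.

Two plain-text tables drive everything:

* a phenotype table, one row per individual: ``study_id``, ``family_id``,
  ``individual_id``, ``sex``, ``age``, ``dnam_age`` (plus optional ``tissue``,
  cell-proportion columns, and derived residual columns);
* a pairs table listing within-family relative pairs: ``family_id``,
  ``id_a``, ``id_b``, ``relationship`` in {MZ, DZ, SIB, PO, SPOUSE},
  ``offspring_member`` ("a"/"b", PO pairs) and ``separation_time`` (spouses).

:class:`FamilyDataset` joins the two, evaluates each pair's cohabitation
clock, and packs families (members linked by any pair) into the structures
:class:`~famclock.likelihood.PackedFamilies` needs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import PackedFamilies

#: analysis grouping of pair types used by the pooled lifespan models
DEFAULT_GROUPS: Dict[str, str] = {
    "MZ": "MZ",
    "DZ": "DZSIB",
    "SIB": "DZSIB",
    "PO": "PO",
    "SPOUSE": "SPOUSE",
}

KINSHIP2: Dict[str, float] = {"MZ": 1.0, "DZ": 0.5, "SIB": 0.5, "PO": 0.5, "SPOUSE": 0.0}

PHENOTYPE_COLUMNS = ["study_id", "family_id", "individual_id", "sex", "age", "dnam_age"]
PAIR_COLUMNS = ["family_id", "id_a", "id_b", "relationship"]


def read_table(path) -> pd.DataFrame:
    """Read a CSV or TSV table (delimiter inferred from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def validate_phenotypes(df: pd.DataFrame) -> None:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    dup = df.duplicated(subset=["study_id", "individual_id"])
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise ValueError(f"duplicate (study_id, individual_id) at rows {rows}")
    if (df["age"] < 0).any():
        rows = df.index[df["age"] < 0].tolist()[:5]
        raise ValueError(f"negative chronological age at rows {rows}")


def validate_pairs(df: pd.DataFrame) -> None:
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pairs table missing columns: {missing}")
    bad = ~df["relationship"].isin(KINSHIP2)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(f"unknown relationship at rows {rows}")


def pair_clocks(
    pairs: pd.DataFrame,
    age_by_id: Dict[str, float],
    adult_age: float = 18.0,
    marriage_age: float = 24.0,
) -> pd.DataFrame:
    """Vectorized cohabitation clocks (t, t0) for a pairs table.

    Follows the same rules as
    :func:`famclock.pedigree.compute_cohabitation_clock`; the scalar version
    is the tested reference.
    """
    age_a = pairs["id_a"].map(age_by_id).to_numpy(dtype=float)
    age_b = pairs["id_b"].map(age_by_id).to_numpy(dtype=float)
    if np.any(~np.isfinite(age_a)) or np.any(~np.isfinite(age_b)):
        bad = pairs.index[~(np.isfinite(age_a) & np.isfinite(age_b))].tolist()[:5]
        raise ValueError(f"pairs reference individuals with missing ages at rows {bad}")
    rel = pairs["relationship"].to_numpy()
    t = np.empty(len(pairs))
    t0 = np.empty(len(pairs))

    twins = np.isin(rel, ["MZ", "DZ"])
    t[twins] = age_a[twins]
    t0[twins] = adult_age

    sib = rel == "SIB"
    younger = np.minimum(age_a, age_b)
    gap = np.abs(age_a - age_b)
    t[sib] = younger[sib]
    t0[sib] = np.maximum(0.0, adult_age - gap[sib])

    po = rel == "PO"
    if po.any():
        if "offspring_member" not in pairs.columns:
            raise ValueError("PO pairs present but no offspring_member column")
        off = pairs["offspring_member"].to_numpy()
        off_age = np.where(off == "a", age_a, age_b)
        t[po] = off_age[po]
        t0[po] = adult_age

    sp = rel == "SPOUSE"
    t[sp] = np.maximum(0.0, 0.5 * (age_a + age_b)[sp] - marriage_age)
    if "separation_time" in pairs.columns:
        sep = pairs["separation_time"].to_numpy(dtype=float)
    else:
        sep = np.full(len(pairs), np.nan)
    t0[sp] = np.where(np.isfinite(sep[sp]), sep[sp], np.inf)

    out = pairs.copy()
    out["t"] = t
    out["t0"] = t0
    out["kinship2"] = out["relationship"].map(KINSHIP2)
    return out


@dataclass
class FamilyDataset:
    """Families packed for likelihood evaluation plus per-edge metadata."""

    packed: PackedFamilies
    studies: List[str]                      # index -> study_id
    edge_t: np.ndarray
    edge_t0: np.ndarray
    edge_k2: np.ndarray
    edge_rel: np.ndarray                    # relationship string per edge
    edge_group: np.ndarray                  # analysis group string per edge
    edge_study_a: np.ndarray                # study index of each member
    edge_study_b: np.ndarray
    edge_y1: np.ndarray                     # member phenotypes, pair order as listed
    edge_y2: np.ndarray
    edge_study_label: np.ndarray            # study_id of member a (for reporting)
    edge_mean_age: np.ndarray
    study_var_init: np.ndarray              # empirical per-study variance (start values)
    fingerprint: str = ""

    @property
    def n_edges(self) -> int:
        return self.edge_t.size

    @property
    def groups_present(self) -> List[str]:
        return sorted(set(self.edge_group.tolist()))

    @classmethod
    def from_frames(
        cls,
        phenotypes: pd.DataFrame,
        pairs: pd.DataFrame,
        value_col: str = "phenotype",
        adult_age: float = 18.0,
        marriage_age: float = 24.0,
        groups: Optional[Dict[str, str]] = None,
        include_singletons: bool = False,
    ) -> "FamilyDataset":
        """Join phenotype and pairs tables into a packed dataset.

        Families are the connected units implied by ``family_id``; every
        within-family pair listed in the pairs table becomes a modelled
        covariance edge, and all other within-family member pairs are
        treated as uncorrelated (covariance 0).
        """
        validate_pairs(pairs)
        if value_col not in phenotypes.columns:
            raise ValueError(f"phenotype table has no column {value_col!r}")
        groups = dict(DEFAULT_GROUPS if groups is None else groups)

        pheno = phenotypes.reset_index(drop=True)
        ids = pheno["individual_id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError("individual_id must be unique across the dataset")
        id_index = pd.Series(np.arange(len(ids), dtype=np.intp), index=ids)
        age_all = pheno["age"].to_numpy(dtype=float)
        y_all = pheno[value_col].to_numpy(dtype=float)

        studies = sorted(pheno["study_id"].unique().tolist())
        study_idx = {s: i for i, s in enumerate(studies)}
        sidx_all = pheno["study_id"].map(study_idx).to_numpy(dtype=np.intp)

        ia_raw = pairs["id_a"].map(id_index)
        ib_raw = pairs["id_b"].map(id_index)
        if ia_raw.isna().any() or ib_raw.isna().any():
            bad = pairs.loc[ia_raw.isna() | ib_raw.isna(), ["id_a", "id_b"]]
            raise ValueError(f"pairs reference unknown individuals:\n{bad.head()}")
        ia = ia_raw.to_numpy(dtype=np.intp)
        ib = ib_raw.to_numpy(dtype=np.intp)
        age_by_id = dict(zip(ids, age_all))
        pairs = pair_clocks(pairs, age_by_id, adult_age, marriage_age)

        # group edges by family (stable order), then pack member blocks
        fam_codes, _ = pd.factorize(pairs["family_id"], sort=True)
        order = np.argsort(fam_codes, kind="stable")
        boundaries = np.flatnonzero(np.diff(fam_codes[order])) + 1
        fam_edge_rows = np.split(order, boundaries)

        families = []
        n_edges = len(pairs)
        filler_rows = 0
        paired = np.zeros(len(ids), dtype=bool)
        for rows in fam_edge_rows:
            local: Dict[int, int] = {}
            for r in rows:
                for g in (ia[r], ib[r]):
                    if g not in local:
                        local[g] = len(local)
            members = np.fromiter(local.keys(), dtype=np.intp, count=len(local))
            paired[members] = True
            m = len(members)
            listed = {}
            for r in rows:
                i, j = local[ia[r]], local[ib[r]]
                if i > j:
                    i, j = j, i
                listed[(i, j)] = r
            edges = []
            for i in range(m):
                for j in range(i + 1, m):
                    if (i, j) in listed:
                        edges.append((i, j, listed[(i, j)]))
                    else:
                        edges.append((i, j, n_edges + filler_rows))
                        filler_rows += 1
            families.append((y_all[members], sidx_all[members], edges))

        if include_singletons:
            for g in np.flatnonzero(~paired):
                families.append((y_all[g : g + 1], sidx_all[g : g + 1], []))

        packed = PackedFamilies(families, n_studies=len(studies), n_edges=n_edges + filler_rows)

        y1 = y_all[ia]
        y2 = y_all[ib]
        sa = sidx_all[ia]
        sb = sidx_all[ib]
        mean_age = 0.5 * (age_all[ia] + age_all[ib])
        var_init = np.array([
            max(float(np.var(y_all[sidx_all == i], ddof=1)), 1e-3)
            if np.sum(sidx_all == i) > 1 else 1.0
            for i in range(len(studies))
        ])
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(y1).tobytes())
        h.update(np.ascontiguousarray(y2).tobytes())
        h.update(str(len(pheno)).encode())

        return cls(
            packed=packed,
            studies=studies,
            edge_t=pairs["t"].to_numpy(),
            edge_t0=pairs["t0"].to_numpy(),
            edge_k2=pairs["kinship2"].to_numpy(dtype=float),
            edge_rel=pairs["relationship"].to_numpy(),
            edge_group=pairs["relationship"].map(groups).to_numpy(),
            edge_study_a=sa,
            edge_study_b=sb,
            edge_y1=y1,
            edge_y2=y2,
            edge_study_label=pheno["study_id"].to_numpy()[ia],
            edge_mean_age=mean_age,
            study_var_init=var_init,
            fingerprint=h.hexdigest()[:16],
        )

    def full_edge_cov(self, listed_cov: np.ndarray) -> np.ndarray:
        """Extend listed-edge covariances with zeros for filler edges."""
        out = np.zeros(self.packed.n_edges)
        out[: listed_cov.size] = listed_cov
        return out
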