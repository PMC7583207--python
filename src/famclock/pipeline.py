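"""End-to-end orchestration: residualization -> correlations -> model ladders.

``run_pipeline`` reproduces the full analysis sequence on a phenotype/pairs
table pair: epigenetic age acceleration, within-study familial correlations,
the pooled cohabitation-dependent correlation-model ladder, the five
variance-components variants with AIC comparison, and a run manifest.  All
outputs are TSV/JSON in the configured output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acceleration import adjust_covariates, compute_age_acceleration, descriptives, standardize_multitissue
from .correlation import fit_lifespan_correlation_model, predicted_rho_curve, within_study_table
from .data import FamilyDataset, read_table, validate_pairs, validate_phenotypes
from .likelihood import lrt
from .varcomp import Variant, VarianceModelSpec, compare_variants, fit_variance_model, variance_proportion_curves

log = logging.getLogger(__name__)

#: nested comparisons evaluated in the AIC table (null, alternative, df)
DEFAULT_NESTINGS = [("COHAB_CE", "COHAB_CE_PLUS_A", 1)]


@dataclass
class RunConfig:
    phenotypes: str
    pairs: str
    out_dir: str
    seed: int = 0
    strata: List[str] = field(default_factory=lambda: ["study_id"])
    covariates: List[str] = field(default_factory=lambda: ["sex"])
    adult_age: float = 18.0
    marriage_age: float = 24.0
    multitissue: bool = False
    variants: List[str] = field(default_factory=lambda: [v.value for v in Variant])
    n_starts: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def prepare_phenotype(pheno: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Acceleration residuals plus covariate adjustment -> ``phenotype``."""
    if config.multitissue and "tissue" in pheno.columns and pheno["tissue"].nunique() > 1:
        pheno = standardize_multitissue(pheno)
    pheno = compute_age_acceleration(pheno, strata=config.strata)
    pheno = adjust_covariates(pheno, covariates=config.covariates)
    return pheno


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute all stages; returns a report dict (also written to disk)."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"stages": {}}

    pheno = read_table(config.phenotypes)
    validate_phenotypes(pheno)
    pairs = read_table(config.pairs)
    if len(pairs):
        validate_pairs(pairs)

    pheno = prepare_phenotype(pheno, config)
    pheno.to_csv(out / "acceleration.tsv", sep="\t", index=False)
    report["stages"]["acceleration"] = {"n_individuals": len(pheno)}

    desc = descriptives(pheno)
    desc["by_study"].to_csv(out / "descriptives_by_study.tsv", sep="\t", index=False)
    desc["variance_by_age"].to_csv(out / "variance_by_age.tsv", sep="\t", index=False)
    report["stages"]["descriptives"] = {"n_studies": len(desc["by_study"])}

    if len(pairs) == 0:
        report["stages"]["models"] = {"skipped": "empty pairs table"}
        log.warning("pairs table empty: correlation and variance stages skipped")
        _write_manifest(report, config, out, t_start)
        return report

    dataset = FamilyDataset.from_frames(
        pheno, pairs, value_col="phenotype",
        adult_age=config.adult_age, marriage_age=config.marriage_age,
    )

    table2 = within_study_table(dataset, seed=config.seed)
    table2.to_csv(out / "within_study_correlations.tsv", sep="\t", index=False)
    report["stages"]["within_study"] = {"n_rows": len(table2)}

    # lifespan correlation ladder: theta free -> theta = 1 -> shared lambda
    ladder = {}
    fit_free = fit_lifespan_correlation_model(
        dataset, theta_mode="free", seed=config.seed, n_starts=config.n_starts)
    fit_theta1 = fit_lifespan_correlation_model(
        dataset, theta_mode="fixed1", seed=config.seed, n_starts=config.n_starts)
    _, p_theta = lrt(fit_theta1, fit_free, df=len(dataset.groups_present))
    fit_shared = fit_lifespan_correlation_model(
        dataset, theta_mode="fixed1", lambda_mode="shared",
        seed=config.seed, n_starts=config.n_starts)
    _, p_lambda = lrt(fit_shared, fit_theta1, df=len(dataset.groups_present) - 1)
    ladder["theta_free"] = json.loads(fit_free.to_json())
    ladder["theta_fixed1"] = json.loads(fit_theta1.to_json())
    ladder["lambda_shared"] = json.loads(fit_shared.to_json())
    ladder["p_theta_equals_1"] = p_theta
    ladder["p_lambda_heterogeneity"] = p_lambda
    (out / "lifespan_correlation.json").write_text(json.dumps(ladder, indent=2))
    ages = np.arange(0.0, 91.0, 1.0)
    curve_rows = []
    for g in dataset.groups_present:
        r = predicted_rho_curve(fit_theta1, g, ages)
        curve_rows.extend(
            {"group": g, "age": float(a), "rho": float(x)} for a, x in zip(ages, r)
        )
    pd.DataFrame(curve_rows).to_csv(out / "predicted_correlations.tsv", sep="\t", index=False)
    report["stages"]["lifespan_correlation"] = {
        "p_theta_equals_1": p_theta, "p_lambda_heterogeneity": p_lambda,
        "loglik": fit_theta1.loglik,
    }

    # variance-components ladder
    fits = []
    for name in config.variants:
        spec = VarianceModelSpec(Variant(name))
        try:
            fit = fit_variance_model(spec, dataset, seed=config.seed, n_starts=config.n_starts)
        except ValueError as exc:
            log.warning("variant %s skipped: %s", name, exc)
            continue
        (out / f"variance_fit_{name}.json").write_text(fit.to_json())
        fits.append((spec, fit))
    if fits:
        table = compare_variants([f for _, f in fits], nestings=DEFAULT_NESTINGS)
        table.to_csv(out / "variance_comparison.tsv", sep="\t", index=False)
        best_name = table.iloc[0]["variant"]
        best_spec, best_fit = next((s, f) for s, f in fits if f.extras["variant"] == best_name)
        curves = variance_proportion_curves(best_fit, best_spec, ages)
        curves.to_csv(out / "variance_proportions.tsv", sep="\t", index=False)
        report["stages"]["variance_models"] = {
            "best_by_aic": best_name,
            "aic": {f.extras["variant"]: f.aic for _, f in fits},
        }

    _write_manifest(report, config, out, t_start)
    return report


def _write_manifest(report, config: RunConfig, out: Path, t_start: float) -> None:
    manifest = {
        "famclock_version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {
            "phenotypes": _checksum(config.phenotypes),
            "pairs": _checksum(config.pairs),
        },
        "elapsed_s": round(time.time() - t_start, 2),
        "report": report,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
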