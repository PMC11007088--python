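"""End-to-end orchestration: simulate/load -> QC -> PRS -> wPRSsum ->
PCE -> exclusions -> strata -> survival evaluation -> report bundle.

The pipeline enforces the study's information ordering: combination
weights for the multi-score are fitted against *prevalent* cases on
the full genotyped cohort, genetic-group cutpoints are taken over that
same base set, and only then are prevalent (and incomplete) samples
excluded to form the incident-analysis set.  Every stage logs its
record counts; samples are never dropped silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (read_cohort_csv, read_dosage_tsv, read_weight_panel,
                 write_cohort_csv)
from .model import RiskStratificationModel
from .multiprs import assign_genetic_groups, combine_wprssum, fit_prs_weights, prs_association_scan
from .params import TRAITS
from .pce import (PceCalibration, assign_pce_groups, pce_linear_sum_cohort, pce_risk,
                  recalibrate)
from .prs import compute_prs, logo_prs, normalize_scores
from .qc import QCThresholds, run_qc
from .simulate import StudyData, generate_study

__all__ = ["AnalysisConfig", "apply_exclusions", "combine_strata", "run_all"]

PCE_COVARIATES = ("age", "tc", "hdl", "sbp", "bp_treated", "smoker", "diabetes", "sex")


@dataclass
class LogoConfig:
    enabled: bool = False
    traits: tuple[str, ...] = ("HTN",)
    k: int = 10
    p_threshold: float = 1.0


@dataclass
class AnalysisConfig:
    """Serializable description of one full run."""

    schema_version: int = 1
    simulate: bool = True
    preset: str = "table1"
    n_samples: int | None = None
    # input paths, used when simulate is False
    dosage_path: str | None = None
    variant_meta_path: str | None = None
    weights_dir: str | None = None
    cohort_path: str | None = None
    qc: dict = field(default_factory=dict)             # QCThresholds overrides
    logo: LogoConfig = field(default_factory=LogoConfig)
    normalization: str = "inverse_normal"
    genetic_cuts: tuple[float, float] = (0.20, 0.80)
    cutpoint_base: str = "pre_exclusion"               # or "post_exclusion"
    pce_calibration: dict | None = None                # optional fixed anchors
    pce_threshold: float = 0.075
    age_split: float = 55.0
    seed: int = 0
    out_dir: str = "cvdstrat_out"

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(**self.qc)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "logo" in raw and isinstance(raw["logo"], dict):
            raw["logo"] = LogoConfig(**raw["logo"])
        if "genetic_cuts" in raw:
            raw["genetic_cuts"] = tuple(raw["genetic_cuts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis-relevant fields (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove prevalent-disease samples and samples missing any clinical
    covariate of the risk equations; report counts per reason."""
    for c in ("prevalent_cvd", *PCE_COVARIATES):
        if c not in cohort.columns:
            raise ValueError(f"cohort lacks column {c!r}")
    prevalent = cohort["prevalent_cvd"].to_numpy() == 1
    missing = cohort[list(PCE_COVARIATES)].isna().any(axis=1).to_numpy()
    keep = ~(prevalent | missing)
    report = {
        "n_input": int(len(cohort)),
        "excluded_prevalent": int(prevalent.sum()),
        "excluded_missing_covariates": int((missing & ~prevalent).sum()),
        "n_analysis": int(keep.sum()),
    }
    out = cohort.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("exclusions removed every sample")
    return out, report


def combine_strata(genetic_group, pce_group) -> pd.Series:
    """Cross-classify the two groupings into the six analysis strata."""
    g = pd.Series(genetic_group).astype(str).reset_index(drop=True)
    p = pd.Series(pce_group).astype(str).reset_index(drop=True)
    if len(g) != len(p):
        raise ValueError("group labelings differ in length")
    return p + "/" + g


def _hypertension_phenotype(cohort: pd.DataFrame) -> np.ndarray:
    """Working hypertension definition for the LOGO GWAS stage:
    SBP >= 140 mmHg or on blood-pressure treatment."""
    return ((cohort["sbp"].to_numpy() >= 140) | (cohort["bp_treated"].to_numpy() == 1)).astype(int)


def run_all(config: AnalysisConfig, study: StudyData | None = None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results (score panel, tables,
    fitted results object, reports).  All randomness derives from
    ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name, **info):
        log.append({"stage": name, **info})

    # -- inputs -------------------------------------------------------------
    if study is None:
        if config.simulate:
            overrides = {}
            if config.n_samples:
                overrides["n_samples"] = config.n_samples
            study = generate_study(config.preset, seed=config.seed, **overrides)
        else:
            geno = read_dosage_tsv(config.dosage_path, config.variant_meta_path)
            weights = {t: read_weight_panel(Path(config.weights_dir) / f"weights_{t}.tsv", t)
                       for t in TRAITS}
            cohort = read_cohort_csv(config.cohort_path)
            study = StudyData(genotypes=geno, weights=weights, cohort=cohort, truth=None)
    geno, cohort = study.genotypes, study.cohort.reset_index(drop=True)
    stage("input", n_samples=geno.n_samples, n_variants=geno.n_variants)

    # -- QC -----------------------------------------------------------------
    geno_qc, qc_report = run_qc(geno, config.qc_thresholds())
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc_report, fh, indent=2)
    surviving = set(geno_qc.sample_ids)
    cohort = cohort[cohort["sample_id"].isin(surviving)].reset_index(drop=True)
    stage("qc", n_samples=geno_qc.n_samples, n_variants=geno_qc.n_variants)

    # -- per-trait PRS ------------------------------------------------------
    raw_scores = {}
    for trait in TRAITS:
        if config.logo.enabled and trait in config.logo.traits:
            pheno = _hypertension_phenotype(cohort)
            raw = logo_prs(geno_qc, pheno, k=config.logo.k,
                           p_threshold=config.logo.p_threshold, seed=config.seed)
            raw.trait = trait
        else:
            raw = compute_prs(geno_qc, study.weights[trait])
        raw_scores[trait] = raw
    prs_norm = pd.DataFrame({t: normalize_scores(raw_scores[t], config.normalization)
                             for t in TRAITS})
    stage("prs", traits=list(TRAITS),
          n_variants_used={t: raw_scores[t].n_variants_used for t in TRAITS})

    # -- multi-score combination (prevalent cases, pre-exclusion) ----------
    weight_fit = fit_prs_weights(prs_norm, cohort["prevalent_cvd"], cohort["age"], cohort["sex"])
    wprssum = combine_wprssum(prs_norm, weight_fit)
    scan = prs_association_scan(prs_norm, cohort["prevalent_cvd"], cohort["age"], cohort["sex"])
    scan.to_csv(out / "table2_prs_association.csv", index=False)
    stage("wprssum", n_cases=weight_fit.n_cases, n_total=weight_fit.n_total)

    # -- PCE ----------------------------------------------------------------
    pce_sum = pce_linear_sum_cohort(cohort)

    # -- exclusions ---------------------------------------------------------
    full = cohort.copy()
    full["wprssum"] = wprssum
    full["pce_sum_raw"] = pce_sum
    analysis, excl_report = apply_exclusions(full)
    with open(out / "exclusion_report.json", "w") as fh:
        json.dump(excl_report, fh, indent=2)
    stage("exclusions", **excl_report)

    # -- PCE recalibration & risk (incident-analysis set) ------------------
    if config.pce_calibration:
        cal = PceCalibration(**config.pce_calibration)
    else:
        cal = recalibrate(analysis["pce_sum_raw"], analysis["time_years"],
                          analysis["event"], analysis["sex"])
    risk = pce_risk(analysis["pce_sum_raw"], analysis["sex"], cal)
    analysis["pce_risk"] = risk
    analysis["pce_group"] = assign_pce_groups(risk, config.pce_threshold)
    # centered sum: cross-sex comparable log-relative-hazard scale
    mean_sum = np.where(analysis["sex"] > 0, cal.mean_sum_male, cal.mean_sum_female)
    analysis["pce_sum"] = analysis["pce_sum_raw"] - mean_sum

    # -- genetic groups ------------------------------------------------------
    base = full["wprssum"].to_numpy() if config.cutpoint_base == "pre_exclusion" \
        else analysis["wprssum"].to_numpy()
    ga = assign_genetic_groups(analysis["wprssum"], *config.genetic_cuts, base=base)
    analysis["genetic_group"] = ga.group
    stage("groups", cutpoints=list(ga.cutpoints),
          pce_high=int((analysis["pce_group"] == "high").sum()))

    # -- survival evaluation -------------------------------------------------
    res = RiskStratificationModel(analysis).fit()
    res.genetic_group_table.to_csv(out / "table3_genetic_groups.csv", index=False)
    res.pce_group_table.to_csv(out / "table4_pce_groups.csv", index=False)
    res.stratum_table.to_csv(out / "table5_strata.csv", index=False)
    res.cindex_table.to_csv(out / "table6_cindex.csv")
    res.km_genetic.to_csv(out / "km_genetic.csv", index=False)
    res.km_pce.to_csv(out / "km_pce.csv", index=False)
    res.km_strata.to_csv(out / "km_strata.csv", index=False)
    write_cohort_csv(analysis, out / "analysis_set.csv")
    stage("survival", n=len(analysis), events=int(analysis["event"].sum()))

    # -- provenance ----------------------------------------------------------
    config.to_yaml(out / "config_snapshot.yaml")
    with open(out / "run_log.json", "w") as fh:
        json.dump({"package_version": __version__, "seed": config.seed,
                   "config_digest": config.digest(), "stages": log}, fh, indent=2)

    return {"config": config, "study": study, "qc_report": qc_report,
            "scores": prs_norm, "weight_fit": weight_fit, "scan": scan,
            "calibration": cal, "analysis": analysis, "results": res,
            "exclusion_report": excl_report, "log": log}
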