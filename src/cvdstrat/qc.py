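"""Variant- and sample-level genotype quality control.

Filters mirror standard array-QC practice: variants are dropped for
low call rate (<95%), Hardy-Weinberg failure (p < 1e-6), low minor
allele frequency (<1%) or low imputation quality (<0.8); samples for
low call rate (<97%) or outlying heterozygosity (beyond 3 SD of the
cohort mean).  Comparisons are strict on the removal side, so a value
exactly at a threshold survives.  Filters run variants-then-samples,
one pass each.  Gender-discrepancy, relatedness and PCA-outlier checks
are out of scope here and flagged as not-performed in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .io import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "hwe_test", "filter_variants", "filter_samples", "run_qc"]


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate_min: float = 0.97
    variant_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    info_min: float = 0.8
    het_outlier_sd: float = 3.0

    def __post_init__(self):
        for name in ("sample_call_rate_min", "variant_call_rate_min", "maf_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min outside [0, 1]")
        if self.het_outlier_sd <= 0:
            raise ValueError("het_outlier_sd must be positive")


@dataclass
class QCReport:
    axis: str  # "variants" or "samples"
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_removed: int = 0
    n_surviving: int = 0
    surviving_ids: list[str] = field(default_factory=list)
    not_performed: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("surviving_ids")
        return d


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value.

    Expected genotype counts come from the empirical allele frequency;
    a monomorphic variant (allele frequency 0 or 1) returns p = 1.0
    since every genotype class is structurally determined.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p_hat ** 2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _require_columns(geno: GenotypeMatrix, cols) -> None:
    for c in cols:
        if c not in geno.variants.columns:
            raise ValueError(f"variant metadata lacks required column {c!r}")


def filter_variants(geno: GenotypeMatrix, th: QCThresholds = QCThresholds()
                    ) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants below the call-rate, HWE, MAF or imputation-quality
    thresholds; order of survivors is preserved."""
    _require_columns(geno, ["call_rate", "hwe_p", "maf", "info_quality"])
    v = geno.variants
    fail_call = v["call_rate"].to_numpy() < th.variant_call_rate_min
    fail_hwe = v["hwe_p"].to_numpy() < th.hwe_p_min
    fail_maf = v["maf"].to_numpy() < th.maf_min
    fail_info = v["info_quality"].to_numpy() < th.info_min
    keep = ~(fail_call | fail_hwe | fail_maf | fail_info)
    report = QCReport(
        axis="variants", n_input=geno.n_variants,
        removed={
            "low_call_rate": int(fail_call.sum()),
            "hwe_failure": int(fail_hwe.sum()),
            "low_maf": int(fail_maf.sum()),
            "low_info": int(fail_info.sum()),
        },
        n_removed=int((~keep).sum()), n_surviving=int(keep.sum()),
        surviving_ids=v.loc[keep, "variant_id"].tolist(),
    )
    return geno.take_variants(keep), report


def filter_samples(geno: GenotypeMatrix, th: QCThresholds = QCThresholds()
                   ) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with low call rate or outlying heterozygosity.

    Heterozygosity is the fraction of (rounded) dosages equal to 1
    among non-missing calls; outliers lie beyond ``het_outlier_sd``
    standard deviations of the cohort mean.
    """
    if geno.n_samples < 2:
        raise ValueError("need >= 2 samples for the heterozygosity filter")
    obs = ~np.isnan(geno.dosages)
    call_rate = obs.mean(axis=1)
    fail_call = call_rate < th.sample_call_rate_min

    hard = np.round(geno.dosages)
    het = np.where(obs, hard == 1, False).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
    mu, sd = het.mean(), het.std()
    fail_het = np.abs(het - mu) > th.het_outlier_sd * sd if sd > 0 else np.zeros(len(het), bool)

    keep = ~(fail_call | fail_het)
    report = QCReport(
        axis="samples", n_input=geno.n_samples,
        removed={
            "low_call_rate": int(fail_call.sum()),
            "heterozygosity_outlier": int(fail_het.sum()),
        },
        n_removed=int((~keep).sum()), n_surviving=int(keep.sum()),
        surviving_ids=[s for s, k in zip(geno.sample_ids, keep) if k],
        not_performed=["gender_discrepancy", "relatedness", "pca_outliers"],
    )
    return geno.take_samples(keep), report


def run_qc(geno: GenotypeMatrix, th: QCThresholds = QCThresholds()
           ) -> tuple[GenotypeMatrix, dict]:
    """Variants-then-samples single-pass QC; returns the filtered matrix
    and a JSON-ready report."""
    g1, vrep = filter_variants(geno, th)
    g2, srep = filter_samples(g1, th)
    return g2, {"variants": vrep.to_dict(), "samples": srep.to_dict()}
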