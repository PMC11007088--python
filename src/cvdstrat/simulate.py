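"""Synthetic longitudinal-cohort generator.

Emulates the data-generating structure a genotype-plus-survey CVD
cohort study assumes: independent biallelic variants, four trait
panels (hypertension, myocardial infarction, ischemic stroke, coronary
artery disease) with sparse additive causal effects, per-sex clinical
covariates, baseline (prevalent) disease from a liability threshold,
and incident events from an exponential proportional-hazards model
observed on a biannual visit grid with per-visit dropout.

Ground truth (causal variants, true genetic scores, generative log
hazard ratios) is retained in :class:`TrueModel` so parameter-recovery
tests can compare downstream estimates with the values that produced
the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeMatrix, WeightPanel, VARIANT_META_COLUMNS, write_cohort_csv, write_vcf
from .params import TRAITS, ParameterError, SimulationParams, get_preset, truncnorm_underlying
from .pce import pce_linear_sum

__all__ = [
    "TrueModel",
    "StudyData",
    "sample_genotypes",
    "simulate_covariates",
    "assign_prevalent",
    "simulate_survival",
    "generate_study",
]


@dataclass
class TrueModel:
    """Generative ground truth kept alongside the synthetic cohort."""

    causal_effects: dict[str, pd.DataFrame]   # trait -> (variant_id, effect)
    genetic_scores: pd.DataFrame              # per-sample per-trait true scores
    total_genetic_z: np.ndarray               # standardized sum of trait z-scores
    clinical_z: np.ndarray                    # standardized clinical predictor
    liability: np.ndarray                     # prevalence liability
    log_hr_genetic: float
    log_hr_clinical: float


@dataclass
class StudyData:
    genotypes: GenotypeMatrix
    weights: dict[str, WeightPanel]
    cohort: pd.DataFrame
    truth: TrueModel


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# genotypes

def sample_genotypes(params: SimulationParams, rng: np.random.Generator | None = None,
                     corruption: dict | None = None) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotype dosages at independent variants.

    Each variant's MAF is uniform over ``params.maf_range`` and dosages
    are binomial(2, maf).  Metadata (empirical allele frequency, call
    rate, HWE p, simulated imputation quality) is populated from the
    drawn matrix.

    ``corruption`` optionally injects known QC violations for testing,
    with integer counts per kind: ``low_maf``, ``hwe_fail``,
    ``low_info``, ``low_call_variant``, ``low_call_sample``,
    ``high_het_sample``.
    """
    from .qc import hwe_test  # local import avoids a cycle

    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, m = params.n_samples, params.n_variants
    lo, hi = params.maf_range
    maf = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    info = rng.uniform(0.9, 1.0, size=m)

    corruption = dict(corruption or {})
    cursor = 0  # corrupted variants take the leading columns, one kind each

    def next_cols(k):
        nonlocal cursor
        cols = list(range(cursor, cursor + k))
        cursor += k
        if cursor > m:
            raise ParameterError("corruption profile exceeds n_variants")
        return cols

    for j in next_cols(corruption.get("low_maf", 0)):
        # exactly one minor-allele copy short of the 1% MAF boundary
        k = max(0, int(np.ceil(0.01 * 2 * n)) - 1)
        dosages[:, j] = 0.0
        dosages[rng.choice(n, size=k, replace=False), j] = 1.0
    for j in next_cols(corruption.get("hwe_fail", 0)):
        # heterozygote-free column: extreme HWE departure at any n
        dosages[:, j] = rng.choice([0.0, 2.0], size=n)
    low_info_cols = next_cols(corruption.get("low_info", 0))
    info[low_info_cols] = rng.uniform(0.3, 0.75, size=len(low_info_cols))
    for j in next_cols(corruption.get("low_call_variant", 0)):
        miss = rng.choice(n, size=max(1, int(np.ceil(0.06 * n))), replace=False)
        dosages[miss, j] = np.nan
    for i in rng.choice(n, size=corruption.get("low_call_sample", 0), replace=False):
        miss = rng.choice(m, size=max(1, int(np.ceil(0.04 * m))), replace=False)
        dosages[i, miss] = np.nan
    for i in rng.choice(n, size=corruption.get("high_het_sample", 0), replace=False):
        dosages[i, :] = 1.0  # fully heterozygous sample

    obs = ~np.isnan(dosages)
    af = np.nansum(dosages, axis=0) / (2 * obs.sum(axis=0))
    emp_maf = np.minimum(af, 1 - af)
    call_rate_v = obs.mean(axis=0)
    hwe_p = np.empty(m)
    for j in range(m):
        d = dosages[obs[:, j], j]
        counts = np.round(d).astype(int)
        n_aa = int((counts == 0).sum()); n_het = int((counts == 1).sum()); n_bb = int((counts == 2).sum())
        hwe_p[j] = hwe_test(n_bb, n_het, n_aa)

    variants = pd.DataFrame({
        "variant_id": [f"var{j + 1}" for j in range(m)],
        "chrom": np.repeat("1", m),
        "pos": np.arange(1, m + 1) * 1000,
        "effect_allele": np.repeat("A", m),
        "other_allele": np.repeat("G", m),
        "maf": emp_maf,
        "call_rate": call_rate_v,
        "hwe_p": hwe_p,
        "info_quality": info,
    })[VARIANT_META_COLUMNS]
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(dosages, sample_ids, variants)


# ---------------------------------------------------------------------------
# covariates

def simulate_covariates(params: SimulationParams, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample baseline clinical covariates with per-sex distributions.

    Age is drawn from a truncated normal on the enrolment range whose
    *observed* mean/SD match the configured values (the underlying
    normal is solved for at run time); continuous biomarkers are
    truncated below at zero.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cp = params.covariate_params
    n = params.n_samples
    female = rng.random(n) < cp.female_fraction
    sex = (~female).astype(int)  # 1 = male

    lo, hi = cp.age_range
    out = {"sex": sex}
    for name in ("age", "sbp", "tc", "hdl"):
        col = np.empty(n)
        for is_male, sp in ((True, cp.male), (False, cp.female)):
            mask = sex == (1 if is_male else 0)
            mean, sd = getattr(sp, f"{name}_mean"), getattr(sp, f"{name}_sd")
            if name == "age":
                mu, sigma = truncnorm_underlying(mean, sd, lo, hi)
                a, b = (lo - mu) / sigma, (hi - mu) / sigma
            else:
                mu, sigma = mean, sd
                a, b = (0.0 - mu) / sigma, np.inf
            col[mask] = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                            size=mask.sum(), random_state=rng)
        out[name] = col
    for name, attr in (("smoker", "smoking_prev"), ("bp_treated", "bp_treat_prev"),
                       ("diabetes", "diabetes_prev")):
        p = np.where(sex == 1, cp.male.__getattribute__(attr), cp.female.__getattribute__(attr))
        out[name] = (rng.random(n) < p).astype(int)
    df = pd.DataFrame(out)
    df.insert(0, "sample_id", [f"S{i + 1:05d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# prevalent disease

def assign_prevalent(liability, target: float, rng, slope: float = 0.5) -> np.ndarray:
    """Draw baseline-disease flags from a probit liability model.

    P(prevalent_i) = Phi(a + slope * z_i) with the intercept ``a``
    solved so the expected prevalence equals ``target`` exactly; the
    probability is strictly increasing in liability.
    """
    liability = np.asarray(liability, dtype=float)
    if not np.all(np.isfinite(liability)):
        raise ParameterError("non-finite liability values")
    if not 0.0 <= target < 1.0:
        raise ParameterError(f"prevalence target {target} outside [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if target == 0.0:
        return np.zeros(len(liability), dtype=int)
    z = _zscore(liability)

    def mean_prob(a):
        return stats.norm.cdf(a + slope * z).mean() - target

    a = optimize.brentq(mean_prob, -30, 30)
    p = stats.norm.cdf(a + slope * z)
    return (rng.random(len(z)) < p).astype(int)


# ---------------------------------------------------------------------------
# incident events on the visit grid

def simulate_survival(linear_predictor, params: SimulationParams,
                      rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards event times observed biannually.

    hazard_i = baseline_hazard * exp(lp_i).  The raw event time is
    discretized to the first visit at or after it (interval detection
    by survey); otherwise the sample is censored at its last attended
    visit.  Planned follow-up ends at one of the last two grid visits
    (equally likely — a two-wave enrolment window relative to the final
    survey), and after each attended visit a sample drops out with
    probability ``dropout_prob_per_visit``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    bad = np.flatnonzero(~np.isfinite(lp))
    if bad.size:
        raise ParameterError(f"non-finite linear predictor for sample index {bad[0]}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(lp)
    grid = params.visit_grid
    n_visits = len(grid)

    # planned last visit: one of the final two waves
    planned_idx = np.where(rng.random(n) < 0.5, n_visits - 1, n_visits)  # 1-based count
    if n_visits == 1:
        planned_idx = np.ones(n, dtype=int)
    q = params.dropout_prob_per_visit
    if q > 0:
        attended = np.minimum(rng.geometric(q, size=n), planned_idx)
    else:
        attended = planned_idx
    censor_time = grid[attended - 1]

    if params.baseline_hazard == 0:
        raw = np.full(n, np.inf)
    else:
        rate = params.baseline_hazard * np.exp(lp)
        raw = rng.exponential(1.0 / rate)
    event = (raw <= censor_time).astype(int)
    event_visit = grid[np.minimum(np.searchsorted(grid, raw), n_visits - 1)]
    time = np.where(event == 1, event_visit, censor_time)
    return time, event


# ---------------------------------------------------------------------------
# end-to-end study

def generate_study(params: SimulationParams | str = "table1", out_dir=None,
                   seed: int | None = None, **overrides) -> StudyData:
    """Generate a complete synthetic study: genotypes, per-trait weight
    panels, cohort table with prevalent flags and incident outcomes, and
    the generative ground truth.

    ``params`` may be a :class:`SimulationParams` or a preset name.
    When ``out_dir`` is given, all external-format files are written
    there (VCF + dosage/metadata TSVs, weight TSVs, cohort CSV).
    """
    if isinstance(params, str):
        params = get_preset(params, **overrides)
    elif overrides or seed is not None:
        from dataclasses import replace
        params = replace(params, **overrides, **({"seed": seed} if seed is not None else {}))
    if seed is not None and params.seed != seed:
        from dataclasses import replace
        params = replace(params, seed=seed)

    root = np.random.SeedSequence(params.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]
    geno = sample_genotypes(params, rng=rngs[0])
    cov = simulate_covariates(params, rng=rngs[1])

    # sparse causal architecture per trait
    effects_rng = rngs[2]
    causal_effects: dict[str, pd.DataFrame] = {}
    scores = {}
    dos = np.nan_to_num(geno.dosages, nan=0.0)
    for trait in TRAITS:
        idx = effects_rng.choice(params.n_variants, size=params.n_causal_per_trait, replace=False)
        beta = effects_rng.normal(0.0, params.trait_effect_sd, size=params.n_causal_per_trait)
        causal_effects[trait] = pd.DataFrame({
            "variant_id": geno.variants["variant_id"].to_numpy()[idx],
            "effect": beta,
        })
        scores[trait] = dos[:, idx] @ beta
    genetic_scores = pd.DataFrame(scores)
    total_genetic_z = _zscore(np.sum([_zscore(genetic_scores[t].to_numpy()) for t in TRAITS], axis=0))

    clin_sum = pce_linear_sum(cov["age"], cov["tc"], cov["hdl"], cov["sbp"],
                              cov["bp_treated"], cov["smoker"], cov["diabetes"], cov["sex"])
    clinical_z = np.empty(len(cov))
    for s in (0, 1):  # PCE sums live on different scales per sex
        m = cov["sex"].to_numpy() == s
        clinical_z[m] = _zscore(clin_sum[m])

    liability = total_genetic_z + 0.5 * _zscore(cov["age"].to_numpy()) + 0.3 * (cov["sex"].to_numpy() - cov["sex"].mean())
    prevalent = assign_prevalent(liability, params.prevalence_target, rngs[3])

    lp = params.log_hr_genetic * total_genetic_z + params.log_hr_clinical * clinical_z
    lp = lp - lp.mean()
    time, event = simulate_survival(lp, params, rng=rngs[4])

    cohort = cov.copy()
    cohort["prevalent_cvd"] = prevalent
    cohort["time_years"] = time
    cohort["event"] = event

    weights = {
        t: WeightPanel(t, causal_effects[t].rename(columns={"effect": "weight"}).assign(
            effect_allele="A")[["variant_id", "effect_allele", "weight"]])
        for t in TRAITS
    }
    truth = TrueModel(causal_effects=causal_effects, genetic_scores=genetic_scores,
                      total_genetic_z=total_genetic_z, clinical_z=clinical_z,
                      liability=liability, log_hr_genetic=params.log_hr_genetic,
                      log_hr_clinical=params.log_hr_clinical)
    study = StudyData(genotypes=geno, weights=weights, cohort=cohort, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            geno.write_tsv(out / "dosages.tsv", out / "variants.tsv")
            write_vcf(geno, out / "genotypes.vcf")
            for t, panel in weights.items():
                panel.write_tsv(out / f"weights_{t}.tsv")
            write_cohort_csv(cohort, out / "cohort.csv")
        except OSError as exc:
            raise OSError(f"failed writing study files under {out}: {exc}") from exc
    return study
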