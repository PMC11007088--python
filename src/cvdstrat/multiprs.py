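"""Combination of trait-specific scores into a weighted multi-score.

The combination weight of each normalized trait PRS is its coefficient
in one multiple logistic regression of prevalent disease on all the
trait scores plus age and sex; the weighted sum (wPRSsum) then uses
the PRS coefficients only — covariates re-enter downstream through
Cox adjustment and the clinical equation.  Genetic risk groups are the
bottom 20% / middle 60% / top 20% of wPRSsum, with cutpoints taken
over a configurable base set (by default the full genotyped cohort,
before any exclusions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from itertools import combinations

__all__ = [
    "PrsWeightFit",
    "GeneticGroupAssignment",
    "fit_prs_weights",
    "combine_wprssum",
    "assign_genetic_groups",
    "prs_association_scan",
]


@dataclass
class PrsWeightFit:
    """Logistic combination weights (log-odds per SD of each trait PRS)."""

    weights: pd.Series            # per-trait coefficient
    se: pd.Series
    p: pd.Series
    covariate_coefs: pd.Series    # intercept, age, sex — reporting only
    n_cases: int
    n_total: int

    @property
    def traits(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class GeneticGroupAssignment:
    wprssum: np.ndarray
    group: np.ndarray             # "low" / "intermediate" / "high"
    cutpoints: tuple[float, float]


def _logit_fit(y, X):
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise ValueError(
            f"logistic fit failed ({exc}); with very few prevalent cases the "
            "model can separate — use a larger synthetic cohort") from exc
    if not np.all(np.isfinite(res.bse)):
        raise ValueError("logistic fit did not converge to finite standard errors; "
                         "use a larger synthetic cohort")
    return res


def fit_prs_weights(prs: pd.DataFrame, prevalent, age, sex) -> PrsWeightFit:
    """One multiple logistic regression of prevalent status on all trait
    scores, adjusted for age and sex; the PRS coefficients are the
    combination weights."""
    y = np.asarray(prevalent, dtype=int)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one prevalent case and one non-case")
    traits = list(prs.columns)
    X = pd.DataFrame({t: np.asarray(prs[t], float) for t in traits})
    X["age"] = np.asarray(age, float)
    X["sex"] = np.asarray(sex, float)
    X = sm.add_constant(X, prepend=True)
    res = _logit_fit(y, X)
    return PrsWeightFit(
        weights=res.params[traits],
        se=res.bse[traits],
        p=res.pvalues[traits],
        covariate_coefs=res.params[["const", "age", "sex"]],
        n_cases=int(y.sum()),
        n_total=len(y),
    )


def combine_wprssum(prs: pd.DataFrame, fit: PrsWeightFit) -> np.ndarray:
    """wPRSsum_i = sum_t weight_t * prs_it (no intercept, no covariates)."""
    missing = [t for t in fit.traits if t not in prs.columns]
    if missing:
        raise ValueError(f"score table lacks trait column(s): {missing}")
    return prs[fit.traits].to_numpy(float) @ fit.weights.to_numpy(float)


def assign_genetic_groups(wprssum, cut_low: float = 0.20, cut_high: float = 0.80,
                          base=None) -> GeneticGroupAssignment:
    """Label samples low / intermediate / high genetic risk.

    Cutpoints are empirical quantiles (linear interpolation) of
    ``base`` — by default the scores themselves; pass the full-cohort
    scores to classify a subset against cohort-wide quintiles.
    Intervals are half-open on the left group's right edge:
    [min, q20) / [q20, q80) / [q80, max].
    """
    w = np.asarray(wprssum, dtype=float)
    b = w if base is None else np.asarray(base, dtype=float)
    if len(b) == 0:
        raise ValueError("cutpoint base set is empty")
    q_lo, q_hi = np.quantile(b, [cut_low, cut_high])
    if q_lo == q_hi:
        raise ValueError("degenerate score distribution: q20 == q80")
    group = np.where(w < q_lo, "low", np.where(w < q_hi, "intermediate", "high"))
    return GeneticGroupAssignment(wprssum=w, group=group, cutpoints=(float(q_lo), float(q_hi)))


def prs_association_scan(prs: pd.DataFrame, prevalent, age, sex) -> pd.DataFrame:
    """Association of every nonempty trait subset with prevalent disease.

    For each subset, combination weights are fitted on that subset and
    the subset's weighted sum formed; the reported odds ratio is per SD
    of that sum (age/sex-adjusted).  Because the sum's weights are
    estimated on the same response, a Wald test of the sum would be
    anti-conservative; the row's p-value is therefore the
    likelihood-ratio test of the subset's trait coefficients (k df,
    against the age/sex-only model), which is calibrated under the
    null.  Returns one row per subset (15 rows for four traits).
    """
    from scipy import stats as _stats

    traits = list(prs.columns)
    y = np.asarray(prevalent, dtype=int)
    age = np.asarray(age, float)
    sex = np.asarray(sex, float)
    reduced = _logit_fit(y, sm.add_constant(
        pd.DataFrame({"age": age, "sex": sex}), prepend=True))
    rows = []
    for r in range(1, len(traits) + 1):
        for subset in combinations(traits, r):
            sub = prs[list(subset)]
            fit = fit_prs_weights(sub, y, age, sex)
            combined = sub.to_numpy(float) @ fit.weights.to_numpy(float)
            z = (combined - combined.mean()) / combined.std()
            X = sm.add_constant(pd.DataFrame({"score": z, "age": age, "sex": sex}),
                                prepend=True)
            res = _logit_fit(y, X)
            full = _logit_fit(y, sm.add_constant(
                pd.concat([sub.reset_index(drop=True),
                           pd.DataFrame({"age": age, "sex": sex})], axis=1),
                prepend=True))
            lr = 2.0 * (full.llf - reduced.llf)
            rows.append({
                "subset": " + ".join(subset),
                "n_traits": r,
                "odds_ratio": float(np.exp(res.params["score"])),
                "p_value": float(_stats.chi2.sf(max(lr, 0.0), df=r)),
            })
    return pd.DataFrame(rows)
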