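"""Recalibrated pooled cohort equations (PCE) for 10-year CVD risk.

The PCE is a sex-specific linear score on log-transformed clinical
covariates.  Exactly one blood-pressure pathway is active per person:
for treated individuals TRSBP carries the measured SBP and UNSBP is 1
(so its log terms vanish); untreated individuals are the mirror image.
The linear sum is converted to an absolute 10-year risk through a
cohort-recalibrated mean sum and 10-year baseline survival:

    risk = 1 - S0(10) ** exp(sum - mean_sum)

Neither the mean sum nor the baseline survival is part of the published
coefficient set; both are estimated from the target cohort (the
recalibration step) or supplied via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCE_COEF_MEN",
    "PCE_COEF_WOMEN",
    "PceCalibration",
    "pce_linear_sum",
    "recalibrate",
    "pce_risk",
    "assign_pce_groups",
    "PCE_RISK_THRESHOLD",
]

#: Men's coefficient set (Korean-recalibrated pooled cohort equation).
PCE_COEF_MEN = {
    "ln_age": 4.950,
    "ln_tc": 0.943,
    "ln_hdl": -0.693,
    "ln_trsbp": 1.101,
    "ln_unsbp": 1.002,
    "cusmok": 5.485,
    "ln_age_x_cusmok": -1.287,
    "dm": 0.558,
}

#: Women's coefficient set, with age-by-blood-pressure interactions.
PCE_COEF_WOMEN = {
    "ln_age": 36.699,
    "ln_tc": 0.625,
    "ln_hdl": -0.449,
    "ln_trsbp": 29.947,
    "ln_age_x_ln_trsbp": -7.010,
    "ln_unsbp": 29.255,
    "ln_age_x_ln_unsbp": -6.847,
    "cusmok": 0.497,
    "dm": 0.962,
}

#: 10-year risk cut separating the low (<7.5%) and high (>=7.5%) groups.
PCE_RISK_THRESHOLD = 0.075


@dataclass(frozen=True)
class PceCalibration:
    """Cohort anchors of the risk transform, per sex."""

    mean_sum_male: float
    mean_sum_female: float
    s0_10y_male: float
    s0_10y_female: float

    def __post_init__(self):
        for s0 in (self.s0_10y_male, self.s0_10y_female):
            if not 0.0 < s0 <= 1.0:
                raise ValueError(f"baseline survival {s0} outside (0, 1]")

    def mean_sum(self, male: bool) -> float:
        return self.mean_sum_male if male else self.mean_sum_female

    def s0(self, male: bool) -> float:
        return self.s0_10y_male if male else self.s0_10y_female


def _as_arrays(*cols):
    return [np.asarray(c, dtype=float) for c in cols]


def pce_linear_sum(age, tc, hdl, sbp, bp_treated, smoker, diabetes, sex) -> np.ndarray:
    """Evaluate the sex-specific PCE linear sum, vectorized.

    Parameters are the clinical covariates at baseline; ``sex`` is 1 for
    male, 0 for female.  Natural logs throughout; the treated/untreated
    SBP split follows the one-active-pathway encoding described in the
    module docstring.
    """
    age, tc, hdl, sbp, bp_treated, smoker, diabetes, sex = _as_arrays(
        age, tc, hdl, sbp, bp_treated, smoker, diabetes, sex)
    if np.any(tc <= 0) or np.any(hdl <= 0) or np.any(sbp <= 0) or np.any(age <= 0):
        raise ValueError("age, TC, HDL and SBP must be positive")
    ln_age, ln_tc, ln_hdl = np.log(age), np.log(tc), np.log(hdl)
    treated = bp_treated > 0
    ln_trsbp = np.where(treated, np.log(sbp), 0.0)  # ln(1) = 0 when untreated
    ln_unsbp = np.where(treated, 0.0, np.log(sbp))

    cm = PCE_COEF_MEN
    men = (cm["ln_age"] * ln_age + cm["ln_tc"] * ln_tc + cm["ln_hdl"] * ln_hdl
           + cm["ln_trsbp"] * ln_trsbp + cm["ln_unsbp"] * ln_unsbp
           + cm["cusmok"] * smoker + cm["ln_age_x_cusmok"] * ln_age * smoker
           + cm["dm"] * diabetes)
    cw = PCE_COEF_WOMEN
    women = (cw["ln_age"] * ln_age + cw["ln_tc"] * ln_tc + cw["ln_hdl"] * ln_hdl
             + cw["ln_trsbp"] * ln_trsbp + cw["ln_age_x_ln_trsbp"] * ln_age * ln_trsbp
             + cw["ln_unsbp"] * ln_unsbp + cw["ln_age_x_ln_unsbp"] * ln_age * ln_unsbp
             + cw["cusmok"] * smoker + cw["dm"] * diabetes)
    return np.where(sex > 0, men, women)


def pce_linear_sum_cohort(cohort: pd.DataFrame) -> np.ndarray:
    """Convenience wrapper taking the canonical cohort schema."""
    return pce_linear_sum(cohort["age"], cohort["tc"], cohort["hdl"], cohort["sbp"],
                          cohort["bp_treated"], cohort["smoker"], cohort["diabetes"],
                          cohort["sex"])


def recalibrate(sums, time, event, sex, horizon: float = 10.0) -> PceCalibration:
    """Estimate per-sex mean linear sum and Kaplan-Meier baseline survival
    at the risk horizon from the target cohort."""
    from .survival import km_survival_at

    sums, time, event, sex = _as_arrays(sums, time, event, sex)
    out = {}
    for label, male in (("male", True), ("female", False)):
        m = sex > 0 if male else sex <= 0
        if m.sum() < 2:
            raise ValueError(f"fewer than 2 {label} samples; cannot recalibrate")
        if time[m].max() < horizon:
            raise ValueError(f"no {label} follow-up reaches the {horizon}-year horizon")
        out[f"mean_sum_{label}"] = float(sums[m].mean())
        out[f"s0_10y_{label}"] = km_survival_at(time[m], event[m], horizon)
    return PceCalibration(**out)


def pce_risk(sums, sex, cal: PceCalibration) -> np.ndarray:
    """10-year risk = 1 - S0(10) ** exp(sum - mean_sum), per sex."""
    sums, sex = _as_arrays(sums, sex)
    male = sex > 0
    mean_sum = np.where(male, cal.mean_sum(True), cal.mean_sum(False))
    s0 = np.where(male, cal.s0(True), cal.s0(False))
    return 1.0 - np.power(s0, np.exp(sums - mean_sum))


def assign_pce_groups(risk, threshold: float = PCE_RISK_THRESHOLD) -> np.ndarray:
    """Label each sample ``high`` iff its 10-year risk >= threshold."""
    risk = np.asarray(risk, dtype=float)
    if np.any((risk < 0) | (risk > 1)):
        raise ValueError("risks must lie in [0, 1]")
    return np.where(risk >= threshold, "high", "low")
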