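"""Shared scoring helper: turn a synthetic study into an analysis-ready
frame the way the pipeline does, minus file I/O and the LOGO stage."""

import pandas as pd

from cvdstrat.multiprs import assign_genetic_groups, combine_wprssum, fit_prs_weights
from cvdstrat.params import TRAITS
from cvdstrat.pce import assign_pce_groups, pce_linear_sum_cohort, pce_risk, recalibrate
from cvdstrat.pipeline import apply_exclusions
from cvdstrat.prs import compute_prs, normalize_scores


def build_analysis_frame(study) -> pd.DataFrame:
    cohort = study.cohort
    prs_norm = pd.DataFrame({
        t: normalize_scores(compute_prs(study.genotypes, study.weights[t]))
        for t in TRAITS})
    fit = fit_prs_weights(prs_norm, cohort["prevalent_cvd"], cohort["age"], cohort["sex"])
    full = cohort.copy()
    full["wprssum"] = combine_wprssum(prs_norm, fit)
    full["pce_sum_raw"] = pce_linear_sum_cohort(cohort)
    analysis, _ = apply_exclusions(full)
    cal = recalibrate(analysis["pce_sum_raw"], analysis["time_years"],
                      analysis["event"], analysis["sex"])
    risk = pce_risk(analysis["pce_sum_raw"], analysis["sex"], cal)
    analysis["pce_group"] = assign_pce_groups(risk)
    analysis["pce_sum"] = analysis["pce_sum_raw"] - [
        cal.mean_sum(bool(s)) for s in analysis["sex"]]
    ga = assign_genetic_groups(analysis["wprssum"], base=full["wprssum"].to_numpy())
    analysis["genetic_group"] = ga.group
    return analysis
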