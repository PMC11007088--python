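"""Risk-stratification model: the fitted-object view of the analysis.

:class:`RiskStratificationModel` is built from an analysis-ready
cohort frame (follow-up, events, covariates, combined genetic score,
clinical score, group labels); :meth:`~RiskStratificationModel.fit`
runs the Cox models and concordance evaluation and returns a
:class:`RiskStratificationResults` carrying:

* the hazard ratio per SD of the combined genetic score and the
  genetic-group stratum HRs (low / intermediate / high);
* the clinical (PCE) group HR (high vs low 10-year risk);
* the 2 x 3 cross-stratum table with the (low, low) baseline;
* the C-index table of the five predictive models, overall and in
  sex / age-55 subgroups;
* Kaplan-Meier curves by each grouping.

All stratum models are adjusted for age and sex; the stratum-indicator
HRs are what is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import (MODEL_SPECS, DEFAULT_SUBGROUPS, CoxFit, evaluate_models,
                       fit_cox, km_curve)

__all__ = ["RiskStratificationModel", "RiskStratificationResults",
           "GENETIC_GROUP_ORDER", "PCE_GROUP_ORDER", "stratum_order"]

GENETIC_GROUP_ORDER = ("low", "intermediate", "high")
PCE_GROUP_ORDER = ("low", "high")

REQUIRED_COLUMNS = ("time_years", "event", "age", "sex", "wprssum", "pce_sum",
                    "genetic_group", "pce_group")


def stratum_order():
    """Row order of the cross-stratum table: PCE-major, genetic-minor."""
    return [(p, g) for p in PCE_GROUP_ORDER for g in GENETIC_GROUP_ORDER]


class RiskStratificationModel:
    """Survival model of incident disease on genetic and clinical strata.

    Parameters
    ----------
    data:
        Analysis set (prevalent cases already excluded), one row per
        participant, with the columns named in ``REQUIRED_COLUMNS``.
    adjust:
        Adjustment covariates for the stratum models (default age, sex).
    """

    def __init__(self, data: pd.DataFrame, adjust: tuple[str, ...] = ("age", "sex")):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"analysis frame lacks column(s): {missing}")
        if len(data) == 0:
            raise ValueError("empty analysis set")
        self.data = data.reset_index(drop=True).copy()
        self.adjust = list(adjust)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "RiskStratificationModel":
        return cls(data, **kw)

    # ------------------------------------------------------------------

    def _indicator_cox(self, labels: np.ndarray, order, baseline) -> pd.DataFrame:
        """Cox fit on stratum indicator columns (baseline omitted), with
        adjustment covariates; returns one row per stratum."""
        df = self.data
        cov = pd.DataFrame(index=df.index)
        names = []
        for lev in order:
            if lev == baseline:
                continue
            name = str(lev)
            cov[name] = (labels == lev).astype(float)
            names.append(name)
        for a in self.adjust:
            cov[a] = df[a].to_numpy(float)
        fit = fit_cox(df["time_years"], df["event"], cov)
        rows = []
        for lev in order:
            mask = labels == lev
            row = {"group": lev, "n": int(mask.sum()), "events": int(df.loc[mask, "event"].sum())}
            if lev == baseline or str(lev) not in fit.table.index:
                row.update({"hr": np.nan, "se": np.nan, "p": np.nan})
            else:
                row.update({"hr": fit.hr(str(lev)),
                            "se": float(fit.table.loc[str(lev), "se"]),
                            "p": float(fit.table.loc[str(lev), "p"])})
            rows.append(row)
        return pd.DataFrame(rows)

    def fit(self, subgroups=DEFAULT_SUBGROUPS) -> "RiskStratificationResults":
        df = self.data
        # continuous combined-score HR (per SD), age/sex-adjusted
        z = (df["wprssum"] - df["wprssum"].mean()) / df["wprssum"].std()
        cont = fit_cox(df["time_years"], df["event"],
                       pd.DataFrame({"wprssum": z, **{a: df[a] for a in self.adjust}}))

        genetic = self._indicator_cox(df["genetic_group"].to_numpy(),
                                      GENETIC_GROUP_ORDER, "low")
        pce = self._indicator_cox(df["pce_group"].to_numpy(), PCE_GROUP_ORDER, "low")

        # 2 x 3 cross strata with (low, low) baseline
        combo = df["pce_group"].astype(str) + "/" + df["genetic_group"].astype(str)
        order = [f"{p}/{g}" for p, g in stratum_order()]
        present = [o for o in order if (combo == o).any()]
        strata = self._indicator_cox(combo.to_numpy(), present, "low/low")
        strata[["pce_group", "genetic_group"]] = strata["group"].str.split("/", expand=True)
        strata = strata[["pce_group", "genetic_group", "n", "events", "hr", "se", "p"]]

        cindex = evaluate_models(df, MODEL_SPECS, subgroups)
        km_genetic = km_curve(df["time_years"], df["event"], df["genetic_group"])
        km_pce = km_curve(df["time_years"], df["event"], df["pce_group"])
        km_strata = km_curve(df["time_years"], df["event"], combo)

        return RiskStratificationResults(
            model=self, wprssum_fit=cont, genetic_group_table=genetic,
            pce_group_table=pce, stratum_table=strata, cindex_table=cindex,
            km_genetic=km_genetic, km_pce=km_pce, km_strata=km_strata)


@dataclass
class RiskStratificationResults:
    model: RiskStratificationModel
    wprssum_fit: CoxFit
    genetic_group_table: pd.DataFrame
    pce_group_table: pd.DataFrame
    stratum_table: pd.DataFrame
    cindex_table: pd.DataFrame
    km_genetic: pd.DataFrame
    km_pce: pd.DataFrame
    km_strata: pd.DataFrame

    def summary(self) -> str:
        df = self.model.data
        w = self.wprssum_fit.table.loc["wprssum"]
        lines = [
            "Risk stratification of incident CVD",
            "===================================",
            f"analysis set: n = {len(df)}, events = {int(df['event'].sum())}",
            "",
            f"combined genetic score (per SD, age/sex-adjusted): "
            f"HR = {w['hr']:.3f} (SE {w['se']:.3f}, p = {w['p']:.3g})",
            "",
            "genetic risk groups (baseline: low):",
            self.genetic_group_table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "clinical 10-year-risk groups (baseline: low):",
            self.pce_group_table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "cross strata (baseline: low PCE / low genetic):",
            self.stratum_table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "C-index of the predictive models:",
            self.cindex_table.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def plot_km(self, which: str = "genetic", ax=None):
        """Step-plot the Kaplan-Meier curves for one grouping
        (``genetic``, ``pce`` or ``strata``)."""
        import matplotlib.pyplot as plt

        km = {"genetic": self.km_genetic, "pce": self.km_pce, "strata": self.km_strata}[which]
        if ax is None:
            _, ax = plt.subplots()
        for g, sub in km.groupby("group"):
            ax.step(np.r_[0, sub["time_years"] if "time_years" in sub else sub["time"]],
                    np.r_[1.0, sub["survival"]], where="post", label=str(g))
        ax.set_xlabel("years of follow-up")
        ax.set_ylabel("event-free survival")
        ax.legend(title=which)
        return ax
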