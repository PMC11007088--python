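"""Survival estimation against independent oracles: brute-force Efron
partial likelihood, hand product-limit arithmetic, and exhaustive
concordant-pair enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cvdstrat.survival import c_index, evaluate_models, fit_cox, km_curve, km_survival_at


# ---------------------------------------------------------------------------
# oracles

def efron_log_partial_likelihood(beta, x, time, event):
    """Single-covariate Cox partial log-likelihood with Efron ties,
    written directly from the estimator's definition."""
    eta = beta * x
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = int(D.sum())
        theta_D = theta[D].sum()
        theta_R = theta[R].sum()
        ll += eta[D].sum()
        for ell in range(d):
            ll -= np.log(theta_R - (ell / d) * theta_D)
    return ll


def cindex_enumeration_oracle(score, time, event):
    """O(n^2) pair enumeration following Harrell's comparability rule."""
    n = len(score)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = event[i] == 1 and (
                time[i] < time[j] or (time[i] == time[j] and event[j] == 0))
            if not comparable:
                continue
            den += 1
            if score[i] > score[j]:
                num += 1
            elif score[i] == score[j]:
                num += 0.5
    return num / den


# ---------------------------------------------------------------------------

class TestCox:
    def test_tied_toy_matches_brute_force_efron(self):
        # 8 observations on a coarse grid with heavy ties
        time = np.array([2.0, 2.0, 2.0, 4.0, 4.0, 6.0, 6.0, 6.0])
        event = np.array([1, 1, 0, 1, 0, 1, 1, 0])
        x = np.array([0.5, 1.2, -0.3, 0.8, -1.0, 1.5, 0.2, -0.7])
        fit = fit_cox(time, event, pd.DataFrame({"x": x}))
        res = optimize.minimize_scalar(
            lambda b: -efron_log_partial_likelihood(b, x, time, event),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12})
        assert fit.table.loc["x", "log_hr"] == pytest.approx(res.x, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)

    def test_null_covariate_recovered(self):
        rng = np.random.default_rng(0)
        n = 2000
        t = rng.exponential(10, n)
        e = (t < 15).astype(int)
        t = np.minimum(t, 15)
        x = rng.normal(size=n)  # independent of hazard
        fit = fit_cox(t, e, pd.DataFrame({"x": x}))
        assert abs(fit.table.loc["x", "log_hr"]) < 3 * fit.table.loc["x", "se"]

    def test_optimum_beats_null_likelihood(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        t = rng.exponential(1 / np.exp(0.5 * x))
        e = np.ones(300, dtype=int)
        fit = fit_cox(t, e, pd.DataFrame({"x": x}))
        ll_null = efron_log_partial_likelihood(0.0, x, t, e)
        assert fit.log_likelihood >= ll_null

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox([1, 2], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 50)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_cox(t, np.ones(50), pd.DataFrame({"c": np.ones(50),
                                                        "x": rng.normal(size=50)}))
        assert list(fit.table.index) == ["x"]


class TestKm:
    def test_no_events_flat_at_one(self):
        km = km_curve([2, 4, 6], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        km = km_curve([1.0, 2.0, 3.0], [1, 0, 1]).set_index("time")
        assert km.loc[1.0, "survival"] == pytest.approx(2 / 3)
        assert km.loc[3.0, "survival"] == pytest.approx(0.0)

    def test_survival_monotone_from_one(self):
        rng = np.random.default_rng(2)
        t = np.ceil(rng.exponential(5, 200))
        e = rng.integers(0, 2, 200)
        km = km_curve(t, e)
        s = km["survival"].to_numpy()
        assert s[0] <= 1.0 + 1e-12
        assert (np.diff(s) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()

    def test_duplicated_group_gives_identical_curves(self):
        t = np.array([2.0, 4.0, 6.0, 8.0] * 2)
        e = np.array([1, 0, 1, 0] * 2)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        km = km_curve(t, e, g)
        a = km[km["group"] == 0].drop(columns="group").reset_index(drop=True)
        b = km[km["group"] == 1].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        t = np.ceil(rng.exponential(5, 100))
        e = rng.integers(0, 2, 100)
        perm = rng.permutation(100)
        pd.testing.assert_frame_equal(km_curve(t, e), km_curve(t[perm], e[perm]))

    def test_survival_at_horizon(self):
        assert km_survival_at([2, 4, 6, 8, 12], [1, 0, 1, 0, 0], 10.0) == \
            pytest.approx(8 / 15)


class TestCindex:
    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert c_index(-t, t, np.ones(4, int)) == 1.0

    def test_constant_score_half(self):
        t = np.array([1.0, 2.0, 3.0])
        assert c_index(np.zeros(3), t, np.ones(3, int)) == 0.5

    def test_mixed_censoring_toy_matches_enumeration(self):
        score = np.array([3.0, 1.0, 2.0, 2.0, 0.0, 4.0])
        time = np.array([2.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        event = np.array([1, 1, 0, 1, 0, 1])
        assert c_index(score, time, event) == \
            pytest.approx(cindex_enumeration_oracle(score, time, event), abs=1e-12)

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(6, 21)
            score = np.round(rng.normal(size=n), 1)  # induce score ties
            time = rng.integers(1, 6, n).astype(float)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            assert c_index(score, time, event) == \
                pytest.approx(cindex_enumeration_oracle(score, time, event), abs=1e-12)

    def test_negation_symmetry_without_ties(self):
        rng = np.random.default_rng(9)
        score = rng.normal(size=30)
        time = rng.permutation(30).astype(float)
        event = rng.integers(0, 2, 30)
        event[0] = 1
        assert c_index(score, time, event) + c_index(-score, time, event) == \
            pytest.approx(1.0)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            c_index([1.0, 2.0], [5.0, 5.0], [0, 0])


class TestEvaluateModels:
    def _frame(self, rng, n=800, signal=0.0):
        x = rng.normal(size=n)
        age = rng.uniform(40, 69, n)
        sex = rng.integers(0, 2, n)
        lp = signal * x
        t = np.ceil(rng.exponential(1 / (0.05 * np.exp(lp - lp.mean()))) / 2) * 2
        e = (t <= 16).astype(int)
        t = np.minimum(t, 16)
        return pd.DataFrame({"time_years": t, "event": e, "age": age, "sex": sex,
                             "wprssum": x, "pce_sum": rng.normal(size=n)})

    def test_null_models_near_half(self):
        df = self._frame(np.random.default_rng(0))
        tab = evaluate_models(df, subgroups=("all",))
        assert np.nanmax(np.abs(tab["all"].to_numpy() - 0.5)) < 0.06

    def test_signal_model_dominates(self):
        df = self._frame(np.random.default_rng(1), signal=0.6)
        tab = evaluate_models(df, subgroups=("all",))
        assert tab.loc[2, "all"] > 0.55  # wprssum model carries the signal

    def test_monotone_rescaling_of_single_covariate_invariant(self):
        df = self._frame(np.random.default_rng(2), signal=0.4)
        a = evaluate_models(df, specs={2: ["wprssum"]}, subgroups=("all",)).loc[2, "all"]
        direct = c_index(df["wprssum"], df["time_years"], df["event"])
        assert a == pytest.approx(direct, abs=1e-12)

    def test_eventless_subgroup_is_nan(self):
        df = self._frame(np.random.default_rng(3), n=100)
        df.loc[df["sex"] == 1, "event"] = 0
        tab = evaluate_models(df, specs={2: ["wprssum"]}, subgroups=("male",))
        assert np.isnan(tab.loc[2, "male"])
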