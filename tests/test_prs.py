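"""Scoring engine: additive PRS against a loop oracle, inverse-normal
transform, vectorized logistic GWAS against statsmodels and closed
forms, inverse-variance pooling, and the LOGO cross-fit."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cvdstrat.prs import (GwasResult, compute_prs, logo_prs, meta_analyze,
                          normalize_scores, run_gwas)
from tests.conftest import make_geno, make_panel


def prs_loop_oracle(dosages, geno_variants, panel_table):
    """Brute-force double loop over samples and panel rows."""
    idx = {v: j for j, v in enumerate(geno_variants["variant_id"])}
    ea = dict(zip(geno_variants["variant_id"], geno_variants["effect_allele"]))
    oa = dict(zip(geno_variants["variant_id"], geno_variants["other_allele"]))
    n = dosages.shape[0]
    out = np.zeros(n)
    for _, row in panel_table.iterrows():
        v = row["variant_id"]
        if v not in idx:
            continue
        for i in range(n):
            d = dosages[i, idx[v]]
            if row["effect_allele"] == ea[v]:
                out[i] += d * row["weight"]
            elif row["effect_allele"] == oa[v]:
                out[i] += (2 - d) * row["weight"]
    return out


class TestComputePrs:
    def test_zero_weights_zero_scores(self):
        g = make_geno(np.random.default_rng(0).binomial(2, 0.4, (6, 3)).astype(float))
        r = compute_prs(g, make_panel("t", ["v0", "v1", "v2"], [0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(r.scores, 0.0)

    def test_single_variant_sum(self):
        g = make_geno([[2.0], [0.0]])
        r = compute_prs(g, make_panel("t", ["v0"], [0.5]))
        assert r.scores[0] == 1.0 and r.scores[1] == 0.0

    def test_matches_loop_oracle_with_allele_flips(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, (5, 4)).astype(float)
        g = make_geno(d)
        panel = make_panel("t", ["v0", "v1", "v2", "v3"],
                           rng.normal(size=4),
                           effect_alleles=["A", "G", "A", "G"])  # two flipped
        r = compute_prs(g, panel)
        np.testing.assert_allclose(r.scores, prs_loop_oracle(d, g.variants, panel.table),
                                   rtol=0, atol=1e-12)
        assert r.n_variants_used == 4

    def test_absent_and_mismatched_variants_counted(self):
        g = make_geno(np.ones((3, 2)))
        panel = make_panel("t", ["v0", "v1", "nope"], [1.0, 1.0, 1.0],
                           effect_alleles=["A", "T", "A"])  # v1 matches neither allele
        r = compute_prs(g, panel)
        assert (r.n_variants_used, r.n_skipped_absent, r.n_skipped_mismatch) == (1, 1, 1)

    def test_zero_overlap_is_error(self):
        g = make_geno(np.ones((2, 1)))
        with pytest.raises(ValueError, match="overlap"):
            compute_prs(g, make_panel("t", ["x"], [1.0]))

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.4, (7, 5)).astype(float)
        g = make_geno(d)
        ids = [f"v{j}" for j in range(5)]
        wa, wb = rng.normal(size=5), rng.normal(size=5)
        sa = compute_prs(g, make_panel("a", ids, wa)).scores
        sb = compute_prs(g, make_panel("b", ids, wb)).scores
        sab = compute_prs(g, make_panel("ab", ids, wa + wb)).scores
        np.testing.assert_allclose(sab, sa + sb, atol=1e-12)


class TestNormalize:
    def test_blom_formula_n5(self):
        x = np.array([3.0, -1.0, 7.0, 0.5, 2.0])
        out = normalize_scores(x)
        r = stats.rankdata(x)
        np.testing.assert_allclose(out, stats.norm.ppf((r - 0.375) / 5.25), atol=1e-12)

    def test_rank_preservation(self):
        x = np.random.default_rng(1).exponential(size=50)
        out = normalize_scores(x)
        assert stats.spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_normal_quantile_fixed_point(self):
        q = stats.norm.ppf((np.arange(1, 201) - 0.375) / 200.25)
        np.testing.assert_allclose(normalize_scores(q), q, atol=1e-12)

    def test_output_passes_normality_at_n500(self):
        x = np.random.default_rng(3).exponential(size=600)  # heavily skewed input
        out = normalize_scores(x)
        assert abs(out.mean()) < 0.05 and abs(out.std() - 1) < 0.05
        ad = stats.anderson(out, dist="norm", method="interpolate")
        assert ad.pvalue > 0.01

    def test_zscore_alternative(self):
        x = np.array([1.0, 2.0, 4.0])
        out = normalize_scores(x, method="zscore")
        assert out.mean() == pytest.approx(0) and out.std() == pytest.approx(1)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_scores(np.ones(10))


class TestGwas:
    def test_null_variant_beta_near_zero(self):
        rng = np.random.default_rng(0)
        g = make_geno(rng.binomial(2, 0.3, (4000, 1)).astype(float))
        y = rng.random(4000) < 0.3
        res = run_gwas(g, y).table
        assert abs(res["beta"][0]) < 3 * res["se"][0]

    def test_collapsed_two_by_two_closed_form(self):
        # dosages only 0/2: logistic slope per dosage = logOR/2,
        # se per dosage = sqrt(sum of reciprocal cells)/2
        d = np.r_[np.zeros(40), np.full(60, 2.0)]
        y = np.r_[np.repeat([0, 1], [30, 10]), np.repeat([0, 1], [35, 25])]
        res = run_gwas(make_geno(d[:, None]), y).table
        log_or = np.log((25 / 35) / (10 / 30))
        se = np.sqrt(1 / 25 + 1 / 35 + 1 / 10 + 1 / 30)
        assert 2 * res["beta"][0] == pytest.approx(log_or, abs=1e-6)
        assert 2 * res["se"][0] == pytest.approx(se, abs=1e-6)

    def test_recovers_generative_log_odds(self):
        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.3, 5000).astype(float)
        p = 1 / (1 + np.exp(-(-1.5 + 0.3 * x)))
        y = rng.random(5000) < p
        res = run_gwas(make_geno(x[:, None]), y).table
        assert abs(res["beta"][0] - 0.3) < 3 * res["se"][0]

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.35, (300, 5)).astype(float)
        y = (rng.random(300) < 0.4).astype(int)
        res = run_gwas(make_geno(d), y).table
        for j in range(5):
            sm_fit = sm.Logit(y, sm.add_constant(d[:, j])).fit(disp=0)
            assert res["beta"][j] == pytest.approx(sm_fit.params[1], abs=1e-6)
            assert res["se"][j] == pytest.approx(sm_fit.bse[1], abs=1e-6)
            assert res["p"][j] == pytest.approx(sm_fit.pvalues[1], abs=1e-6)

    def test_single_class_rejected(self):
        g = make_geno(np.ones((10, 1)))
        with pytest.raises(ValueError):
            run_gwas(g, np.ones(10))

    def test_separated_variant_flagged_with_score_p(self):
        # dosage perfectly predicts the phenotype
        d = np.r_[np.zeros(20), np.full(20, 2.0)]
        y = np.r_[np.zeros(20), np.ones(20)]
        res = run_gwas(make_geno(d[:, None]), y).table
        assert bool(res["flagged"][0])
        assert abs(res["beta"][0]) == 10.0
        assert 0 < res["p"][0] < 1e-6  # score test still yields strong evidence


def _result(betas, ses):
    m = len(betas)
    return GwasResult(pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "beta": betas, "se": ses, "p": np.full(m, 0.5), "flagged": False}))


class TestMeta:
    def test_identical_studies_shrink_se_by_sqrt_k(self):
        res = meta_analyze([_result([0.3], [0.1])] * 4)
        assert res.table["beta"][0] == pytest.approx(0.3)
        assert res.table["se"][0] == pytest.approx(0.05)

    def test_closed_form_two_studies(self):
        res = meta_analyze([_result([0.2], [0.1]), _result([0.4], [0.2])])
        assert res.table["beta"][0] == pytest.approx(0.24, abs=1e-12)
        assert res.table["se"][0] == pytest.approx(1 / np.sqrt(125), abs=1e-12)

    def test_infinite_se_study_has_zero_weight(self):
        res = meta_analyze([_result([0.2], [0.1]), _result([5.0], [np.inf])])
        assert res.table["beta"][0] == pytest.approx(0.2)
        assert res.table["se"][0] == pytest.approx(0.1)

    def test_precision_never_worse_than_best_study(self):
        rng = np.random.default_rng(2)
        studies = [_result(rng.normal(size=3), rng.uniform(0.05, 0.5, 3)) for _ in range(5)]
        res = meta_analyze(studies)
        best = np.min([s.table["se"].to_numpy() for s in studies], axis=0)
        assert (res.table["se"].to_numpy() <= best + 1e-12).all()

    def test_misaligned_variants_rejected(self):
        a = _result([0.1], [0.1])
        b = _result([0.1], [0.1])
        b.table["variant_id"] = ["other"]
        with pytest.raises(ValueError):
            meta_analyze([a, b])


class TestLogo:
    def _toy(self, seed=0, n=60, m=3):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        y = (rng.random(n) < 0.4).astype(int)
        return make_geno(d), y

    def test_two_fold_matches_hand_rolled_oracle(self):
        geno, y = self._toy(seed=3, n=40, m=3)
        seed = 17
        rsv = logo_prs(geno, y, k=2, seed=seed)
        # oracle: replicate the documented partition rule, fit each half's
        # per-variant logistic with statsmodels, score the other half
        groups = np.random.default_rng(seed).permutation(np.arange(40) % 2)
        expected = np.empty(40)
        for g in (0, 1):
            train = groups != g
            w = []
            for j in range(3):
                fit = sm.Logit(y[train], sm.add_constant(geno.dosages[train, j])).fit(disp=0)
                w.append(fit.params[1])
            expected[groups == g] = geno.dosages[groups == g] @ np.array(w)
        np.testing.assert_allclose(rsv.scores, expected, atol=1e-5)

    def test_held_out_labels_do_not_touch_held_out_scores(self):
        geno, y = self._toy(seed=5, n=120, m=6)
        rsv1, groups = logo_prs(geno, y, k=4, seed=2, return_groups=True)
        g = 1
        y2 = y.copy()
        idx = np.flatnonzero(groups == g)
        y2[idx] = np.random.default_rng(0).permutation(y2[idx])
        rsv2, groups2 = logo_prs(geno, y2, k=4, seed=2, return_groups=True)
        np.testing.assert_array_equal(groups, groups2)
        np.testing.assert_allclose(rsv1.scores[idx], rsv2.scores[idx], atol=1e-10)

    def test_null_phenotype_gives_uncorrelated_scores(self):
        rng = np.random.default_rng(12)
        n = 400
        geno = make_geno(rng.binomial(2, 0.3, (n, 30)).astype(float))
        y = (rng.random(n) < 0.5).astype(int)
        rsv = logo_prs(geno, y, k=5, seed=1)
        r = np.corrcoef(rsv.scores, y)[0, 1]
        assert abs(r) <= 3 / np.sqrt(n)

    def test_signal_recovered_without_leakage(self):
        # heritable phenotype: LOGO score positively associated out-of-fold
        hits = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            n, m = 1000, 20
            d = rng.binomial(2, 0.3, (n, m)).astype(float)
            eta = -0.5 + d[:, :10] @ np.full(10, 0.25)
            y = (rng.random(n) < 1 / (1 + np.exp(-(eta - eta.mean())))).astype(int)
            rsv = logo_prs(make_geno(d), y, k=5, seed=rep)
            z = (rsv.scores - rsv.scores.mean()) / rsv.scores.std()
            fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
            hits += fit.params[1] > 0
        assert hits >= 4

    def test_unsplittable_classes_reported(self):
        geno, y = self._toy(n=30)
        y[:] = 0
        y[0] = 1  # a single case cannot reach every group
        with pytest.raises(ValueError, match="group"):
            logo_prs(geno, y, k=3, seed=0)
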