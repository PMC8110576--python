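"""Cohort statistics: t-test, correlation, AUC/DeLong, APRI, Mayo risk score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mreh import (
    ClinicalRecord,
    SubjectStats,
    apri,
    auc_ci,
    build_cohort_table,
    mayo_risk_score,
    pearson_r,
    two_sided_t_test,
)


def brute_force_auc(pos, neg):
    """Exhaustive pair counting: wins + half-ties over all pairs."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _record(**kw):
    base = dict(
        age_years=45.0,
        ast_u_per_l=60.0,
        ast_uln_u_per_l=40.0,
        platelets_1e9_per_l=200.0,
        bilirubin_mg_per_dl=1.0,
        albumin_g_per_dl=4.0,
        variceal_bleeding=False,
        group_label="PSC",
    )
    base.update(kw)
    return ClinicalRecord(**base)


class TestTTest:
    def test_identical_groups(self):
        t, _, p = two_sided_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_degenerate_zero_variance_equal_means(self):
        t, _, p = two_sided_t_test([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_extreme_separation(self):
        a = [1.0, 2.0, 3.0]
        b = [11.001, 12.0, 12.999]
        _, _, p = two_sided_t_test(a, b)
        assert p < 0.001

    def test_welch_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(21, 5, 20)
        b = rng.normal(19, 4, 26)
        _, _, p_welch = two_sided_t_test(a, b)

        # vectorized permutation of the Welch statistic, 1e5 shuffles
        n_perm = 100_000
        allv = np.concatenate([a, b])
        na = len(a)
        prng = np.random.default_rng(0)
        idx = np.argsort(prng.random((n_perm, allv.size)), axis=1)
        perm = allv[idx]
        ga, gb = perm[:, :na], perm[:, na:]

        def welch_t(x, y):
            vx = x.var(axis=1, ddof=1) / x.shape[1]
            vy = y.var(axis=1, ddof=1) / y.shape[1]
            return (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(vx + vy)

        t_obs = abs(welch_t(a[None], b[None])[0])
        p_perm = (np.sum(np.abs(welch_t(ga, gb)) >= t_obs) + 1) / (n_perm + 1)
        assert p_welch == pytest.approx(p_perm, abs=0.01)

    def test_invariance_under_shift_and_scale(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1.2, 15)
        _, _, p0 = two_sided_t_test(a, b)
        _, _, p1 = two_sided_t_test(3.5 * a + 7, 3.5 * b + 7)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sided_t_test([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        r, _ = pearson_r(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAucCi:
    def test_perfect_separation(self):
        auc, lo, hi = auc_ci([3.0, 4.0, 5.0], [1.0, 2.0, 2.5])
        assert auc == 1.0 and lo <= auc <= hi

    def test_identical_scores_all_ties(self):
        auc, _, _ = auc_ci([2.0, 2.0], [2.0, 2.0, 2.0])
        assert auc == 0.5

    def test_small_example_exhaustive_pairs(self):
        pos, neg = [1.0, 2.0, 3.0], [0.5, 2.0, 3.5]
        auc, _, _ = auc_ci(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 10), min_size=1, max_size=12),
        neg=st.lists(st.integers(0, 10), min_size=1, max_size=12),
    )
    def test_auc_equals_pair_counting_everywhere(self, pos, neg):
        # integers force ties; the midrank identity must hold exactly
        pos = [float(x) for x in pos]
        neg = [float(x) for x in neg]
        auc, lo, hi = auc_ci(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        assert 0.0 <= lo <= hi <= 1.0

    def test_delong_ci_matches_independent_reference(self):
        # frozen reference interval computed with R pROC::ci.auc (DeLong)
        pos = [22.52, 15.8, 24.75, 25.7, 11.24, 14.49, 21.64, 19.42, 20.92, 16.73, 25.4, 24.89]
        neg = [18.2, 21.38, 19.4, 15.42, 19.11, 15.12, 20.64, 17.85, 17.45, 15.96, 21.67,
               17.54, 16.72, 16.94, 19.6]
        auc, lo, hi = auc_ci(pos, neg)
        assert auc == pytest.approx(0.6611, abs=1e-4)
        assert lo == pytest.approx(0.4131, abs=1e-3)
        assert hi == pytest.approx(0.9091, abs=1e-3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc_ci([], [1.0])


class TestApri:
    def test_band_edges(self):
        # AST at ULN with platelets 200e9/L sits exactly on the 0.5 edge
        score, cat = apri(_record(ast_u_per_l=40.0, platelets_1e9_per_l=200.0))
        assert score == pytest.approx(0.5)
        assert cat == "cirrhosis unlikely"

    def test_cirrhosis_band(self):
        score, cat = apri(_record(ast_u_per_l=120.0, platelets_1e9_per_l=100.0))
        assert score == pytest.approx(3.0)
        assert cat == "cirrhosis"

    @pytest.mark.parametrize(
        "score,category",
        [
            (0.49, "absence of significant fibrosis"),
            (0.99, "cirrhosis unlikely"),
            (1.0, "no reliable assessment"),
            (1.49, "no reliable assessment"),
            (1.5, "presence of significant fibrosis"),
            (2.0, "presence of significant fibrosis"),
            (2.01, "cirrhosis"),
        ],
    )
    def test_band_assignment(self, score, category):
        # choose platelets so that the score lands exactly on the target
        rec = _record(ast_u_per_l=40.0, platelets_1e9_per_l=100.0 / score)
        got_score, got_cat = apri(rec)
        assert got_score == pytest.approx(score, rel=1e-9)
        assert got_cat == category

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            ast = float(rng.uniform(20, 300))
            plate = float(rng.uniform(50, 400))
            rec = _record(ast_u_per_l=ast, platelets_1e9_per_l=plate)
            score, _ = apri(rec)
            assert score == pytest.approx(100.0 * (ast / 40.0) / plate, rel=1e-12)


class TestMayoRiskScore:
    def test_formula_worked_example(self):
        rec = _record(age_years=35.0, bilirubin_mg_per_dl=1.0, ast_u_per_l=60.0,
                      albumin_g_per_dl=4.0, variceal_bleeding=False)
        score, group = mayo_risk_score(rec)
        expected = 0.0295 * 35 + 0.5373 * math.log(1.0) + 0.5380 * math.log(60.0) \
            - 0.8389 * 4.0
        assert score == pytest.approx(expected, rel=1e-12)
        assert score < 0 and group == "low risk"

    def test_variceal_bleeding_adds_fixed_risk(self):
        s0, _ = mayo_risk_score(_record())
        s1, _ = mayo_risk_score(_record(variceal_bleeding=True))
        assert s1 - s0 == pytest.approx(1.2426, rel=1e-12)

    def test_risk_groups(self):
        # engineer scores on each side of the 0 and 2 breakpoints via age
        def score_for(age):
            return mayo_risk_score(_record(age_years=age))

        low = score_for(20.0)
        assert low[0] <= 0 and low[1] == "low risk"
        mid = score_for(60.0)
        assert 0 < mid[0] <= 2 and mid[1] == "intermediate risk"
        high = score_for(130.0)
        assert high[0] > 2 and high[1] == "high risk"

    def test_nonpositive_labs_rejected(self):
        with pytest.raises(ValueError):
            _record(bilirubin_mg_per_dl=0.0)


def _subject(sws_mean, sws_cv, phi_cv=40.0, group="PSC"):
    sd = sws_mean * sws_cv / 100.0
    return (
        SubjectStats(
            sws_mean_mps=sws_mean,
            sws_sd_mps=sd,
            sws_cv_percent=sws_cv,
            phi_mean_rad=0.5,
            phi_sd_rad=0.5 * phi_cv / 100,
            phi_cv_percent=phi_cv,
            fibrosis_stage=2,
            voi_volume_cm3=560.0,
        ),
        _record(group_label=group),
    )


class TestBuildCohortTable:
    def _cohort(self, psc_cvs, viral_cvs):
        pairs = [_subject(1.7, cv, group="PSC") for cv in psc_cvs] + [
            _subject(1.84, cv, group="viral") for cv in viral_cvs
        ]
        stats = [p[0] for p in pairs]
        recs = [p[1] for p in pairs]
        return build_cohort_table(stats, recs)

    def test_summary_schema_matches_report_layout(self):
        res = self._cohort([20.0, 22.0], [17.0, 19.0])
        assert list(res.summary["metric"]) == [
            "SWS (m/s)",
            "SD of SWS (m/s)",
            "CV of SWS (%)",
            "phi (rad)",
            "SD of phi (rad)",
            "CV of phi (%)",
            "Fibrosis stage",
        ]
        for col in ("all_mean", "all_sd", "PSC_mean", "PSC_sd", "viral_mean", "viral_sd"):
            assert col in res.summary.columns

    def test_group_cv_is_mean_of_subject_cvs(self):
        # subjects with very different means: the mean-of-CVs and the
        # ratio-of-group-summaries disagree, pinning the aggregation order
        pairs = [_subject(1.2, 10.0, group="PSC"), _subject(2.8, 30.0, group="PSC"),
                 _subject(1.8, 18.0, group="viral"), _subject(1.9, 18.0, group="viral")]
        res = build_cohort_table([p[0] for p in pairs], [p[1] for p in pairs])
        row = res.summary[res.summary["metric"] == "CV of SWS (%)"].iloc[0]
        assert row["PSC_mean"] == pytest.approx(20.0)  # mean of 10 and 30
        sws_row = res.summary[res.summary["metric"] == "SWS (m/s)"].iloc[0]
        sd_row = res.summary[res.summary["metric"] == "SD of SWS (m/s)"].iloc[0]
        ratio = 100 * sd_row["PSC_mean"] / sws_row["PSC_mean"]
        assert abs(ratio - 20.0) > 1.0  # the wrong aggregation differs clearly

    def test_disjoint_cv_distributions_give_auc_one(self):
        res = self._cohort([25.0, 26.0, 27.0], [15.0, 16.0, 17.0])
        auc_sws = res.auc[res.auc["metric"] == "CV of SWS (%)"]["auc"].iloc[0]
        assert auc_sws == 1.0

    def test_identical_groups_give_auc_half(self):
        res = self._cohort([18.0, 20.0, 22.0], [18.0, 20.0, 22.0])
        auc_sws = res.auc[res.auc["metric"] == "CV of SWS (%)"]["auc"].iloc[0]
        assert auc_sws == pytest.approx(0.5)

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError):
            self._cohort([20.0], [17.0, 18.0])
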