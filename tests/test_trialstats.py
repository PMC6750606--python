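"""Genotype-stratified treatment-effect statistics against textbook oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omega3cmr import trialstats as ts
from omega3cmr.exceptions import DegenerateDataError, DomainError, InsufficientDataError


def cohort_frame(rows):
    """Minimal cohort frame from (genotype, arm, baseline, followup) LVESVi rows."""
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(rows))],
            "genotype": [r[0] for r in rows],
            "arm": [r[1] for r in rows],
            "lvesvi_baseline": [r[2] for r in rows],
            "lvesvi_6mo": [r[3] for r in rows],
        }
    )


def welch_oracle(a, b):
    """Independently coded Welch t-test (textbook formula)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestChangeScore:
    def test_followup_minus_baseline(self):
        df = cohort_frame([("AA", "drug", 40.0, 36.0), ("AA", "drug", 30.0, 30.0)])
        out = ts.change_score(df, "lvesvi")
        assert list(out) == [-4.0, 0.0]

    def test_missing_rows_excluded(self):
        df = cohort_frame([("AA", "drug", 40.0, 36.0), ("AA", "drug", np.nan, 30.0)])
        assert len(ts.change_score(df, "lvesvi")) == 1

    def test_columnwise_equals_row_loop(self, rng):
        base = rng.uniform(20, 60, 25)
        follow = base + rng.normal(0, 5, 25)
        df = cohort_frame([("AA", "drug", b, f) for b, f in zip(base, follow)])
        out = ts.change_score(df, "lvesvi").to_numpy()
        oracle = np.array([f - b for b, f in zip(base, follow)])
        assert np.allclose(out, oracle)

    def test_log_scale_changes(self):
        df = pd.DataFrame(
            {"ntprobnp_baseline": [100.0, 200.0], "ntprobnp_6mo": [50.0, 400.0]}
        )
        out = ts.change_score(df, "ntprobnp", log_transform=True)
        assert np.allclose(out, [math.log(0.5), math.log(2.0)])


class TestStratifiedEffect:
    def _frame(self, drug_changes, placebo_changes, genotype="GG"):
        rows = [(genotype, "drug", 40.0, 40.0 + d) for d in drug_changes]
        rows += [(genotype, "placebo", 40.0, 40.0 + d) for d in placebo_changes]
        return cohort_frame(rows)

    def test_identical_arms_give_p_one(self):
        df = self._frame([-5, -4, -3, -2], [-5, -4, -3, -2])
        eff = ts.stratified_effect(df, "lvesvi", "GG")
        assert eff.p_value == pytest.approx(1.0)
        assert eff.mean_change_drug == eff.mean_change_placebo

    def test_matches_welch_oracle(self):
        drug, placebo = [-5.0, -4.0, -3.0], [1.0, 2.0, 3.0]
        eff = ts.stratified_effect(self._frame(drug, placebo), "lvesvi", "GG")
        assert eff.p_value == pytest.approx(welch_oracle(drug, placebo), rel=1e-10)
        assert eff.mean_change_drug == pytest.approx(-4.0)
        assert eff.sd_drug == pytest.approx(1.0)
        assert (eff.n_drug, eff.n_placebo) == (3, 3)

    def test_pooled_flavor_matches_scipy_student(self, rng):
        drug = list(rng.normal(-4, 5, 12))
        placebo = list(rng.normal(1, 4, 15))
        eff = ts.stratified_effect(self._frame(drug, placebo), "lvesvi", "GG",
                                   ttest="pooled")
        ref = stats.ttest_ind(drug, placebo, equal_var=True).pvalue
        assert eff.p_value == pytest.approx(ref, rel=1e-12)

    def test_location_shift_moves_difference_exactly(self, rng):
        drug = list(rng.normal(-4, 5, 10))
        placebo = list(rng.normal(1, 4, 10))
        e0 = ts.stratified_effect(self._frame(drug, placebo), "lvesvi", "GG")
        shifted = [p + 2.5 for p in placebo]
        e1 = ts.stratified_effect(self._frame(drug, shifted), "lvesvi", "GG")
        d0 = e0.mean_change_drug - e0.mean_change_placebo
        d1 = e1.mean_change_drug - e1.mean_change_placebo
        assert d1 == pytest.approx(d0 - 2.5, abs=1e-10)

    def test_monte_carlo_recovery_of_stratum_means(self):
        """GG stratum at n=2000/arm reproduces generator means -4.4 vs 1.2."""
        rng = np.random.default_rng(99)
        drug = rng.normal(-4.4, 5.6, 2000)
        placebo = rng.normal(1.2, 4.1, 2000)
        eff = ts.stratified_effect(self._frame(list(drug), list(placebo)),
                                   "lvesvi", "GG")
        assert eff.mean_change_drug == pytest.approx(-4.4, abs=3 * 5.6 / math.sqrt(2000))
        assert eff.mean_change_placebo == pytest.approx(1.2, abs=3 * 4.1 / math.sqrt(2000))

    def test_empty_stratum_rejected(self):
        df = self._frame([-5, -4], [1, 2], genotype="AA")
        with pytest.raises(InsufficientDataError):
            ts.stratified_effect(df, "lvesvi", "GG")


class TestResponderOdds:
    def _frame_from_counts(self, rd, nd, rp, np_):
        rows = []
        rows += [("GG", "drug", 40.0, 30.0)] * rd       # 25% improvement
        rows += [("GG", "drug", 40.0, 39.0)] * nd       # 2.5% improvement
        rows += [("GG", "placebo", 40.0, 30.0)] * rp
        rows += [("GG", "placebo", 40.0, 39.0)] * np_
        return cohort_frame(rows)

    def test_printed_odds_arithmetic(self):
        assert ts.odds_ratio(0.60, 0.083) == pytest.approx(7.2, abs=0.05)

    def test_equal_odds_give_unit_ratio(self):
        res = ts.responder_odds(self._frame_from_counts(3, 6, 2, 4))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_matches_contingency_enumeration(self, rng):
        rd, nd, rp, np_ = 7, 13, 3, 17
        df = self._frame_from_counts(rd, nd, rp, np_)
        res = ts.responder_odds(df)
        assert (res.n_responders_drug, res.n_nonresponders_drug) == (rd, nd)
        assert res.odds_ratio == pytest.approx((rd / nd) / (rp / np_), rel=1e-12)

    def test_order_invariance_and_arm_swap_inverts(self):
        df = self._frame_from_counts(7, 13, 3, 17)
        shuffled = df.sample(frac=1.0, random_state=3)
        assert ts.responder_odds(shuffled).odds_ratio == pytest.approx(
            ts.responder_odds(df).odds_ratio
        )
        swapped = df.assign(arm=df["arm"].map({"drug": "placebo", "placebo": "drug"}))
        assert ts.responder_odds(swapped).odds_ratio == pytest.approx(
            1.0 / ts.responder_odds(df).odds_ratio
        )

    def test_zero_cell_flagged_infinite(self):
        res = ts.responder_odds(self._frame_from_counts(5, 0, 3, 7))
        assert res.infinite
        assert math.isinf(res.odds_ratio)

    def test_haldane_correction_finite(self):
        res = ts.responder_odds(self._frame_from_counts(5, 0, 3, 7),
                                haldane_correction=True)
        assert res.odds_drug == pytest.approx(5.5 / 0.5)
        assert math.isfinite(res.odds_ratio)

    def test_relative_definition_uses_baseline_fraction(self):
        # 10% of baseline 50 is 5 mL/m^2: a 4-unit improvement is not a response
        df = cohort_frame(
            [("GG", "drug", 50.0, 46.0), ("GG", "drug", 50.0, 44.0),
             ("GG", "placebo", 50.0, 46.0), ("GG", "placebo", 50.0, 44.0)]
        )
        res = ts.responder_odds(df)
        assert res.n_responders_drug == 1
        assert res.n_nonresponders_drug == 1


class TestDeltaCorrelation:
    def _frame(self, d_fat, d_lvesvi):
        n = len(d_fat)
        return pd.DataFrame(
            {
                "epa_baseline": np.full(n, 1.5),
                "epa_6mo": 1.5 + np.asarray(d_fat, float),
                "lvesvi_baseline": np.full(n, 40.0),
                "lvesvi_6mo": 40.0 + np.asarray(d_lvesvi, float),
            }
        )

    def test_perfect_inverse_monotone(self):
        df = self._frame([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert ts.delta_correlation(df, "epa").rho == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        df = self._frame(rng.normal(0, 1, 4000), rng.normal(0, 1, 4000))
        assert abs(ts.delta_correlation(df, "epa").rho) < 0.05

    def test_matches_midrank_pearson_oracle(self):
        d_fat = [0.5, 1.2, 1.2, 2.0, 0.1, 3.3, 2.0, 0.9, 1.5, 2.7]
        d_lv = [1.0, -2.0, 0.0, -3.0, 2.0, -4.0, -3.0, 0.5, -1.0, -2.5]
        res = ts.delta_correlation(self._frame(d_fat, d_lv), "epa")
        ranks_x = stats.rankdata(d_fat)  # midranks for ties
        ranks_y = stats.rankdata(d_lv)
        oracle = np.corrcoef(ranks_x, ranks_y)[0, 1]
        assert res.rho == pytest.approx(oracle, rel=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        d_fat = rng.normal(1, 0.5, 50)
        d_lv = rng.normal(-2, 3, 50)
        base = ts.delta_correlation(self._frame(d_fat, d_lv), "epa").rho
        transformed = ts.delta_correlation(
            self._frame(np.exp(d_fat), d_lv), "epa"
        ).rho
        assert transformed == pytest.approx(base, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            ts.delta_correlation(self._frame([1, 1, 1, 1], [1, 2, 3, 4]), "epa")

    def test_unknown_fatty_acid_rejected(self):
        with pytest.raises(DomainError):
            ts.delta_correlation(self._frame([1, 2, 3], [1, 2, 3]), "ala")


class TestBaselineComparison:
    def test_identical_groups_f_zero(self):
        df = pd.DataFrame(
            {
                "genotype": ["AA"] * 4 + ["AG"] * 4 + ["GG"] * 4,
                "age": [50, 60, 70, 80] * 3,
            }
        )
        res = ts.baseline_comparison(df, "age", "continuous")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_balanced_contingency_chi2_zero(self):
        df = pd.DataFrame(
            {
                "genotype": ["AA"] * 20 + ["AG"] * 20 + ["GG"] * 20,
                "sex": (["F"] * 10 + ["M"] * 10) * 3,
            }
        )
        res = ts.baseline_comparison(df, "sex", "categorical")
        assert res.statistic == pytest.approx(0.0)

    def test_matches_anova_decomposition_oracle(self):
        groups = {"AA": [1.0, 2.0, 3.0], "AG": [2.0, 4.0, 6.0], "GG": [5.0, 6.0, 10.0]}
        df = pd.DataFrame(
            {
                "genotype": sum(([g] * len(v) for g, v in groups.items()), []),
                "bmi": sum((v for v in groups.values()), []),
            }
        )
        res = ts.baseline_comparison(df, "bmi", "continuous")
        # oracle: between/within sums of squares by hand
        all_vals = np.concatenate([np.array(v) for v in groups.values()])
        grand = all_vals.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f = (ss_between / 2) / (ss_within / (len(all_vals) - 3))
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.p_value == pytest.approx(stats.f.sf(f, 2, len(all_vals) - 3), rel=1e-10)


class TestPairedVisitTest:
    def test_uniform_increase_is_highly_significant(self, rng):
        base = rng.uniform(1, 5, 20)
        assert ts.paired_visit_test(base, base + rng.uniform(1, 2, 20)) < 0.001

    def test_bonferroni_cap_at_one(self, rng):
        base = rng.normal(0, 1, 10)
        follow = base + rng.normal(0, 1, 10)
        assert ts.paired_visit_test(base, follow, n_comparisons=10**6) == 1.0

    def test_bonferroni_multiplies_raw_p(self, rng):
        base = rng.normal(0, 1, 12)
        follow = base + rng.normal(0.5, 1, 12)
        p1 = ts.paired_visit_test(base, follow, 1)
        p3 = ts.paired_visit_test(base, follow, 3)
        assert p3 == pytest.approx(min(1.0, 3 * p1))

    def test_matches_exact_enumeration_at_n8(self):
        """Signed-rank p equals enumeration over all 2^8 sign assignments."""
        base = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0, 8.0, 15.0])
        follow = base + np.array([1.5, -0.7, 2.3, 0.4, -1.1, 3.2, 0.9, -2.6])
        diffs = follow - base
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=8)
        ]
        ws = np.array(ws)
        p_exact = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        assert ts.paired_visit_test(base, follow) == pytest.approx(p_exact, rel=1e-12)

    def test_all_zero_differences_rejected(self):
        v = np.arange(1.0, 9.0)
        with pytest.raises(DegenerateDataError):
            ts.paired_visit_test(v, v)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            ts.paired_visit_test([1, 2, 3], [2, 3, 4])


class TestSubgroupFilterAndMedianSplit:
    def test_filter_keeps_matching_records(self):
        df = cohort_frame([("AA", "drug", 40, 38)] * 3).assign(
            race=["Caucasian", "Black", "Caucasian"]
        )
        out = ts.subgroup_filter(df)
        assert len(out) == 2
        assert set(out["race"]) == {"Caucasian"}

    def test_absent_category_warns(self):
        df = cohort_frame([("AA", "drug", 40, 38)]).assign(race=["Black"])
        with pytest.warns(UserWarning):
            out = ts.subgroup_filter(df, "Asian")
        assert out.empty

    def test_filter_composes_with_stratified_effect(self, small_cohort):
        df, _ = small_cohort
        filtered = ts.subgroup_filter(df, "Caucasian")
        eff = ts.stratified_effect(filtered, "lvesvi", "AA")
        oracle = ts.stratified_effect(df[df["race"] == "Caucasian"], "lvesvi", "AA")
        assert eff == oracle

    def test_median_split_basic(self):
        assert list(ts.median_split([1, 2, 3, 4])) == ["low", "low", "high", "high"]

    def test_median_ties_go_low(self):
        assert list(ts.median_split([1, 2, 2, 3])) == ["low", "low", "low", "high"]

    def test_group_size_imbalance_bounded_by_ties(self, rng):
        v = rng.integers(0, 10, 101).astype(float)
        labels = ts.median_split(v)
        n_ties = int((v == np.median(v)).sum())
        assert abs((labels == "low").sum() - (labels == "high").sum()) <= n_ties + 1

    def test_degenerate_split_warns(self):
        with pytest.warns(UserWarning):
            ts.median_split([2.0, 2.0, 2.0])


class TestBiomarkerRegression:
    def _frame(self, x, y):
        return pd.DataFrame({"ntprobnp_baseline": x, "lvesvi_baseline": y})

    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ts.biomarker_cmr_regression(
            self._frame(x, 2 * x + 1), "ntprobnp_baseline", "lvesvi_baseline"
        )
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDataError):
            ts.biomarker_cmr_regression(
                self._frame([2.0] * 5, [1, 2, 3, 4, 5]),
                "ntprobnp_baseline",
                "lvesvi_baseline",
            )

    def test_matches_closed_form_slope(self, rng):
        x = rng.uniform(100, 1000, 30)
        y = 0.01 * x + rng.normal(0, 2, 30)
        res = ts.biomarker_cmr_regression(
            self._frame(x, y), "ntprobnp_baseline", "lvesvi_baseline"
        )
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert res.slope == pytest.approx(slope, rel=1e-12)

    def test_log_transform_drops_nonpositive(self):
        x = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        y = np.array([9.9, 1.0, 2.0, 3.0, 4.0])
        res = ts.biomarker_cmr_regression(
            self._frame(x, y), "ntprobnp_baseline", "lvesvi_baseline",
            log_biomarker=True,
        )
        assert res.n == 4
        assert res.slope == pytest.approx(1.0 / math.log(2.0), rel=1e-10)
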