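"""Repeated-measures / mixed ANOVA engines, Fisher's LSD, assumption checks.

The sums-of-squares decompositions are verified against (a) a hand-coded
independent decomposition written directly in the tests and (b) pingouin's
implementations as an external oracle.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from cortifract.errors import DegenerateSignalError, ParameterError
from cortifract.group_stats import (
    assumption_checks,
    fisher_lsd,
    mixed_anova_twoway,
    rm_anova_oneway,
)


def tidy_from_wide(y, groups=None):
    n, c = y.shape
    rows = []
    for i in range(n):
        for j in range(c):
            row = {"subject": f"s{i}", "condition": f"c{j}", "value": y[i, j]}
            if groups is not None:
                row["group"] = groups[i]
            rows.append(row)
    return pd.DataFrame(rows)


# 5 subjects x 3 conditions, a classic within-subject layout
TEXTBOOK = np.array(
    [
        [8.0, 7.0, 1.0],
        [9.0, 5.0, 2.0],
        [6.0, 2.0, 3.0],
        [5.0, 3.0, 1.0],
        [7.0, 3.0, 3.0],
    ]
)


class TestOneWayRM:
    def test_textbook_table_matches_hand_decomposition(self):
        res = rm_anova_oneway(tidy_from_wide(TEXTBOOK))
        y = TEXTBOOK
        n, c = y.shape
        grand = y.mean()
        ss_cond = n * ((y.mean(0) - grand) ** 2).sum()
        ss_subj = c * ((y.mean(1) - grand) ** 2).sum()
        ss_err = ((y - grand) ** 2).sum() - ss_cond - ss_subj
        f_hand = (ss_cond / (c - 1)) / (ss_err / ((c - 1) * (n - 1)))
        assert res.F == pytest.approx(f_hand, abs=1e-8)
        assert (res.df_num, res.df_den) == (2, 8)
        assert res.p == pytest.approx(stats.f.sf(f_hand, 2, 8), abs=1e-12)

    def test_matches_pingouin(self, rng):
        y = rng.normal(size=(7, 4)) + rng.normal(size=(7, 1))
        res = rm_anova_oneway(tidy_from_wide(y))
        oracle = pg.rm_anova(
            data=tidy_from_wide(y), dv="value", within="condition", subject="subject"
        )
        assert res.F == pytest.approx(float(oracle["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(oracle["p_unc"].iloc[0]), rel=1e-9)

    def test_two_conditions_reproduce_paired_t(self, rng):
        y = rng.normal(size=(9, 2))
        res = rm_anova_oneway(tidy_from_wide(y))
        t, p = stats.ttest_rel(y[:, 0], y[:, 1])
        assert res.F == pytest.approx(t**2, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_identical_conditions_give_f_zero(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.column_stack([col, col, col])
        res = rm_anova_oneway(tidy_from_wide(y))
        assert res.F == 0.0
        assert res.p == 1.0

    def test_missing_cell_rejected(self):
        table = tidy_from_wide(TEXTBOOK).drop(index=3)
        with pytest.raises(ParameterError, match="incomplete"):
            rm_anova_oneway(table)

    def test_f_invariant_to_affine_transform(self, rng):
        y = rng.normal(size=(6, 3))
        f0 = rm_anova_oneway(tidy_from_wide(y)).F
        f1 = rm_anova_oneway(tidy_from_wide(3.2 * y + 17.0)).F
        assert f1 == pytest.approx(f0, rel=1e-10)

    def test_null_rejection_rate_quick(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            y = rng.normal(size=(6, 3))
            hits += rm_anova_oneway(tidy_from_wide(y)).p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)


class TestMixedTwoWay:
    @staticmethod
    def study_table(rng, group_shift=0.0, treat_shift=0.0, inter_shift=0.0):
        groups = ["pd"] * 8 + ["control"] * 7
        y = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
        y[:8] += group_shift
        y[:, 1] += treat_shift
        y[:8, 1] += inter_shift
        return tidy_from_wide(y, groups)

    def test_group_df_matches_study_shape(self, rng):
        results = mixed_anova_twoway(self.study_table(rng))
        by_name = {r.effect_name: r for r in results}
        assert (by_name["group"].df_num, by_name["group"].df_den) == (1, 13)
        assert (by_name["treatment"].df_num, by_name["treatment"].df_den) == (1, 13)
        assert (by_name["interaction"].df_num, by_name["interaction"].df_den) == (1, 13)

    def test_matches_pingouin(self, rng):
        table = self.study_table(rng, group_shift=0.8, inter_shift=0.5)
        results = {r.effect_name: r for r in mixed_anova_twoway(table)}
        oracle = pg.mixed_anova(
            data=table, dv="value", within="condition", subject="subject",
            between="group",
        ).set_index("Source")
        for mine, theirs in (
            ("group", "group"),
            ("treatment", "condition"),
            ("interaction", "Interaction"),
        ):
            assert results[mine].F == pytest.approx(
                float(oracle.loc[theirs, "F"]), rel=1e-9
            ), mine
            assert results[mine].p == pytest.approx(
                float(oracle.loc[theirs, "p_unc"]), rel=1e-9
            ), mine

    def test_shuffled_groups_rarely_significant_under_pure_treatment_effect(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            table = self.study_table(rng, treat_shift=2.0)  # no group effect
            res = {r.effect_name: r for r in mixed_anova_twoway(table)}
            hits += res["group"].p < 0.05
        assert hits / reps <= 0.10

    def test_zero_variance_rejected(self):
        groups = ["pd"] * 3 + ["control"] * 3
        y = np.ones((6, 2))
        with pytest.raises(DegenerateSignalError):
            mixed_anova_twoway(tidy_from_wide(y, groups))

    def test_subject_in_two_groups_rejected(self, rng):
        table = self.study_table(rng)
        table.loc[table["subject"] == "s0", "group"] = ["pd", "control"]
        with pytest.raises(ParameterError, match="exactly one group"):
            mixed_anova_twoway(table)


class TestFisherLSD:
    def test_two_condition_lsd_equals_paired_t(self, rng):
        y = rng.normal(size=(8, 2))
        table = tidy_from_wide(y)
        anova = rm_anova_oneway(table)
        lsd = fisher_lsd(table, anova, ("c0", "c1"))
        t, p = stats.ttest_rel(y[:, 0], y[:, 1])
        assert lsd.t == pytest.approx(t, abs=1e-10)
        assert lsd.p == pytest.approx(p, abs=1e-10)
        assert lsd.mean_diff == pytest.approx(y[:, 0].mean() - y[:, 1].mean())

    def test_identical_means_give_p_one(self):
        y = np.array([[1.0, 1.0], [2.0, 2.0], [3.5, 3.5], [0.0, 0.0]])
        y[:, 1] += 1e-15
        table = tidy_from_wide(np.column_stack([y[:, 0], y[:, 0], y[:, 1]]))
        anova = rm_anova_oneway(table)
        lsd = fisher_lsd(table, anova, ("c0", "c1"))
        assert lsd.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert lsd.p > 0.999

    def test_large_effect_detected_reliably(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            y = rng.normal(size=(8, 3))
            y[:, 1] += 3.0  # 3 SD shift
            table = tidy_from_wide(y)
            lsd = fisher_lsd(table, rm_anova_oneway(table), ("c0", "c1"))
            hits += lsd.p < 0.001
        # exact power of this design is ~0.94 (noncentral t, ncp = 6, df = 14)
        assert hits >= 88

    def test_unknown_level_rejected(self, rng):
        table = tidy_from_wide(rng.normal(size=(5, 3)))
        anova = rm_anova_oneway(table)
        with pytest.raises(ParameterError, match="not present"):
            fisher_lsd(table, anova, ("c0", "nope"))

    def test_between_group_comparison_uses_between_error(self, rng):
        groups = ["pd"] * 8 + ["control"] * 7
        y = rng.normal(size=(15, 2))
        y[:8] += 1.5
        table = tidy_from_wide(y, groups)
        res = {r.effect_name: r for r in mixed_anova_twoway(table)}
        lsd = fisher_lsd(table, res["group"], ("pd", "control"))
        # with g = 2 groups the LSD t-test is exactly the group F test
        assert lsd.t**2 == pytest.approx(res["group"].F, rel=1e-9)
        assert lsd.df == 13
        assert lsd.mean_diff > 0


class TestAssumptionChecks:
    def test_gaussian_cells_pass(self, rng):
        y = rng.normal(size=(20, 3))
        report = assumption_checks(tidy_from_wide(y))
        assert set(report.shapiro_p) == {"c0", "c1", "c2"}
        assert 0 <= report.levene_p <= 1

    def test_calibrated_rejection_rates(self, rng):
        sh = lev = 0
        reps = 300
        for _ in range(reps):
            y = rng.normal(size=(10, 2))
            rep = assumption_checks(tidy_from_wide(y))
            sh += min(rep.shapiro_p.values()) <= 0.05  # 2 cells, familywise
            lev += rep.levene_p <= 0.05
        # per-test level ~5%: familywise over 2 cells <= ~10%
        assert sh / reps < 0.2
        assert lev / reps == pytest.approx(0.05, abs=0.04)

    def test_constant_cell_rejected(self):
        y = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateSignalError, match="constant"):
            assumption_checks(tidy_from_wide(y))

    def test_too_few_observations_rejected(self):
        y = np.random.default_rng(0).normal(size=(2, 2))
        with pytest.raises(ParameterError, match="fewer than 3"):
            assumption_checks(tidy_from_wide(y))

    def test_skewed_data_warns_but_returns(self, rng):
        y = rng.exponential(size=(40, 2)) ** 3
        report = assumption_checks(tidy_from_wide(y))
        assert report.warnings  # flagged, not raised
        assert not report.all_met
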