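"""Analysis pipeline: summaries, contrasts, mixed ANOVA, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stairtask import (
    GroupSummary,
    MixedAnova,
    bonferroni_adjust,
    manipulation_check_summary,
    marginal_mean_difference,
    mixed_anova,
    posthoc_mean_difference,
    summarize_cohort,
)

from conftest import TABLE2_MEANS, simulated_wide_frame


def brute_force_mixed_ss(df):
    """Independent sums-of-squares oracle: direct cell-mean decomposition of
    the balanced two-way (group x time) layout with subjects nested in group."""
    long = []
    for _, row in df.iterrows():
        long.append((row["condition"], row["participant_id"], 1, row["accuracy_block1"]))
        long.append((row["condition"], row["participant_id"], 2, row["accuracy_block2"]))
    L = pd.DataFrame(long, columns=["g", "s", "t", "y"])
    grand = L["y"].mean()
    n_subj = L["s"].nunique()
    T = 2
    subj_means = L.groupby("s")["y"].mean()
    group_means = L.groupby("g")["y"].mean()
    time_means = L.groupby("t")["y"].mean()
    cell_means = L.groupby(["g", "t"])["y"].mean()
    subj_group = L.drop_duplicates("s").set_index("s")["g"]
    counts = L.groupby("g")["s"].nunique()

    ss_time = float(sum(n_subj * (m - grand) ** 2 for m in time_means))
    ss_group = float(T * sum(counts[g] * (m - grand) ** 2 for g, m in group_means.items()))
    ss_inter = float(sum(
        counts[g] * (cell_means[(g, t)] - group_means[g] - time_means[t] + grand) ** 2
        for g, t in cell_means.index))
    ss_between_err = float(T * sum(
        (subj_means[s] - group_means[subj_group[s]]) ** 2 for s in subj_means.index))
    ss_total = float(((L["y"] - grand) ** 2).sum())
    ss_within_err = ss_total - ss_time - ss_group - ss_inter - ss_between_err
    return {
        "time": ss_time, "condition": ss_group, "time:condition": ss_inter,
        "between_error": ss_between_err, "within_error": ss_within_err,
    }


class TestGroupSummary:
    def test_two_value_hand_arithmetic(self):
        df = pd.DataFrame({
            "condition": ["a", "a"],
            "accuracy_block1": [10.0, 30.0],
            "accuracy_block2": [50.0, 50.0],
        })
        s = GroupSummary.from_participants(df)
        row = s.table[(s.table.condition == "a") & (s.table.block == "block1")].iloc[0]
        assert row["mean"] == pytest.approx(20.0)
        assert row["sd"] == pytest.approx(14.1421356, abs=1e-4)
        row2 = s.table[(s.table.condition == "a") & (s.table.block == "block2")].iloc[0]
        assert row2["sd"] == 0.0

    def test_shape_for_four_conditions(self):
        s = summarize_cohort(simulated_wide_frame())
        assert len(s.table) == 8  # 4 conditions x 2 blocks
        assert set(s.conditions()) == set(TABLE2_MEANS)

    def test_excluded_participants_are_omitted(self):
        df = simulated_wide_frame(n_per_group=3)
        df["excluded"] = 0
        df.loc[0, "excluded"] = 1
        s = summarize_cohort(df)
        n0 = s.table[(s.table.condition == df.loc[0, "condition"])]["n"].iloc[0]
        assert n0 == 2

    def test_missing_cell_is_loud(self):
        df = pd.DataFrame({"condition": [], "accuracy_block1": [], "accuracy_block2": []})
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame({
                "condition": ["a"], "accuracy_block1": [np.nan], "accuracy_block2": [1.0],
            }).dropna())


class TestMeanDifferences:
    def test_identical_groups_give_zero(self):
        s = GroupSummary.from_means({"a": (10.0, 20.0), "b": (10.0, 20.0)})
        assert posthoc_mean_difference(s, "a", "b", "block2").m_diff == 0.0
        assert marginal_mean_difference(s, "a", "b").m_diff == 0.0

    def test_marginal_averages_the_two_blocks(self):
        s = GroupSummary.from_means({"a": (10.0, 30.0), "b": (20.0, 20.0)})
        assert marginal_mean_difference(s, "a", "b").m_diff == pytest.approx(0.0)
        assert posthoc_mean_difference(s, "a", "b", "block2").m_diff == pytest.approx(10.0)

    def test_unknown_group_label_rejected(self):
        s = GroupSummary.from_means({"a": (10.0, 30.0)})
        with pytest.raises(KeyError):
            posthoc_mean_difference(s, "a", "zzz", "block2")

    def test_raw_data_ci_brackets_difference_and_matches_summary(self):
        df = simulated_wide_frame(n_per_group=15, seed=4)
        s = summarize_cohort(df)
        c = posthoc_mean_difference(s, "confirmation", "violation", "block2", raw=df)
        assert c.ci_low <= c.m_diff <= c.ci_high
        assert c.method == "bonferroni"
        assert 0.0 <= c.p_adjusted <= 1.0
        assert c.m_diff == pytest.approx(
            s.mean("confirmation", "block2") - s.mean("violation", "block2"))
        m = marginal_mean_difference(s, "confirmation", "violation", raw=df)
        assert m.ci_low <= m.m_diff <= m.ci_high

    def test_widening_family_widens_interval(self):
        df = simulated_wide_frame(n_per_group=15, seed=4)
        s = summarize_cohort(df)
        narrow = posthoc_mean_difference(s, "confirmation", "violation", "block2",
                                         raw=df, family_size=1)
        wide = posthoc_mean_difference(s, "confirmation", "violation", "block2",
                                       raw=df, family_size=6)
        assert (wide.ci_high - wide.ci_low) > (narrow.ci_high - narrow.ci_low)


class TestMixedAnova:
    def test_toy_fixture_matches_brute_force_decomposition(self):
        # 2 groups x 2 subjects, hand-checkable sums of squares
        df = pd.DataFrame({
            "participant_id": ["a1", "a2", "b1", "b2"],
            "condition": ["A", "A", "B", "B"],
            "accuracy_block1": [1.0, 2.0, 1.0, 2.0],
            "accuracy_block2": [2.0, 3.0, 1.0, 2.0],
        })
        expected = brute_force_mixed_ss(df)
        # frozen hand-computed values for this 4-row fixture
        assert expected["time"] == pytest.approx(0.5)
        assert expected["condition"] == pytest.approx(0.5)
        assert expected["time:condition"] == pytest.approx(0.5)
        assert expected["between_error"] == pytest.approx(2.0)
        assert expected["within_error"] == pytest.approx(0.0, abs=1e-12)

        res = mixed_anova(df)
        tab = res.anova_table
        for effect in ("time", "condition", "time:condition"):
            assert tab.loc[effect, "ss"] == pytest.approx(expected[effect], abs=1e-10)
        assert tab.loc["condition", "ss_error"] == pytest.approx(expected["between_error"])
        assert tab.loc["time", "ss_error"] == pytest.approx(expected["within_error"], abs=1e-10)
        # zero within error with nonzero effect: definitional eta^2 limit
        assert tab.loc["time", "eta_sq_p"] == 1.0
        assert np.isinf(tab.loc["time", "F"])

    def test_balanced_simulation_matches_brute_force(self):
        df = simulated_wide_frame(n_per_group=12, seed=7)
        expected = brute_force_mixed_ss(df)
        tab = mixed_anova(df).anova_table
        for effect in ("time", "condition", "time:condition"):
            assert tab.loc[effect, "ss"] == pytest.approx(expected[effect], rel=1e-9)
        assert tab.loc["time", "ss_error"] == pytest.approx(expected["within_error"], rel=1e-9)
        assert tab.loc["condition", "ss_error"] == pytest.approx(
            expected["between_error"], rel=1e-9)

    def test_agrees_with_pingouin_on_balanced_design(self):
        pingouin = pytest.importorskip("pingouin")
        df = simulated_wide_frame(n_per_group=10, seed=3)
        long = df.melt(
            id_vars=["participant_id", "condition"],
            value_vars=["accuracy_block1", "accuracy_block2"],
            var_name="block", value_name="accuracy",
        )
        aov = pingouin.mixed_anova(
            data=long, dv="accuracy", within="block",
            subject="participant_id", between="condition",
        ).set_index("Source")
        tab = mixed_anova(df).anova_table
        assert tab.loc["condition", "F"] == pytest.approx(aov.loc["condition", "F"], rel=1e-6)
        assert tab.loc["time", "F"] == pytest.approx(aov.loc["block", "F"], rel=1e-6)
        assert tab.loc["time:condition", "F"] == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-6)
        assert tab.loc["condition", "eta_sq_p"] == pytest.approx(
            aov.loc["condition", "np2"], rel=1e-6)

    def test_zero_within_change_gives_zero_time_effect(self):
        df = simulated_wide_frame(n_per_group=8, seed=2)
        df["accuracy_block2"] = df["accuracy_block1"]  # additive group shift only
        tab = mixed_anova(df).anova_table
        assert tab.loc["time", "F"] == 0.0
        assert tab.loc["time", "eta_sq_p"] == 0.0
        assert tab.loc["time:condition", "F"] == 0.0
        assert tab.loc["condition", "F"] > 0.0

    def test_eta_squared_identity_on_reported_effects(self):
        df = simulated_wide_frame(n_per_group=9, seed=11)
        tab = mixed_anova(df).anova_table
        for _, row in tab.iterrows():
            assert row["eta_sq_p"] == pytest.approx(
                row["ss"] / (row["ss"] + row["ss_error"]))

    def test_planned_contrasts_detect_the_built_in_interaction(self):
        # only the third/fourth groups change across blocks
        df = simulated_wide_frame(
            n_per_group=20,
            group_means=((15.0, 15.0), (15.0, 15.0), (15.0, 50.0), (15.0, 50.0)),
            sd=5.0, seed=8)
        res = mixed_anova(df)
        ct = res.contrast_table.set_index("contrast")
        assert ct.loc["experiment1 vs experiment2", "p"] < 1e-6
        # the null contrast must be orders of magnitude less extreme
        assert ct.loc["confirmation vs violation", "p"] > 1e-3
        assert (ct.loc["confirmation vs violation", "p"]
                > 1e3 * ct.loc["experiment1 vs experiment2", "p"])
        assert "Planned contrasts" in res.summary()

    def test_singular_design_flagged(self):
        df = simulated_wide_frame(n_per_group=1)
        with pytest.raises(ValueError, match="singular"):
            MixedAnova(df)

    def test_unbalanced_groups_supported(self):
        df = simulated_wide_frame(n_per_group=8, seed=5)
        df = df.iloc[1:]  # 7/8/8/8
        tab = mixed_anova(df).anova_table
        assert (tab["df2"] == 31 - 4).all()
        assert np.isfinite(tab["F"]).all()


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01], 5)[0] == pytest.approx(0.05)
        assert bonferroni_adjust([0.4], 5)[0] == 1.0

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=20),
           hst.integers(1, 50))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_never_below_raw_and_order_preserving(self, ps, m):
        adj = bonferroni_adjust(ps, m)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], 2)


class TestManipulationCheck:
    def test_layout_and_hand_arithmetic(self):
        df = pd.DataFrame({
            "condition": ["a", "a", "b", "b"],
            "post_block1": [10.0, 20.0, 5.0, 15.0],
            "prediction_block2": [20.0, 30.0, 10.0, 20.0],
            "post_block2": [15.0, 25.0, 40.0, 60.0],
        })
        out = manipulation_check_summary(df)
        a = out[out.condition == "a"].iloc[0]
        assert a["post_block1_mean"] == pytest.approx(15.0)
        assert a["post_block1_sd"] == pytest.approx(7.0710678, abs=1e-4)
        assert set(out.columns) >= {
            "post_block1_mean", "prediction_block2_mean", "post_block2_mean"}

    def test_single_row_sd_flagged(self):
        df = pd.DataFrame({
            "condition": ["a"], "post_block1": [10.0],
            "prediction_block2": [20.0], "post_block2": [30.0],
        })
        with pytest.warns(UserWarning, match="SD undefined"):
            out = manipulation_check_summary(df)
        assert np.isnan(out["post_block1_sd"].iloc[0])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            manipulation_check_summary(pd.DataFrame({"condition": ["a"]}))
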