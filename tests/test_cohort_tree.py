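import math

import pytest

from bayestriage import (
    CohortState,
    OutcomeProfile,
    ValidationError,
    aggregate_profiles,
    derive_rates,
    expand,
    level_counts,
    posterior_after_profile,
    trajectory,
)
from bayestriage._rounding import round_half_up
from bayestriage.cohort_tree import profile_label


def _row(rows, n_positive):
    return next(r for r in rows if r.profile.n_positive == n_positive)


class TestExpand:
    def test_depth_zero_is_a_bare_root(self, metro_cohort, metro_test):
        node = expand(metro_cohort, metro_test, 0)
        assert node.split is None
        assert node.pos is None and node.neg is None
        assert node.state == metro_cohort

    def test_depth_two_all_positive_leaf(self, metro_cohort, metro_test):
        node = expand(metro_cohort, metro_test, 2)
        leaf = node.pos.pos
        assert round_half_up(leaf.state.size, 2) == 370.37
        assert round_half_up(leaf.state.prevalence, 8) == 0.02820077
        assert leaf.state.profile_label == "++"

    def test_children_reuse_parent_split_outputs(self, lmr_cohort, symptomatic_test):
        node = expand(lmr_cohort, symptomatic_test, 2)
        assert node.pos.state.size == node.split.n_pos
        assert node.pos.state.prevalence == node.split.prevalence_pos
        assert node.neg.state.size == node.split.n_neg
        assert node.neg.state.prevalence == node.split.prevalence_neg

    def test_leaf_sizes_sum_to_cohort(self, lmr_cohort, symptomatic_test):
        node = expand(lmr_cohort, symptomatic_test, 2)
        leaves = list(node.leaves())
        assert len(leaves) == 4
        assert sum(l.state.size for l in leaves) == pytest.approx(808.0, rel=1e-12)

    def test_leaf_depth_equals_requested_depth(self, metro_cohort, metro_test):
        node = expand(metro_cohort, metro_test, 3)
        for leaf in node.leaves():
            assert len(leaf.state.profile_label) == 3

    def test_depth_beyond_maximum_refused(self, metro_cohort, metro_test):
        with pytest.raises(ValidationError, match="maximum"):
            expand(metro_cohort, metro_test, 13)
        # configurable knob
        expand(metro_cohort, metro_test, 13, max_depth=13)

    def test_empty_branch_is_pruned(self):
        node = expand(CohortState(100.0, 1.0), derive_rates(1.0, 1.0), 2)
        assert node.neg is None  # nobody tests negative
        assert node.pos is not None


class TestOutcomeProfile:
    def test_label_is_positives_first(self):
        assert OutcomeProfile(4, 3).label == "+++-"
        assert profile_label(0, 2) == "--"

    @pytest.mark.parametrize("n", [1, 2, 5, 8])
    def test_multiplicities_sum_to_two_to_the_n(self, n):
        total = sum(OutcomeProfile(n, k).multiplicity for k in range(n + 1))
        assert total == 2**n

    def test_invalid_profiles_raise(self):
        with pytest.raises(ValidationError):
            OutcomeProfile(0, 0)
        with pytest.raises(ValidationError):
            OutcomeProfile(3, 4)


class TestAggregateProfiles:
    def test_metro_depth_four_table(self, metro_cohort, metro_test):
        rows = aggregate_profiles(metro_cohort, metro_test, 4)
        assert [r.profile.label for r in rows] == ["++++", "+++-", "++--", "+---", "----"]
        expected = {
            4: (6.86, 5.57, 1.30),
            3: (89.43, 8.23, 81.20),
            2: (1912.77, 4.57, 1908.20),
            1: (19931.24, 1.13, 19930.11),
            0: (78059.70, 0.10, 78059.59),
        }
        for k, (concerned, sick, healthy) in expected.items():
            row = _row(rows, k)
            assert round_half_up(row.concerned, 2) == concerned
            assert round_half_up(row.sick, 2) == sick
            assert round_half_up(row.healthy, 2) == healthy

    def test_metro_depth_four_posteriors(self, metro_cohort, metro_test):
        rows = aggregate_profiles(metro_cohort, metro_test, 4)
        assert round_half_up(_row(rows, 4).posterior * 100, 6) == 81.116533
        assert round_half_up(_row(rows, 3).posterior * 100, 6) == 9.207504
        assert round_half_up(_row(rows, 0).posterior * 100, 9) == 0.000133439

    def test_hr_depth_four_table(self, hr_cohort, symptomatic_test):
        rows = aggregate_profiles(hr_cohort, symptomatic_test, 4)
        row = _row(rows, 4)
        assert round_half_up(row.concerned, 2) == 17.56
        assert round_half_up(row.sick, 2) == 13.76
        assert round_half_up(row.healthy, 2) == 3.80

    def test_depth_two_mixed_row_doubles_single_ordering(self, metro_cohort, metro_test):
        rows = aggregate_profiles(metro_cohort, metro_test, 2)
        row = _row(rows, 1)
        assert row.profile.multiplicity == 2
        assert round_half_up(row.concerned / 2, 2) == 5642.76
        assert round_half_up(row.posterior, 8) == 0.00068462

    def test_posterior_matches_closed_form(self, lmr_cohort, symptomatic_test):
        rows = aggregate_profiles(lmr_cohort, symptomatic_test, 4)
        for row in rows:
            direct = posterior_after_profile(
                lmr_cohort.prevalence,
                symptomatic_test,
                row.profile.n_positive,
                row.profile.n_negative,
            )
            assert row.posterior == pytest.approx(direct, rel=1e-10)

    def test_conservation_of_size_and_sick(self, lmr_cohort, symptomatic_test):
        rows = aggregate_profiles(lmr_cohort, symptomatic_test, 4)
        assert sum(r.concerned for r in rows) == pytest.approx(808.0, rel=1e-12)
        assert sum(r.sick for r in rows) == pytest.approx(27.0, rel=1e-12)
        for r in rows:
            assert r.concerned == pytest.approx(r.sick + r.healthy, rel=1e-12)

    def test_depth_zero_refused(self, metro_cohort, metro_test):
        with pytest.raises(ValidationError):
            aggregate_profiles(metro_cohort, metro_test, 0)


class TestTrajectory:
    def test_symptomatic_all_positive(self, symptomatic_test):
        series = trajectory(27 / 808, symptomatic_test, 0, 4)
        assert series[0] == (0, 27 / 808)
        assert round_half_up(series[-1][1], 8) == 0.72028812

    def test_symptomatic_one_negative(self, symptomatic_test):
        series = trajectory(27 / 808, symptomatic_test, 1, 4)
        assert [t for t, _ in series] == [1, 2, 3, 4]
        assert round_half_up(series[-1][1], 8) == 0.04607010

    def test_no_tests_returns_prior(self, metro_test):
        assert trajectory(0.25, metro_test, 0, 0) == [(0, 0.25)]

    def test_monotone_when_lr_positive_above_one(self, metro_test):
        series = trajectory(0.001, metro_test, 2, 8)
        posteriors = [p for _, p in series]
        assert posteriors == sorted(posteriors)

    def test_invalid_bounds_raise(self, metro_test):
        with pytest.raises(ValidationError):
            trajectory(0.1, metro_test, 5, 4)


class TestLevelCounts:
    def test_all_positive_counts_match_paperlike_integers(
        self, lmr_cohort, symptomatic_test
    ):
        frame = level_counts(lmr_cohort, symptomatic_test, 5)
        all_pos = frame[frame.n_positive == frame.depth].set_index("depth")
        assert round_half_up(all_pos.loc[1, "concerned"], 2) == 282.00
        assert round_half_up(all_pos.loc[2, "concerned"], 0) == 109
        assert round_half_up(all_pos.loc[3, "concerned"], 0) == 52
        assert round_half_up(all_pos.loc[4, "concerned"], 0) == 32
        assert round_half_up(all_pos.loc[5, "concerned"], 0) == 25

    def test_depth_five_four_positive_profile(self, lmr_cohort, symptomatic_test):
        frame = level_counts(lmr_cohort, symptomatic_test, 5)
        row = frame[(frame.depth == 5) & (frame.n_positive == 4)].iloc[0]
        assert round_half_up(row["concerned"], 0) == 35
        assert row["label"] == "++++-"

    def test_all_positive_closed_form(self, lmr_cohort, symptomatic_test):
        frame = level_counts(lmr_cohort, symptomatic_test, 4)
        n_sick = 27.0
        n_healthy = 781.0
        for d in range(1, 5):
            expected = (
                n_sick * symptomatic_test.sensitivity**d
                + n_healthy * symptomatic_test.p_false_positive**d
            )
            got = frame[(frame.depth == d) & (frame.n_positive == d)].iloc[0]["concerned"]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_prevalence(self, metro_test):
        frame = level_counts(CohortState(1000.0, 0.0), metro_test, 3)
        for d in range(1, 4):
            row = frame[(frame.depth == d) & (frame.n_positive == d)].iloc[0]
            assert row["sick"] == 0.0
            assert row["concerned"] == pytest.approx(
                1000.0 * metro_test.p_false_positive**d, rel=1e-12
            )

    def test_per_depth_totals_conserved(self, metro_cohort, metro_test):
        frame = level_counts(metro_cohort, metro_test, 5)
        totals = frame.groupby("depth")["concerned"].sum()
        assert all(math.isclose(t, 100_000.0, rel_tol=1e-12) for t in totals)
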