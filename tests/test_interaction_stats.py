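"""Interaction-log statistics: passage contrasts, proportions, associations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from burplan.deployment import DeploymentWindow
from burplan.interaction_stats import (
    behaviour_proportions,
    passage_table,
    reaction_summary,
    split_early_late,
    trail_association,
    validate_events,
    yates_chi2,
)
from burplan.synthetic import LogScenario, gen_interaction_log


def _events(timestamps, species="badger", passed=True, **overrides):
    n = len(timestamps)
    base = {
        "site": ["s1"] * n,
        "timestamp": pd.to_datetime(timestamps),
        "species": [species] * n,
        "looked": [0] * n,
        "paused": [0] * n,
        "sniffed": [0] * n,
        "attracted": [0] * n,
        "repelled": [0] * n,
        "passed_through": [int(passed)] * n,
        "within_tagging_distance": [1] * n,
        "trail_type": ["none"] * n,
        "baited": [0] * n,
        "reaction_rating": [pd.NA] * n,
    }
    base.update(overrides)
    return validate_events(pd.DataFrame(base))


class TestValidation:
    def test_attracted_and_repelled_mutually_exclusive(self):
        with pytest.raises(ValueError, match="attracted and repelled"):
            _events(["2022-06-01"], attracted=[1], repelled=[1])

    def test_unknown_trail_type(self):
        with pytest.raises(ValueError, match="trail_type"):
            _events(["2022-06-01"], trail_type=["motorway"])

    def test_bad_reaction_rating(self):
        with pytest.raises(ValueError, match="reaction_rating"):
            _events(["2022-06-01"], reaction_rating=[5])


class TestSplitEarlyLate:
    WINDOW = DeploymentWindow("s1", "2022-06-01 00:00", "2022-06-05 00:00")

    def test_events_on_either_side_of_midpoint(self):
        events = _events(["2022-06-01 12:00", "2022-06-04 12:00"])
        early, late = split_early_late(events, self.WINDOW)
        assert len(early) == 1 and len(late) == 1

    def test_midpoint_boundary_goes_late(self):
        events = _events(["2022-06-03 00:00"])  # exactly the midpoint
        early, late = split_early_late(events, self.WINDOW)
        assert len(early) == 0 and len(late) == 1

    def test_empty_log(self):
        early, late = split_early_late(_events([]), self.WINDOW)
        assert early.empty and late.empty

    def test_event_outside_window_listed(self):
        events = _events(["2022-07-01 00:00"])
        with pytest.raises(ValueError, match="2022-07-01"):
            split_early_late(events, self.WINDOW)


class TestPassageTable:
    def test_counts_passed_and_not_passed(self):
        early = pd.concat(
            [
                _events(["2022-06-01"] * 27, passed=True),
                _events(["2022-06-01"] * 9, passed=False),
            ]
        )
        late = pd.concat(
            [
                _events(["2022-06-04"] * 30, passed=True),
                _events(["2022-06-04"] * 5, passed=False),
            ]
        )
        table = passage_table(early, late, "badger")
        assert table.values.tolist() == [[27, 9], [30, 5]]

    def test_other_species_ignored(self):
        early = _events(["2022-06-01"], species="fox")
        table = passage_table(early, early, "badger")
        assert table.values.sum() == 0


class TestYatesChi2:
    def test_badger_passage_contrast(self, badger_table):
        stat, df, p = yates_chi2(badger_table)
        assert round(stat, 2) == 0.70
        assert df == 1
        assert round(p, 2) == 0.40

    def test_fox_passage_contrast(self, fox_table):
        stat, _, p = yates_chi2(fox_table)
        assert round(stat, 2) == 4.97
        assert round(p, 3) == 0.026

    def test_identical_row_proportions_give_zero(self):
        stat, _, p = yates_chi2([[20, 10], [40, 20]])
        assert stat == 0.0
        assert p == 1.0

    def test_matches_scipy_continuity_correction_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            table = rng.integers(1, 60, size=(2, 2))
            stat, _, p = yates_chi2(table)
            ref = chi2_contingency(table, correction=True)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_transposition_and_label_swap_invariance(self, fox_table):
        table = np.array(fox_table)
        stat, _, _ = yates_chi2(table)
        assert yates_chi2(table.T)[0] == pytest.approx(stat)
        assert yates_chi2(table[::-1])[0] == pytest.approx(stat)
        assert yates_chi2(table[:, ::-1])[0] == pytest.approx(stat)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            yates_chi2([[0, 0], [5, 3]])

    def test_uncorrected_mode_is_pearson(self, fox_table):
        stat, _, _ = yates_chi2(fox_table, correction=False)
        ref = chi2_contingency(np.array(fox_table), correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)


class TestBehaviourProportions:
    def test_every_event_passed(self):
        events = _events(["2022-06-01"] * 7, passed=True)
        assert behaviour_proportions(events)["passed_through"] == 100

    def test_single_event_log(self):
        events = _events(["2022-06-01"], looked=[1], sniffed=[1])
        props = behaviour_proportions(events)
        assert props["look"] == 100 and props["sniff"] == 100 and props["pause"] == 0

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            behaviour_proportions(_events([]))

    def test_generated_log_recovers_category_probabilities(self):
        scenario = LogScenario(
            site_presence={"s": 0.9},
            species_mix={"badger": 1.0},
            window_hours=5556,  # ~5000 expected events
            seed=21,
        )
        log = gen_interaction_log(scenario)
        n = len(log)
        props = behaviour_proportions(log)
        for label, p_true in [("look", 0.29), ("pause", 0.30), ("sniff", 0.41)]:
            se = math.sqrt(p_true * (1 - p_true) / n)
            assert abs(props[label] / 100 - p_true) < 3 * se + 0.005  # rounding slack
        for label, p_true in [("attracted", 0.30), ("repelled", 0.20), ("passed_through", 0.74)]:
            se = math.sqrt(p_true * (1 - p_true) / n)
            assert abs(props[label] / 100 - p_true) < 3 * se + 0.005


class TestTrailAssociation:
    def test_equal_counts_give_zero(self):
        events = pd.concat(
            [
                _events(["2022-06-01"] * 10, trail_type=["well_used"] * 10),
                _events(["2022-06-01"] * 10, trail_type=["none"] * 10),
            ]
        )
        stat, df, p = trail_association(events, "badger")
        assert stat == 0.0 and df == 1

    def test_skewed_usage_significant_in_replicates(self):
        # simulation oracle: 3:1 well-used:none at n = 400
        rng = np.random.default_rng(7)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            n_well = rng.binomial(400, 0.75)
            events = pd.concat(
                [
                    _events(["2022-06-01"] * n_well, trail_type=["well_used"] * n_well),
                    _events(["2022-06-01"] * (400 - n_well), trail_type=["none"] * (400 - n_well)),
                ]
            )
            if trail_association(events, "badger")[2] < 0.05:
                rejections += 1
        assert rejections / n_reps >= 0.95

    def test_empty_category_dropped_with_warning(self):
        events = _events(["2022-06-01"] * 6, trail_type=["well_used"] * 6)
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match=">= 2"):
                trail_association(events, "badger")

    def test_three_categories_pearson(self):
        events = pd.concat(
            [
                _events(["2022-06-01"] * 30, trail_type=["well_used"] * 30),
                _events(["2022-06-01"] * 20, trail_type=["faint"] * 20),
                _events(["2022-06-01"] * 10, trail_type=["none"] * 10),
            ]
        )
        stat, df, _ = trail_association(events, "badger", ("well_used", "faint", "none"))
        assert df == 2
        assert stat == pytest.approx(10.0)  # sum (O-E)^2/E with E=20


class TestReactionSummary:
    def test_all_rating_one(self):
        events = _events(["2022-06-01"] * 4, reaction_rating=[1, 1, 1, 1])
        out = reaction_summary(events)
        assert out.loc[0, ["pct_rating_1", "pct_rating_2", "pct_rating_3"]].tolist() == [
            100,
            0,
            0,
        ]

    def test_percentages_sum_near_100_per_group(self):
        ratings = [1] * 80 + [2] * 5 + [3] * 3
        events = _events(["2022-06-01"] * 88, reaction_rating=ratings)
        out = reaction_summary(events)
        total = out[["pct_rating_1", "pct_rating_2", "pct_rating_3"]].sum(axis=1)
        assert ((total - 100).abs() <= 1).all()

    def test_generated_ratings_recovered(self):
        scenario = LogScenario(
            site_presence={"s": 0.9},
            species_mix={"dog": 1.0},
            reaction_probs=(0.94, 0.06, 0.0),
            window_hours=2500,
            seed=3,
        )
        log = gen_interaction_log(scenario)
        out = reaction_summary(log, group_by="species")
        n = int(out.loc[0, "n_passes"])
        se = math.sqrt(0.94 * 0.06 / n)
        assert abs(out.loc[0, "pct_rating_1"] / 100 - 0.94) < 3 * se + 0.005
        assert out.loc[0, "pct_rating_3"] == 0
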