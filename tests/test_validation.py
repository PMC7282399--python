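"""Cohort-normality checks: variance components, vision, milestones, summaries."""

import numpy as np
import pandas as pd
import pytest

from internda import (
    MilestoneWindow,
    NormRange,
    describe_cohort,
    milestone_window_check,
    variance_components,
    vision_centile_check,
)
from internda.hd import centile_label
from internda.validation import WHO_MOTOR_WINDOWS


class TestVarianceComponents:
    def test_degenerate_two_site_closed_form(self):
        # sites {0,0} and {1,1}: zero within-site variance, all between
        vd = variance_components([0, 0, 1, 1], ["A", "A", "B", "B"])
        assert vd.sigma2_within == pytest.approx(0.0)
        assert vd.between_share == pytest.approx(1.0)

    def test_hand_computed_unbalanced_fixture(self):
        # sites A={0,1}, B={10,11}: MSB=100, MSW=0.5, n0=2
        # sigma2_between=(100-0.5)/2=49.75, share=49.75/50.25
        vd = variance_components([0, 1, 10, 11], ["A", "A", "B", "B"])
        assert vd.sigma2_between == pytest.approx(49.75)
        assert vd.sigma2_within == pytest.approx(0.5)
        assert vd.between_share == pytest.approx(49.75 / 50.25)

    def test_null_cohort_share_near_zero(self, rng):
        scores = rng.normal(50, 10, 2500)
        sites = np.repeat([f"s{i}" for i in range(5)], 500)
        assert variance_components(scores, sites).between_share < 0.02

    def test_scale_invariance(self, rng):
        scores = rng.normal(0, 1, 300) + np.repeat([0.0, 0.5, 1.0], 100)
        sites = np.repeat(list("ABC"), 100)
        s1 = variance_components(scores, sites).between_share
        s2 = variance_components(scores * 37.2, sites).between_share
        assert s1 == pytest.approx(s2)

    def test_balanced_variance_conservation(self, rng):
        sites = np.repeat(list("ABCDE"), 200)
        scores = rng.normal(0, 1, 1000) + np.repeat(rng.normal(0, 0.5, 5), 200)
        vd = variance_components(scores, sites)
        total = scores.var(ddof=1)
        assert vd.sigma2_between + vd.sigma2_within == pytest.approx(
            total, rel=0.15
        )

    def test_small_site_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="<2 children"):
            vd = variance_components(
                [0, 1, 2, 3, 99], ["A", "A", "B", "B", "tiny"]
            )
        assert vd.n_sites == 2

    def test_single_usable_site_rejected(self):
        with pytest.raises(ValueError, match="at least 2 sites"):
            variance_components([1, 2, 3], ["A", "A", "A"])


class TestVision:
    def test_constant_acuity(self):
        check = vision_centile_check([0.2] * 30, [1.5] * 30)
        assert list(check.centiles["acuity_logmar"].values()) == pytest.approx([0.2] * 5)
        assert check.in_norm["acuity_logmar"] is True

    def test_symmetric_contrast_median(self):
        check = vision_centile_check([0.2, 0.2, 0.2], [1.0, 1.5, 2.0])
        assert check.centiles["contrast_percent"][centile_label(0.5)] == pytest.approx(1.5)

    def test_labels_decrease_for_lower_is_better(self, rng):
        # better (lower) acuity must sit at higher centile labels
        check = vision_centile_check(
            rng.choice([0.1, 0.2, 0.3], 500, p=[0.25, 0.55, 0.2]),
            rng.uniform(1.0, 2.0, 500),
        )
        row = check.centiles["acuity_logmar"]
        assert row[centile_label(0.10)] >= row[centile_label(0.90)]

    def test_out_of_norm_verdict(self):
        norms = {
            "acuity_logmar": NormRange("acuity_logmar", 0.0, 0.1),
            "contrast_percent": NormRange("contrast_percent", 0.5, 3.0),
        }
        check = vision_centile_check([0.4] * 25, [1.5] * 25, norms=norms)
        assert check.in_norm["acuity_logmar"] is False

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            vision_centile_check([], [1.0])


class TestMilestones:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=["child_id", "milestone", "age_months"])

    def test_all_within(self):
        df = self.frame(
            [(f"c{i}", "walking_alone", 12.0) for i in range(5)]
        )
        out = milestone_window_check(df)
        walking = out[out.milestone == "walking_alone"].iloc[0]
        assert walking.proportion_within == 1.0

    def test_one_of_four_outside(self):
        df = self.frame(
            [("c1", "walking_alone", 12), ("c2", "walking_alone", 13),
             ("c3", "walking_alone", 9), ("c4", "walking_alone", 20)]
        )
        out = milestone_window_check(df)
        assert out[out.milestone == "walking_alone"].iloc[0].proportion_within == 0.75

    def test_never_observed_counts_outside_missing_excluded(self):
        df = self.frame(
            [("c1", "standing_alone", 10.0), ("c2", "standing_alone", np.inf),
             ("c3", "standing_alone", np.nan)]
        )
        row = milestone_window_check(df).set_index("milestone").loc["standing_alone"]
        assert row.n == 2 and row.proportion_within == 0.5

    def test_empty_data_reported_missing(self):
        out = milestone_window_check(self.frame([]))
        assert len(out) == len(WHO_MOTOR_WINDOWS)
        assert out.proportion_within.isna().all()

    def test_unknown_milestone_rejected(self):
        with pytest.raises(ValueError, match="unknown milestone"):
            milestone_window_check(self.frame([("c1", "moonwalking", 14.0)]))

    def test_window_validity(self):
        with pytest.raises(ValueError):
            MilestoneWindow("walking_alone", 12.0, 10.0)


class TestDescribe:
    def test_hand_computed_mean_sd(self):
        df = pd.DataFrame({"age": [22, 23, 24, 25]})
        out = describe_cohort(df, continuous=["age"])
        assert out.iloc[0].summary == "23.5 (1.29)"

    def test_single_child_and_binary(self):
        df = pd.DataFrame({"age": [24.0], "preterm": [False]})
        out = describe_cohort(df, continuous=["age"], binary=["preterm"])
        assert out.iloc[0].summary == "24.0 (0.00)"
        assert out.iloc[1].summary == "n=0 (0.0%)"

    def test_empty_cohort(self):
        out = describe_cohort(pd.DataFrame({"age": []}))
        assert out.empty
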