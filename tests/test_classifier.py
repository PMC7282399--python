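"""Screening chart: normality thresholds, zone classification, report rendering."""

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

from internda import (
    StandardsChart,
    build_centile_table,
    chart_from_table,
    classify_score,
    normality_threshold,
    published_chart,
    render_chart,
)
from internda.classifier import HIGHER_IS_BETTER, LOWER_IS_BETTER


@pytest.fixture(scope="module")
def chart():
    return published_chart()


class TestNormalityThresholds:
    @pytest.mark.parametrize(
        "domain, value",
        [
            ("cognitive", 38.5),
            ("fine_motor", 25.7),
            ("gross_motor", 51.7),
            ("language", 17.8),
            ("positive_behaviour", 51.4),
        ],
    )
    def test_higher_is_better_thresholds(self, chart, domain, value):
        assert normality_threshold(chart, domain) == (value, ">=")

    def test_negative_behaviour_mirrored(self, chart):
        assert normality_threshold(chart, "negative_behaviour") == (50.0, "<=")

    def test_degenerate_flat_chart(self):
        flat = StandardsChart(
            boundaries={"cognitive": {"c3": 40, "c10": 40, "c90": 40, "c97": 40}},
            directions={"cognitive": HIGHER_IS_BETTER},
        )
        assert normality_threshold(flat, "cognitive") == (40, ">=")

    def test_unknown_domain(self, chart):
        with pytest.raises(KeyError):
            normality_threshold(chart, "charm")


class TestClassifyScore:
    @pytest.mark.parametrize(
        "domain, score, zone",
        [
            ("cognitive", 38.5, "normal"),   # inclusive at the 10th centile
            ("cognitive", 30.0, "monitor"),  # between c3=27.4 and c10=38.5
            ("cognitive", 27.4, "monitor"),  # exact c3 stays monitor
            ("cognitive", 20.0, "urgent"),
            ("negative_behaviour", 50.0, "normal"),   # inclusive at c90
            ("negative_behaviour", 60.0, "monitor"),
            ("negative_behaviour", 76.5, "monitor"),  # exact c97 stays monitor
            ("negative_behaviour", 80.0, "urgent"),   # beyond c97 = 76.5
        ],
    )
    def test_published_zone_rules(self, chart, domain, score, zone):
        assert classify_score(chart, domain, score).zone == zone

    def test_collapsed_monitor_band(self, chart):
        # negative behaviour has c3 = c10 = 0; classification stays total
        assert classify_score(chart, "negative_behaviour", 0.0).zone == "normal"

    def test_score_out_of_range(self, chart):
        with pytest.raises(ValueError):
            classify_score(chart, "cognitive", 101.0)


@st.composite
def random_charts(draw):
    cuts = sorted(draw(st.lists(st.floats(0, 100), min_size=4, max_size=4)))
    direction = draw(st.sampled_from([HIGHER_IS_BETTER, LOWER_IS_BETTER]))
    return StandardsChart(
        boundaries={"d": dict(zip(("c3", "c10", "c90", "c97"), cuts))},
        directions={"d": direction},
    )


class TestZoneProperties:
    @given(chart=random_charts(), score=st.floats(0, 100))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_totality(self, chart, score):
        assert classify_score(chart, "d", score).zone in ("normal", "monitor", "urgent")

    @given(chart=random_charts(), score=st.floats(0, 99))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_toward_better(self, chart, score):
        rank = {"urgent": 0, "monitor": 1, "normal": 2}
        z1 = rank[classify_score(chart, "d", score).zone]
        better = min(100.0, score + 1.0) if chart.directions["d"] == HIGHER_IS_BETTER \
            else max(0.0, score - 1.0)
        z2 = rank[classify_score(chart, "d", better).zone]
        assert z2 >= z1

    @given(chart=random_charts())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_threshold_consistent_with_zones(self, chart):
        thr, op = normality_threshold(chart, "d")
        res = classify_score(chart, "d", thr)
        assert res.zone == "normal"  # inclusive threshold
        # a nudge past the threshold in the bad direction leaves normal,
        # unless the monitor band is collapsed onto the threshold
        eps = 1e-6
        worse = thr - eps if op == ">=" else thr + eps
        if 0 <= worse <= 100:
            assert classify_score(chart, "d", worse).zone in ("monitor", "urgent")


class TestChartConstruction:
    def test_from_centile_table(self, rng):
        table = build_centile_table(
            {"cognitive": rng.normal(60, 15, 400).clip(0, 100)},
            centile_set=(0.03, 0.10, 0.50, 0.90, 0.97),
        )
        chart = chart_from_table(table)
        assert chart.boundaries["cognitive"]["c3"] <= chart.boundaries["cognitive"]["c97"]

    def test_missing_centiles_rejected(self, rng):
        table = build_centile_table(
            {"cognitive": rng.normal(60, 15, 50)}, centile_set=(0.25, 0.5)
        )
        with pytest.raises(ValueError, match="centile set"):
            chart_from_table(table)

    def test_unordered_boundaries_rejected(self):
        with pytest.raises(ValueError, match="not ordered"):
            StandardsChart(
                boundaries={"d": {"c3": 50, "c10": 40, "c90": 90, "c97": 97}},
                directions={"d": HIGHER_IS_BETTER},
            )


class TestRenderChart:
    def test_empty_results(self, chart):
        report = render_chart(chart, [])
        assert report["n_domains"] == 0 and report["flagged_domains"] == []
        assert "domain" in report["text"]  # header-only table

    def test_six_domain_report(self, chart, tmp_path):
        results = [classify_score(chart, d, 60.0) for d in chart.domains]
        plot = tmp_path / "chart.png"
        report = render_chart(chart, results, plot_path=str(plot))
        assert report["n_domains"] == 6
        assert plot.exists()
        # 60 is normal everywhere except negative behaviour (60 > c90 = 50)
        assert report["flagged_domains"] == ["negative_behaviour"]

    def test_all_normal_profile_has_no_flags(self, chart):
        results = [
            classify_score(chart, d, 60.0)
            for d in chart.domains
            if d != "negative_behaviour"
        ] + [classify_score(chart, "negative_behaviour", 10.0)]
        report = render_chart(chart, results)
        assert report["flagged_domains"] == []
        assert all(r["guidance"] == "no referral indicated" for r in report["rows"])
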