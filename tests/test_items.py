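"""Instrument scoring: raw means, 0-100 scaled scores, completeness."""

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

from internda import (
    AssessmentRecord,
    ItemDefinition,
    ItemMap,
    compute_domain_scores,
    flag_completeness,
    load_item_map,
)
from internda.items import DOMAINS

from conftest import midpoint_response


class TestItemMap:
    def test_default_map_composition(self, item_map):
        assert len(item_map) == 37
        by_scale = {3: 0, 5: 0}
        for it in item_map.items:
            by_scale[it.scale_points] += 1
        # 30 five-point + 6 three-point + 1 unstated-scale item scored five-point
        assert by_scale == {5: 31, 3: 6}
        assert set(item_map.domains) == set(DOMAINS)
        assert all(item_map.items_for(d) for d in DOMAINS)

    def test_single_item_map(self):
        m = load_item_map(
            {"version": "v1", "items": [
                {"item_id": "x1", "domain": "cognitive", "scale_points": 5}
            ]}
        )
        assert len(m) == 1 and m["x1"].domain == "cognitive"

    @pytest.mark.parametrize(
        "bad",
        [
            {"item_id": "x1", "domain": "cognitive", "scale_points": 4},
            {"item_id": "x1", "domain": "telepathy", "scale_points": 5},
        ],
        ids=["four-point scale", "unknown domain"],
    )
    def test_invalid_items_rejected(self, bad):
        with pytest.raises(ValueError):
            load_item_map({"items": [bad]})

    def test_duplicate_ids_rejected(self):
        item = {"item_id": "x1", "domain": "cognitive", "scale_points": 5}
        with pytest.raises(ValueError, match="duplicate"):
            load_item_map({"items": [item, item]})


class TestDomainScores:
    def test_all_minimum_scores_zero(self, item_map):
        rec = AssessmentRecord("c", 24, {it.item_id: 1 for it in item_map.items})
        assert all(s.scaled == 0.0 for s in compute_domain_scores(rec, item_map))

    def test_all_maximum_scores_hundred(self, item_map):
        rec = AssessmentRecord(
            "c", 24, {it.item_id: it.scale_points for it in item_map.items}
        )
        for s in compute_domain_scores(rec, item_map):
            assert s.scaled == 100.0 and s.completeness == 1.0

    def test_two_item_hand_example(self):
        # two 5-point items scored (3, 5): 100 * ((2/4 + 4/4) / 2) = 75.0
        m = ItemMap(
            [ItemDefinition("a", "language", 5), ItemDefinition("b", "language", 5)]
        )
        (score,) = compute_domain_scores(
            AssessmentRecord("c", 24, {"a": 3, "b": 5}), m
        )
        assert score.scaled == pytest.approx(75.0)
        assert score.raw_mean == pytest.approx(4.0)

    def test_missing_items_prorated(self, item_map):
        cog = item_map.items_for("cognitive")
        rec = AssessmentRecord("c", 24, {cog[0].item_id: 5})
        scores = {s.domain: s for s in compute_domain_scores(rec, item_map)}
        assert scores["cognitive"].scaled == pytest.approx(100.0)
        assert scores["cognitive"].n_items_answered == 1
        assert scores["cognitive"].completeness == pytest.approx(1 / len(cog))
        assert scores["language"].scaled is None
        assert scores["language"].completeness == 0.0

    def test_out_of_range_response_rejected(self, item_map):
        rec = AssessmentRecord("c", 24, {item_map.items[0].item_id: 9})
        with pytest.raises(ValueError, match="outside"):
            compute_domain_scores(rec, item_map)

    def test_unknown_item_rejected(self, item_map):
        with pytest.raises(ValueError, match="unknown item"):
            compute_domain_scores(AssessmentRecord("c", 24, {"nope": 1}), item_map)


class TestScoringInvariants:
    """Property tests over random response sets on the default map."""

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scaled_bounded_and_midpoint_is_fifty(self, item_map, data):
        responses = {
            it.item_id: data.draw(
                st.integers(1, it.scale_points), label=it.item_id
            )
            for it in item_map.items
        }
        scores = compute_domain_scores(
            AssessmentRecord("c", 24, responses), item_map
        )
        assert all(0.0 <= s.scaled <= 100.0 for s in scores)
        # midpoint of every item gives exactly 50 whatever the 3/5-point mix
        mid = {it.item_id: midpoint_response(it) for it in item_map.items}
        mid_scores = compute_domain_scores(AssessmentRecord("c", 24, mid), item_map)
        assert all(s.scaled == pytest.approx(50.0) for s in mid_scores)

    @given(data=st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_any_single_response(self, item_map, data):
        responses = {
            it.item_id: data.draw(st.integers(1, it.scale_points))
            for it in item_map.items
        }
        target = data.draw(st.sampled_from(item_map.items))
        before = {
            s.domain: s.scaled
            for s in compute_domain_scores(
                AssessmentRecord("c", 24, responses), item_map
            )
        }
        bumped = dict(responses)
        bumped[target.item_id] = min(target.scale_points, responses[target.item_id] + 1)
        after = {
            s.domain: s.scaled
            for s in compute_domain_scores(
                AssessmentRecord("c", 24, bumped), item_map
            )
        }
        assert after[target.domain] >= before[target.domain]
        for d in before:
            if d != target.domain:
                assert after[d] == before[d]

    def test_item_order_irrelevant(self, item_map):
        reversed_map = ItemMap(list(reversed(item_map.items)), item_map.version)
        rec = AssessmentRecord(
            "c", 24, {it.item_id: (i % it.scale_points) + 1
                      for i, it in enumerate(item_map.items)}
        )
        a = {s.domain: s.scaled for s in compute_domain_scores(rec, item_map)}
        b = {s.domain: s.scaled for s in compute_domain_scores(rec, reversed_map)}
        assert a == b


class TestCompleteness:
    def test_fully_answered_is_complete(self, item_map):
        rec = AssessmentRecord("c", 24, {it.item_id: 1 for it in item_map.items})
        verdict = flag_completeness("c", compute_domain_scores(rec, item_map))
        assert verdict.complete and verdict.incomplete_domains == []

    def test_sparse_domain_listed(self, item_map):
        cog = item_map.items_for("cognitive")
        responses = {it.item_id: 1 for it in item_map.items}
        for it in cog[: len(cog) // 2 + 1]:
            del responses[it.item_id]
        verdict = flag_completeness(
            "c",
            compute_domain_scores(AssessmentRecord("c", 24, responses), item_map),
            min_fraction=0.8,
        )
        assert not verdict.complete
        assert verdict.incomplete_domains == ["cognitive"]

    def test_threshold_boundary_inclusive(self):
        m = ItemMap(
            [ItemDefinition("a", "language", 5), ItemDefinition("b", "language", 5)]
        )
        scores = compute_domain_scores(AssessmentRecord("c", 24, {"a": 3}), m)
        assert scores[0].completeness == 0.5
        assert flag_completeness("c", scores, min_fraction=0.5).complete
        assert not flag_completeness("c", scores, min_fraction=0.51).complete
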