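"""Three-condition shared-use detection: predicates, policies, oracle parity."""

import numpy as np
import pandas as pd
import pytest

from shareduse.claims import ClaimsTable
from shareduse.detection import (
    DetectionParams,
    SharedUseEvent,
    brute_force_oracle,
    condition1_isolated,
    detect_shared_use,
    qualifying_sources,
    select_source,
    SourceCandidate,
)
from shareduse.synthetic import GenerationError, GeneratorConfig, generate_claims

from conftest import day, make_claims


def _exam(claims, patient="P1", facility="T"):
    ex = claims.imaging_exams
    row = ex[(ex["patient_id"] == patient) & (ex["facility_id"] == facility)]
    return row.iloc[0]


class TestCondition1:
    def test_single_exam_is_isolated(self, toy_episode):
        assert condition1_isolated(_exam(toy_episode), toy_episode)

    def test_cross_modality_exam_within_window_breaks_isolation(self):
        claims = make_claims([
            ("P1", "T", 100, True, "CT"),
            ("P1", "T", 150, True, "MRI"),  # 50-day gap <= 91
        ])
        assert not condition1_isolated(_exam(claims), claims)

    def test_exam_beyond_window_keeps_isolation(self):
        claims = make_claims([
            ("P1", "T", 100, True, "CT"),
            ("P1", "T", 200, True, "CT"),  # 100-day gap > 91
        ])
        ex = claims.imaging_exams
        first = ex[ex["service_date"] == day(100)].iloc[0]
        # brute-force over every 91-day window containing day 100: each holds one exam
        for start in range(100 - 91, 101):
            in_window = ex[
                (ex["service_date"] >= day(start)) & (ex["service_date"] <= day(start + 91))
            ]
            if day(100) in set(in_window["service_date"]):
                assert (in_window["service_date"] <= day(191)).all()
        assert condition1_isolated(first, claims)

    def test_other_facility_exam_irrelevant(self):
        claims = make_claims([
            ("P1", "T", 100, True, "CT"),
            ("P1", "U", 110, True, "CT"),
        ])
        assert condition1_isolated(_exam(claims), claims)


class TestQualifyingSources:
    def test_bracketing_pair_qualifies_with_tight_window(self, toy_episode):
        cands = qualifying_sources(_exam(toy_episode), toy_episode)
        assert len(cands) == 1
        c = cands[0]
        assert c.facility_id == "S"
        assert (c.window_start, c.window_end) == (day(70), day(130))
        assert c.visit_count == 2

    def test_window_wider_than_continuity_fails(self):
        claims = make_claims([
            ("P1", "S", 70), ("P1", "S", 300), ("P1", "T", 100, True, "CT"),
        ])
        assert qualifying_sources(_exam(claims), claims) == []

    def test_unbracketed_exam_fails(self):
        claims = make_claims([
            ("P1", "S", 120), ("P1", "S", 150), ("P1", "T", 100, True, "CT"),
        ])
        assert qualifying_sources(_exam(claims), claims) == []

    def test_source_side_exam_disqualifies(self):
        claims = make_claims([
            ("P1", "S", 70), ("P1", "S", 130),
            ("P1", "S", 90, True, "MRI"),  # source conducted imaging inside the bracket
            ("P1", "T", 100, True, "CT"),
        ])
        assert qualifying_sources(_exam(claims), claims) == []

    def test_exhaustive_pair_enumeration_matches(self, toy_episode):
        # oracle-style enumeration of all visit pairs at S
        visits = [70, 130]
        valid = [
            (a, b)
            for a in visits
            for b in visits
            if a < b and a <= 100 <= b and b - a <= 182
        ]
        assert valid == [(70, 130)]


class TestSelectSource:
    def _cand(self, fid, gap, count=2):
        return SourceCandidate(fid, day(0), day(10), count, gap)

    def test_smallest_gap_wins(self):
        assert select_source([self._cand("S1", 5), self._cand("S2", 20)]) == "S1"

    def test_gap_tie_broken_by_count(self):
        assert select_source([self._cand("S1", 5, 3), self._cand("S2", 5, 2)]) == "S1"
        assert select_source([self._cand("S1", 5, 2), self._cand("S2", 5, 3)]) == "S2"

    def test_full_tie_broken_lexicographically(self):
        assert select_source([self._cand("B", 5), self._cand("A", 5)]) == "A"

    def test_empty_candidates_signal_no_source(self):
        assert select_source([]) is None


class TestDetect:
    def test_toy_episode_yields_one_event(self, toy_episode):
        events = detect_shared_use(toy_episode, "CT", 2016)
        assert len(events) == 1
        e = events[0]
        assert (e.source_facility_id, e.target_facility_id) == ("S", "T")
        assert e.exam_date == day(100)
        assert e.fiscal_year == 2016

    def test_second_target_exam_suppresses_event(self, toy_episode):
        claims = make_claims([
            ("P1", "S", 70), ("P1", "S", 130),
            ("P1", "T", 100, True, "CT"), ("P1", "T", 140, True, "CT"),
        ])
        assert detect_shared_use(claims, "CT", 2016) == []

    def test_empty_claims(self):
        empty = ClaimsTable(
            visits=pd.DataFrame(columns=["patient_id", "facility_id", "service_date",
                                         "is_imaging_exam", "modality"]),
            enrollments=pd.DataFrame(columns=["patient_id", "start_date", "end_date"]),
            facilities=pd.DataFrame(columns=["facility_id", "bed_count"]),
        )
        assert detect_shared_use(empty, "CT", 2016) == []

    def test_policy_all_emits_one_event_per_source(self):
        claims = make_claims([
            ("P1", "S1", 90), ("P1", "S1", 120),
            ("P1", "S2", 80), ("P1", "S2", 110),
            ("P1", "T", 100, True, "CT"),
        ])
        nearest = detect_shared_use(claims, "CT", 2016)
        assert len(nearest) == 1
        all_events = detect_shared_use(
            claims, "CT", 2016, DetectionParams(multi_source_policy="all")
        )
        assert {e.source_facility_id for e in all_events} == {"S1", "S2"}

    def test_fiscal_year_stratum_by_exam_date(self):
        # exam in FY2017, source visits crossing the FY boundary still count
        claims = make_claims([
            ("P1", "S", 360), ("P1", "S", 380), ("P1", "T", 370, True, "CT"),
        ])
        assert detect_shared_use(claims, "CT", 2016) == []
        events = detect_shared_use(claims, "CT", 2017)
        assert len(events) == 1

    def test_row_order_invariance(self):
        claims, _ = generate_claims(GeneratorConfig(
            n_facilities=8, n_patients=25, within_community_prob=0.25,
            noise_visit_rate=2.0, violation_mix={1: 1, 2: 1, 3: 1}, seed=17,
        ))
        baseline = [e.key() for e in detect_shared_use(claims, "CT", None)]
        shuffled = ClaimsTable(
            visits=claims.visits.sample(frac=1, random_state=3).reset_index(drop=True),
            enrollments=claims.enrollments,
            facilities=claims.facilities,
        )
        assert [e.key() for e in detect_shared_use(shuffled, "CT", None)] == baseline

    def test_at_most_one_event_per_exam_under_nearest(self):
        claims, _ = generate_claims(GeneratorConfig(
            n_facilities=10, n_patients=30, within_community_prob=0.3,
            noise_visit_rate=3.0, seed=23,
        ))
        events = detect_shared_use(claims, "CT", None)
        exams = [(e.patient_id, e.target_facility_id, e.exam_date) for e in events]
        assert len(exams) == len(set(exams))


@pytest.fixture(scope="module")
def random_claims():
    claims, _ = generate_claims(GeneratorConfig(
        n_facilities=10, n_patients=40, within_community_prob=0.3,
        noise_visit_rate=3.0, violation_mix={1: 2, 2: 2, 3: 2}, seed=29,
    ))
    return claims


class TestWindowMonotonicity:
    def test_shrinking_isolation_window_grows_event_set(self, random_claims):
        # smaller isolation window relaxes the isolation requirement
        wide = {e.key() for e in detect_shared_use(
            random_claims, "CT", None, DetectionParams(isolation_window_days=91))}
        narrow = {e.key() for e in detect_shared_use(
            random_claims, "CT", None, DetectionParams(isolation_window_days=30))}
        assert narrow >= wide

    def test_shrinking_continuity_window_shrinks_event_set(self, random_claims):
        long = {e.key() for e in detect_shared_use(
            random_claims, "CT", None, DetectionParams(continuity_window_days=182))}
        short = {e.key() for e in detect_shared_use(
            random_claims, "CT", None, DetectionParams(continuity_window_days=100))}
        assert short <= long


class TestOracleParity:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_detector_matches_exhaustive_oracle(self, seed):
        claims, _ = generate_claims(GeneratorConfig(
            n_facilities=10, n_patients=30, within_community_prob=0.25,
            noise_visit_rate=2.5, violation_mix={1: 1, 2: 1, 3: 1},
            seed=100 + seed,
        ))
        for policy in ("nearest", "all"):
            params = DetectionParams(multi_source_policy=policy)
            det = {e.key() for e in detect_shared_use(claims, "CT", None, params)}
            orc = {e.key() for e in brute_force_oracle(claims, "CT", None, params)}
            assert det == orc

    def test_single_visit_patients_yield_nothing(self):
        claims = make_claims([
            ("P1", "T", 100, True, "CT"), ("P2", "S", 50),
        ])
        assert brute_force_oracle(claims, "CT", None) == []

    def test_never_a_self_referral(self):
        claims = make_claims([
            ("P1", "T", 60), ("P1", "T", 140), ("P1", "T", 100, True, "CT"),
        ])
        assert brute_force_oracle(claims, "CT", None) == []
        assert detect_shared_use(claims, "CT", None) == []


class TestParams:
    def test_isolation_must_not_exceed_continuity(self):
        with pytest.raises(ValueError):
            DetectionParams(isolation_window_days=200, continuity_window_days=100)

    def test_event_requires_distinct_facilities(self):
        with pytest.raises(ValueError):
            SharedUseEvent("P1", "F1", "F1", day(0), "CT", 2016)
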