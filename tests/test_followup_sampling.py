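import math
from datetime import date

import numpy as np
import pytest

from ctgaudit.followup_sampling import (
    BOSTON,
    AttemptResult,
    OutcomeCategory,
    ResponseKind,
    build_contact_plan,
    classify_outcome,
    followup_eligible,
    followup_table,
    haversine_km,
    stratified_sample,
)
from ctgaudit.registry_io import (
    ContactInfo,
    DatePrecision,
    FuzzyDate,
    OverallStatus,
    TrialLocation,
    TrialRecord,
)
from ctgaudit.synthetic_data import (
    FollowupParams,
    default_corpus_spec,
    generate_corpus,
    run_followup_study,
)


def _mk(nct, day, status=OverallStatus.RECRUITING, locations=(), overall=None, backup=None):
    return TrialRecord(
        nct_id=nct,
        domain_tag="d",
        overall_status=status,
        first_received=FuzzyDate(2010, 1, 1),
        last_update=FuzzyDate(2013, *day),
        locations=locations,
        overall_contact=overall,
        backup_contact=backup,
    )


class TestHaversine:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = (float(rng.uniform(-90, 90)), float(rng.uniform(-180, 180)))
            b = (float(rng.uniform(-90, 90)), float(rng.uniform(-180, 180)))
            assert haversine_km(a, a) == 0
            assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))

    def test_boston_new_york_against_law_of_cosines(self):
        ny = (40.7128, -74.0060)
        d = haversine_km(BOSTON, ny)
        # independent spherical-law-of-cosines computation
        lat1, lon1, lat2, lon2 = map(math.radians, (*BOSTON, *ny))
        loc = 6371.0 * math.acos(
            math.sin(lat1) * math.sin(lat2)
            + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
        )
        assert d == pytest.approx(loc, abs=1e-6)
        assert d == pytest.approx(306, abs=2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((91.0, 0.0), (0.0, 0.0))


class TestStratifiedSample:
    def _trials(self, n):
        return [_mk(f"NCT{i:08d}", (1 + i % 12, 1 + i % 28)) for i in range(n)]

    def test_forty_eligible_all_sampled(self):
        plan = stratified_sample(self._trials(40), seed=0)
        assert [b - a for a, b in plan.segment_boundaries] == [10, 10, 10, 10]
        assert sorted(plan.sampled_ids) == sorted(plan.eligible_ids)

    def test_33_eligible_takes_segments_whole(self):
        plan = stratified_sample(self._trials(33), seed=0)
        assert [b - a for a, b in plan.segment_boundaries] == [9, 8, 8, 8]
        assert len(plan.sampled_ids) == 33

    def test_large_list_samples_ten_per_segment_without_overlap(self):
        plan = stratified_sample(self._trials(120), seed=1)
        assert len(plan.sampled_ids) == 40
        assert len(set(plan.sampled_ids)) == 40
        # each sampled id lies inside its own segment
        pos = {nid: i for i, nid in enumerate(plan.eligible_ids)}
        seg_sets = [
            {nid for nid in plan.sampled_ids if a <= pos[nid] < b}
            for a, b in plan.segment_boundaries
        ]
        assert all(len(s) == 10 for s in seg_sets)

    def test_ordering_is_by_last_update(self):
        trials = self._trials(20)
        plan = stratified_sample(trials, seed=0)
        from ctgaudit.status_audit import latest_day

        by_id = {t.nct_id: t for t in trials}
        days = [latest_day(by_id[n].last_update) for n in plan.eligible_ids]
        assert days == sorted(days)

    def test_determinism_and_seed_sensitivity(self):
        trials = self._trials(120)
        a = stratified_sample(trials, seed=7)
        b = stratified_sample(trials, seed=7)
        c = stratified_sample(trials, seed=8)
        assert a.sampled_ids == b.sampled_ids
        assert a.sampled_ids != c.sampled_ids

    def test_empty_list_gives_empty_plan(self):
        plan = stratified_sample([], seed=0, domain_tag="d")
        assert plan.sampled_ids == () and plan.eligible_ids == ()


def test_followup_eligibility_filter():
    us = TrialLocation("f", "Boston", "United States")
    non_us = TrialLocation("f", "Berlin", "Germany")
    assert followup_eligible(_mk("NCT00000001", (1, 1), locations=(us,)))
    assert not followup_eligible(_mk("NCT00000002", (1, 1), locations=(non_us,)))
    assert not followup_eligible(
        _mk("NCT00000003", (1, 1), status=OverallStatus.COMPLETED, locations=(us,))
    )


class TestContactPlan:
    def _loc(self, city, lat, lon, with_contact=True, facility=None):
        return TrialLocation(
            facility=facility or f"{city} site",
            city=city,
            country="United States",
            latitude=lat,
            longitude=lon,
            contact=ContactInfo("X", phone="1") if with_contact else None,
        )

    def test_nearest_three_then_overall_then_backup(self):
        locs = (
            self._loc("Seattle", 47.61, -122.33),
            self._loc("Boston", 42.36, -71.06),
            self._loc("New York", 40.71, -74.01),
            self._loc("Chicago", 41.88, -87.63),
            self._loc("Philadelphia", 39.95, -75.17),
        )
        rec = _mk(
            "NCT00000001", (1, 1), locations=locs,
            overall=ContactInfo("O", phone="2"), backup=ContactInfo("B", email="b@x"),
        )
        plan = build_contact_plan(rec)
        assert [a.label for a in plan.attempts[:3]] == [
            "Boston site", "New York site", "Philadelphia site",
        ]
        assert [a.kind for a in plan.attempts] == [
            "location", "location", "location", "overall", "backup",
        ]
        assert plan.attempts[0].max_calls == 3 and plan.attempts[0].max_emails == 1

    def test_contactless_locations_are_skipped_not_counted(self):
        locs = (
            self._loc("Boston", 42.36, -71.06, with_contact=False),
            self._loc("Seattle", 47.61, -122.33),
        )
        rec = _mk("NCT00000001", (1, 1), locations=locs)
        plan = build_contact_plan(rec)
        assert [a.label for a in plan.attempts] == ["Seattle site"]

    def test_permutation_invariance_of_nearest_three(self):
        rng = np.random.default_rng(3)
        locs = [
            self._loc(f"c{i}", float(rng.uniform(25, 48)), float(rng.uniform(-124, -67)))
            for i in range(6)
        ]
        rec1 = _mk("NCT00000001", (1, 1), locations=tuple(locs))
        rec2 = _mk("NCT00000001", (1, 1), locations=tuple(reversed(locs)))
        p1 = build_contact_plan(rec1)
        p2 = build_contact_plan(rec2)
        assert [a.label for a in p1.attempts] == [a.label for a in p2.attempts]

    def test_no_contacts_anywhere_yields_empty_plan(self):
        rec = _mk("NCT00000001", (1, 1))
        assert build_contact_plan(rec).attempts == ()


class TestClassifyOutcome:
    def test_first_informative_wins(self):
        o = classify_outcome(
            "NCT00000001",
            [AttemptResult(ResponseKind.UNREACHABLE), AttemptResult(ResponseKind.CONFIRMED_OPEN)],
        )
        assert o.category is OutcomeCategory.OPEN and o.attempts_used == 2

    def test_refusal_without_later_answer_is_dont_know(self):
        o = classify_outcome(
            "NCT00000001",
            [AttemptResult(ResponseKind.REFUSED), AttemptResult(ResponseKind.UNREACHABLE)],
        )
        assert o.category is OutcomeCategory.DONT_KNOW

    def test_refusal_then_informative_answer_wins(self):
        close = FuzzyDate(2013, 1, None, DatePrecision.MONTH)
        o = classify_outcome(
            "NCT00000001",
            [
                AttemptResult(ResponseKind.REFUSED),
                AttemptResult(ResponseKind.CONFIRMED_CLOSED, date=close),
            ],
        )
        assert o.category is OutcomeCategory.CLOSED and o.close_date == close

    def test_empty_plan_is_no_answer(self):
        o = classify_outcome("NCT00000001", [])
        assert o.category is OutcomeCategory.NO_ANSWER and o.attempts_used == 0


def test_followup_table_conserves_n(default_corpus):
    corpus, truth = default_corpus
    _, outcomes, table = run_followup_study(corpus, truth, seed=17)
    for tag, outs in outcomes.items():
        cats = [c.value for c in OutcomeCategory]
        assert table.loc[tag, cats].sum() == len(outs)
    assert table.loc["overall", "n"] == sum(len(o) for o in outcomes.values())


def test_followup_noiseless_limit_recovers_true_status(default_corpus):
    corpus, truth = default_corpus
    params = FollowupParams(p_contactable=1.0, p_refuse=0.0, p_knows=1.0)
    _, outcomes, _ = run_followup_study(corpus, truth, seed=3, params=params)
    checked = 0
    for outs in outcomes.values():
        for o in outs:
            expected = truth.trials[o.nct_id].true_status
            if o.category is OutcomeCategory.NO_ANSWER:
                # only possible when the record carries no contact info at all
                rec = next(r for r in corpus.records if r.nct_id == o.nct_id)
                assert not build_contact_plan(rec).attempts
            else:
                assert o.category.value == expected
                checked += 1
    assert checked > 100


def test_followup_unreachable_limit_all_no_answer(default_corpus):
    corpus, truth = default_corpus
    params = FollowupParams(p_contactable=0.0)
    _, outcomes, table = run_followup_study(corpus, truth, seed=3, params=params)
    assert all(
        o.category is OutcomeCategory.NO_ANSWER for outs in outcomes.values() for o in outs
    )
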