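import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmburden import (
    CaseStatus,
    ClaimEvent,
    ClaimRecord,
    RunConfig,
    build_transition_table,
    classify_cases,
    compute_person_time,
    estimate_rate,
    pool_cohorts,
    probability_to_rate,
    rate_to_probability,
    smooth_by_neighbor,
    substitute_mortality,
)
from dmburden.claims import ClaimsError, records_to_frame, resolve_death_date


class TestRateProbabilityConversion:
    def test_known_values(self):
        assert rate_to_probability(0.0, 1.0) == 0.0
        assert rate_to_probability(-np.log(0.9), 1.0) == pytest.approx(0.1)
        assert rate_to_probability(0.05, 2.0) == pytest.approx(rate_to_probability(0.10, 1.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ClaimsError, match="negative rate"):
            rate_to_probability(-0.1)

    @given(r=st.floats(0.0, 10.0), t=st.floats(0.01, 1.0))
    def test_probability_bounded_and_inverse_consistent(self, r, t):
        p = rate_to_probability(r, t)
        assert 0.0 <= p < 1.0
        assert probability_to_rate(p, t) == pytest.approx(r, rel=1e-9, abs=1e-9)

    @given(r=st.floats(0.001, 5.0))
    def test_strictly_increasing_in_rate(self, r):
        assert rate_to_probability(r + 0.001) > rate_to_probability(r)


class TestRateEstimation:
    def test_events_over_person_years(self):
        est = estimate_rate(5, 50)
        assert est.rate == pytest.approx(0.1)
        assert estimate_rate(0, 50).probability == 0.0
        assert estimate_rate(10, 10).probability == pytest.approx(1 - np.exp(-1.0))

    def test_no_exposure_is_an_error(self):
        with pytest.raises(ClaimsError, match="no exposure"):
            estimate_rate(1, 0.0)

    def test_pooling_sums_before_dividing(self):
        assert pool_cohorts([(1, 10), (2, 20), (3, 30)]).rate == pytest.approx(0.1)
        assert pool_cohorts([(5, 50)]).rate == estimate_rate(5, 50).rate
        # zero-event cohorts keep their person-time in the denominator
        assert pool_cohorts([(0, 10), (1, 10)]).rate == pytest.approx(0.05)
        with pytest.raises(ClaimsError, match="nothing to pool"):
            pool_cohorts([])

    def test_pooling_is_order_invariant(self):
        cohorts = [(0, 10), (3, 7), (1, 30), (2, 2)]
        a = pool_cohorts(cohorts).rate
        b = pool_cohorts(list(reversed(cohorts))).rate
        assert a == pytest.approx(b)


class TestSmoothing:
    @staticmethod
    def _ests(pairs):
        return [
            estimate_rate(e, py, transition="x") if py > 0
            else pytest.fail("toy estimates need exposure")
            for e, py in pairs
        ]

    def test_deficient_group_merges_with_older_neighbor(self):
        ests = self._ests([(0, 10.0), (12, 10.0), (15, 10.0)])
        out, merged = smooth_by_neighbor(ests, min_events=5)
        assert merged == [(0, 1)]
        assert out[0].rate == out[1].rate == pytest.approx(12 / 20)
        assert out[2].rate == pytest.approx(1.5)

    def test_no_op_when_all_groups_sufficient(self):
        ests = self._ests([(6, 10.0), (7, 10.0)])
        out, merged = smooth_by_neighbor(ests, min_events=5)
        assert merged == []
        assert [e.rate for e in out] == [0.6, 0.7]

    def test_exhaustive_merge_when_total_is_deficient(self):
        ests = self._ests([(1, 10.0), (1, 10.0), (1, 10.0)])
        out, merged = smooth_by_neighbor(ests, min_events=5)
        assert merged == [(0, 1, 2)]
        assert all(e.rate == pytest.approx(0.1) for e in out)

    def test_relabeling_of_ages_commutes_with_merging(self):
        # mirror-symmetric inputs give mirror-symmetric pooled rates
        pairs = [(0, 5.0), (9, 10.0), (9, 10.0), (0, 5.0)]
        out, _ = smooth_by_neighbor(self._ests(pairs), min_events=5)
        rev, _ = smooth_by_neighbor(self._ests(pairs[::-1]), min_events=5)
        assert [e.rate for e in out] == pytest.approx([e.rate for e in rev][::-1])


class TestMortalitySubstitution:
    def test_general_floor_for_other_causes(self):
        assert substitute_mortality(0.001, 0.005, "50-54", cause="other") == 0.005
        assert substitute_mortality(0.010, 0.005, "50-54", cause="other") == 0.010

    def test_zero_rule_in_youngest_group(self):
        assert substitute_mortality(0.0, 0.0008, "30-34", cause="dm") == 0.0008
        assert substitute_mortality(0.002, 0.0008, "30-34", cause="dm") == 0.002
        assert substitute_mortality(0.0, 0.0008, "35-39", cause="dm") == 0.0

    @given(m=st.floats(0, 1), g=st.floats(0, 1))
    def test_never_decreases_other_cause_mortality(self, m, g):
        assert substitute_mortality(m, g, "60-64", cause="other") >= m


def _record(pid, sex, birth, events):
    return ClaimRecord(pid, sex, dt.date(*birth), [ClaimEvent(dt.date(*d), c, p) for d, c, p in events])


class TestPersonTime:
    def test_month_precision_death_resolves_to_month_end(self):
        assert resolve_death_date(dt.date(2015, 12, 1), "month") == dt.date(2015, 12, 31)
        assert resolve_death_date(dt.date(2016, 2, 5), "month") == dt.date(2016, 2, 29)
        assert resolve_death_date(dt.date(2015, 12, 14), "day") == dt.date(2015, 12, 14)

    def test_complication_to_death_worked_example(self):
        """A complication indexed 2014-06-01 with death in December 2015
        yields 578 person-days = 1.583... person-years in the complication
        state (the death month resolving to 2015-12-31)."""
        rec = _record(1, "male", (1950, 3, 1), [
            ((2014, 1, 10), "t2dm_dx", "day"),
            ((2014, 6, 1), "complication_ecode", "day"),
            ((2015, 12, 1), "death_dm", "month"),
        ])
        status = CaseStatus(1, "incident", dt.date(2014, 1, 10))
        spells = compute_person_time(status, rec, window_end=dt.date(2016, 12, 31))
        assert spells["Ci"].person_days == 578
        assert spells["Ci"].person_years == pytest.approx(578 / 365)
        assert spells["Ci"].terminal == "dthdm"
        assert spells["Di"].terminal == "ci"

    def test_degenerate_durations(self):
        rec = _record(2, "male", (1950, 1, 1), [((2016, 1, 1), "t2dm_dx", "day")])
        status = CaseStatus(2, "incident", dt.date(2016, 1, 1))
        same_day = compute_person_time(status, rec, window_end=dt.date(2016, 1, 1))
        assert same_day["Di"].person_days == 0
        year = compute_person_time(status, rec, window_end=dt.date(2016, 12, 31))
        assert year["Di"].person_days == 365
        assert year["Di"].person_years == pytest.approx(1.0)

    def test_totals_match_per_person_brute_force(self):
        rng = np.random.default_rng(7)
        records, statuses = [], []
        for pid in range(30):
            idx = dt.date(2016, 1, 1) + dt.timedelta(days=int(rng.integers(0, 300)))
            events = [((idx.year, idx.month, idx.day), "t2dm_dx", "day")]
            if rng.random() < 0.5:
                cd = idx + dt.timedelta(days=int(rng.integers(1, 200)))
                events.append(((cd.year, cd.month, cd.day), "complication_ecode", "day"))
            rec = _record(pid, "male", (1950, 1, 1), events)
            records.append(rec)
            statuses.append(CaseStatus(pid, "incident", idx))
        window_end = dt.date(2016, 12, 31)
        total = sum(
            sp.person_days
            for st_, rec in zip(statuses, records)
            for sp in compute_person_time(st_, rec, window_end).values()
        )
        brute = 0
        for st_, rec in zip(statuses, records):
            comp = next((e.date for e in rec.events if e.event_class.startswith("comp")), None)
            if comp is None or comp > window_end:
                brute += (window_end - st_.index_date).days
            else:
                brute += (comp - st_.index_date).days + (window_end - comp).days
        assert total == brute


class TestClassification:
    def test_clean_washout_yields_incident(self):
        recs = [_record(1, "male", (1970, 1, 1), [((2016, 3, 15), "t2dm_dx", "day")])]
        (status,) = classify_cases(recs, 2016, washout_years=3)
        assert status.status == "incident"
        assert status.index_date == dt.date(2016, 3, 15)

    def test_prior_use_yields_existing_prevalent(self):
        recs = [_record(1, "male", (1970, 1, 1), [
            ((2014, 5, 2), "t2dm_dx", "day"),
            ((2016, 3, 15), "t2dm_dx", "day"),
        ])]
        (status,) = classify_cases(recs, 2016)
        assert status.status == "existing_prevalent"
        assert status.index_date == dt.date(2016, 1, 1)

    def test_ecode_at_diagnosis_reclassified_as_prevalent_with_complications(self):
        recs = [_record(1, "female", (1970, 1, 1), [
            ((2016, 3, 15), "t2dm_dx", "day"),
            ((2016, 3, 15), "complication_ecode", "day"),
        ])]
        (status,) = classify_cases(recs, 2016)
        assert status.status == "existing_prevalent"
        assert status.with_complications

    def test_short_history_is_an_error(self):
        recs = [_record(1, "male", (1970, 1, 1), [((2016, 3, 15), "t2dm_dx", "day")])]
        with pytest.raises(ClaimsError, match="insufficient history"):
            classify_cases(recs, 2016, washout_years=3, window_start=dt.date(2014, 1, 1))

    def test_over60_complication_in_young_person_is_ignored(self):
        recs = [_record(1, "male", (1980, 1, 1), [
            ((2013, 3, 1), "t2dm_dx", "day"),
            ((2015, 6, 1), "complication_over60", "day"),  # aged 35: not a complication
        ])]
        (status,) = classify_cases(recs, 2016)
        assert not status.with_complications


class TestBuildTransitionTable:
    def test_empty_records_rejected(self, config):
        import pandas as pd

        empty = pd.DataFrame(columns=["person_id", "sex", "birth_date",
                                      "event_date", "event_class", "date_precision"])
        with pytest.raises(ClaimsError, match="no cases"):
            build_transition_table(empty, 2016, config)

    def test_eventless_cohort_yields_zero_probabilities(self, config):
        recs = [
            _record(pid, sex, (1950, 1, 1), [((2016, 2, 1), "t2dm_dx", "day")])
            for pid, sex in enumerate(["male", "female"] * 10)
        ]
        tbl = build_transition_table(records_to_frame(recs), 2016, config)
        assert (tbl.df.to_numpy() == 0.0).all()

    def test_duration_assumption_shifts_reverse_case_person_time(self):
        """A pre-diagnosis over-60 complication claim (reverse transition)
        contributes more diabetes-state and less complication-state time
        under the 365-day assumption than under the same-day one."""
        recs = [_record(1, "male", (1950, 1, 1), [
            ((2015, 6, 1), "complication_over60", "day"),   # aged 65: history of IHD
            ((2016, 2, 1), "t2dm_dx", "day"),
            ((2016, 11, 1), "death_dm", "month"),
        ])]
        window_end = dt.date(2016, 12, 31)
        (status,) = classify_cases(recs, 2016)
        assert status.status == "incident"
        short = compute_person_time(status, recs[0], window_end, duration_days=0)
        long = compute_person_time(status, recs[0], window_end, duration_days=365)
        # event counts are invariant; only the person-time split moves
        assert short["Di"].terminal == long["Di"].terminal == "ci"
        assert short["Ci"].terminal == long["Ci"].terminal == "dthdm"
        assert short["Di"].person_days == 0
        assert short["Ci"].person_days == 303     # 2016-02-01 .. 2016-11-30
        # the assumed index is capped at the death date
        assert long["Di"].person_days == 303
        assert long["Ci"].person_days == 0
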