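"""Continuum definitions: eligibility, retention, ART, suppression, LTFU,
care-site classification, and their boundary conventions."""

from datetime import date, timedelta

import pytest

from registrylink.continuum import (
    AnalysisWindow,
    SiteCategory,
    classify_care_sites,
    compute_status,
    encounter_dates,
    ever_suppressed,
    filter_eligible,
    is_ltfu,
    on_art,
    retained_in_care,
    virally_suppressed,
)
from registrylink.reconcile import reconcile_person
from registrylink.synth import SimConfig, generate_population, truth_record
from registrylink.types import (
    ArtPrescription,
    CohortRecord,
    LabResult,
    Origin,
    PersonIdentity,
    Race,
    Sex,
    State,
    TestType,
    Visit,
)

WINDOW = AnalysisWindow()


def _vl(value, when, origin=Origin.COHORT, facility="SITE01", below=False):
    return LabResult(TestType.VL, value, when, facility, origin, below)


def _record(**kw):
    base = dict(
        study_id="C1", enrollment_site="SITE01", enrollment_date=date(2012, 1, 1),
        identity=PersonIdentity("Ann", "Lee", date(1980, 1, 1), Sex.FEMALE),
        race_ethnicity=Race.NH_BLACK, state_of_residence=State.DC,
    )
    base.update(kw)
    return reconcile_person(CohortRecord(**base), None)


class TestEligibility:
    def test_withdrawn_excluded_with_reason(self):
        eligible, reasons = filter_eligible(
            [_record(withdrawn_date=date(2013, 5, 1))], WINDOW
        )
        assert eligible == [] and reasons["withdrawn"] == 1

    def test_enrollment_364_days_before_window_end_excluded(self):
        rec = _record(enrollment_date=WINDOW.end - timedelta(days=364))
        eligible, reasons = filter_eligible([rec], WINDOW)
        assert eligible == [] and reasons["insufficient_followup"] == 1

    def test_enrollment_365_days_before_window_end_eligible(self):
        rec = _record(enrollment_date=WINDOW.end - timedelta(days=365))
        eligible, _ = filter_eligible([rec], WINDOW)
        assert len(eligible) == 1

    def test_tally_matches_generator_truth(self):
        """Exclusion counts equal what the generator bookkeeping implies."""
        cfg = SimConfig(n_persons=500, seed=31)
        population = generate_population(cfg)
        records = [truth_record(p) for p in population]
        eligible, reasons = filter_eligible(records, cfg.window)
        expect = {"withdrawn": 0, "transferred": 0, "died_before_window": 0,
                  "insufficient_followup": 0}
        cutoff = cfg.window.end - timedelta(days=365)
        for p in population:
            if p.withdrawn_date is not None:
                expect["withdrawn"] += 1
            elif p.transferred_date is not None:
                expect["transferred"] += 1
            elif p.death_date is not None and p.death_date < cfg.window.start:
                expect["died_before_window"] += 1
            elif p.enrollment_date > cutoff:
                expect["insufficient_followup"] += 1
        assert dict(reasons) == {k: v for k, v in expect.items() if v}
        assert len(eligible) == len(population) - sum(expect.values())


class TestRetention:
    @pytest.mark.parametrize(
        "dates,expected",
        [
            ([date(2014, 7, 1), date(2014, 10, 15)], True),  # 106 days
            ([date(2014, 7, 1), date(2014, 9, 1)], False),  # 62 days
            ([date(2014, 7, 1), date(2014, 9, 29)], True),  # exactly 90 days
            ([date(2014, 7, 1), date(2014, 9, 28)], False),  # 89 days
            ([date(2014, 7, 1)], False),
            ([], False),
        ],
    )
    def test_gap_rule(self, dates, expected):
        assert retained_in_care(dates, WINDOW) is expected

    def test_same_date_counts_once(self):
        assert not retained_in_care([date(2014, 7, 1)] * 3, WINDOW)

    def test_events_outside_window_ignored(self):
        assert not retained_in_care(
            [date(2014, 1, 1), date(2014, 7, 1)], WINDOW
        )


class TestOnArt:
    def test_ongoing_prescription_overlaps(self):
        assert on_art([ArtPrescription(date(2013, 1, 1), None)], WINDOW)

    def test_ended_day_before_window(self):
        assert not on_art([ArtPrescription(date(2013, 1, 1), date(2014, 6, 14))], WINDOW)

    def test_starts_on_window_end_inclusive(self):
        assert on_art([ArtPrescription(date(2015, 6, 15), None)], WINDOW)


class TestViralSuppression:
    def test_suppressed_when_last_vl_low(self):
        assert virally_suppressed([_vl(50, date(2015, 5, 1))], True, True, WINDOW) is True

    @pytest.mark.parametrize("value,expected", [(199, True), (200, False), (201, False)])
    def test_strict_200_threshold(self, value, expected):
        assert virally_suppressed([_vl(value, date(2015, 5, 1))], True, True, WINDOW) is expected

    def test_only_last_vl_counts(self):
        labs = [_vl(50_000, date(2014, 1, 1)), _vl(40, date(2015, 2, 1))]
        assert virally_suppressed(labs, True, True, WINDOW) is True

    def test_undefined_outside_denominator(self):
        labs = [_vl(50, date(2015, 5, 1))]
        assert virally_suppressed(labs, False, True, WINDOW) is None
        assert virally_suppressed(labs, True, False, WINDOW) is None
        assert virally_suppressed([], True, True, WINDOW) is None

    def test_same_date_tie_prefers_cohort_then_lower(self):
        labs = [
            _vl(300, date(2015, 5, 1), Origin.SURVEILLANCE),
            _vl(150, date(2015, 5, 1), Origin.COHORT),
        ]
        assert virally_suppressed(labs, True, True, WINDOW) is True


class TestEverSuppressed:
    def test_single_low_vl(self):
        assert ever_suppressed([_vl(150, date(2013, 1, 1))], date(2012, 1, 1), WINDOW.as_of)

    def test_all_high(self):
        labs = [_vl(500, date(2013, 1, 1)), _vl(900, date(2014, 1, 1))]
        assert not ever_suppressed(labs, date(2012, 1, 1), WINDOW.as_of)

    def test_before_enrollment_ignored(self):
        assert not ever_suppressed([_vl(150, date(2011, 1, 1))], date(2012, 1, 1), WINDOW.as_of)


class TestLtfu:
    def test_exactly_18_months_inclusive(self):
        rec = _record(visits=[Visit(date(2013, 12, 15), "SITE01")])
        assert is_ltfu(rec, date(2015, 6, 15), 18).ltfu is True

    def test_17_months_not_ltfu(self):
        rec = _record(visits=[Visit(date(2014, 1, 15), "SITE01")])
        assert is_ltfu(rec, date(2015, 6, 15), 18).ltfu is False

    def test_no_events_degenerate(self):
        status = is_ltfu(_record(), date(2015, 6, 15), 18)
        assert status.ltfu and status.degenerate

    def test_agrees_with_brute_force_scan(self):
        """Oracle: LTFU iff no single event date falls after the anchor."""
        from dateutil.relativedelta import relativedelta

        cfg = SimConfig(n_persons=500, seed=37)
        anchor = cfg.window.as_of - relativedelta(months=18)
        for person in generate_population(cfg):
            rec = truth_record(person)
            dates = [v.visit_date for v in rec.visits] + [
                l.collection_date for l in rec.labs
            ]
            brute = not any(d > anchor for d in dates)
            assert is_ltfu(rec, cfg.window.as_of, 18).ltfu is (brute or not dates)


class TestSiteClassification:
    def test_all_labs_from_enrollment_site(self):
        labs = [_vl(50, date(2014, 1, 1), facility="A")] * 3
        assert classify_care_sites(labs, "A") is SiteCategory.ONE

    def test_no_labs_is_one_site(self):
        assert classify_care_sites([], "A") is SiteCategory.ONE

    def test_one_external_lab_is_two_sites(self):
        labs = [
            _vl(50, date(2014, 1, 1), facility="A"),
            _vl(50, date(2014, 2, 1), facility="B"),
        ]
        assert classify_care_sites(labs, "A") is SiteCategory.TWO

    def test_two_labs_two_other_sites_is_three_plus(self):
        labs = [
            _vl(50, date(2014, 1, 1), facility="B"),
            _vl(50, date(2014, 2, 1), facility="C"),
        ]
        assert classify_care_sites(labs, "A") is SiteCategory.THREE_PLUS

    def test_two_labs_same_other_site_is_two(self):
        labs = [
            _vl(50, date(2014, 1, 1), facility="B"),
            _vl(50, date(2014, 2, 1), facility="B"),
        ]
        assert classify_care_sites(labs, "A") is SiteCategory.TWO


class TestMonotonicity:
    def test_augmentation_never_worsens_flags(self, small_pipeline):
        """Adding the surveillance contribution never flips RIC or ever-VS
        true -> false and never moves the site category toward 'one'."""
        rank = {SiteCategory.ONE: 0, SiteCategory.TWO: 1, SiteCategory.THREE_PLUS: 2}
        post = {s.study_id: s for s in small_pipeline.statuses_post}
        for pre in small_pipeline.statuses_pre:
            after = post[pre.study_id]
            assert not (pre.ric and not after.ric)
            assert not (pre.ever_vs and not after.ever_vs)
            assert rank[after.site_category] >= rank[pre.site_category]

    def test_empty_surveillance_contribution_reproduces_pre(self, small_pipeline):
        """Post-linkage computation with no surveillance data is bit-for-bit
        the pre-linkage result."""
        for rec in small_pipeline.merged_pre[:50]:
            again = compute_status(rec, WINDOW)
            match = [s for s in small_pipeline.statuses_pre if s.study_id == rec.study_id]
            if match:
                assert again == match[0]

    def test_vs_denominator_bookkeeping(self, small_pipeline):
        for status in small_pipeline.statuses_post:
            if status.vs is not None:
                assert status.ric and status.on_art
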