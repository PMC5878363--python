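"""Per-person HIV care-continuum outcomes and care-site classification.

Definitions: retention in care (RIC) is >=2 HIV-related encounters (visits
or labs) at least 90 days apart within the analysis window; on-ART is any
prescription interval overlapping the window (prescriptions come from the
cohort source only); viral suppression (VS) is last viral load on file
<200 copies/mL, evaluated only among persons retained and on ART with at
least one VL; ever-VS is any VL <200 since enrollment.  Care-site category
counts the distinct facilities a person's labs came from, relative to their
enrollment site.

Boundary conventions (the source definitions leave these open; fixed here):
"at least 90 days apart" is inclusive (>=90); window endpoints inclusive;
loss to follow-up at exactly 18 calendar months is inclusive; two encounters
on the same date count once.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, NamedTuple, Sequence

from dateutil.relativedelta import relativedelta

from .reconcile import MergedRecord
from .types import ArtPrescription, LabResult, Origin, TestType, Vital


@dataclass(frozen=True)
class AnalysisWindow:
    """The 12-month outcome window and the LTFU look-back anchor."""

    start: date = date(2014, 6, 15)
    end: date = date(2015, 6, 15)
    min_gap_days: int = 90
    ltfu_months: int = 18
    as_of: date = date(2015, 6, 15)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")
        if self.min_gap_days > (self.end - self.start).days:
            raise ValueError("min_gap_days exceeds window length")


class SiteCategory(str, enum.Enum):
    ONE = "one"
    TWO = "two"
    THREE_PLUS = "three_plus"


class LtfuStatus(NamedTuple):
    ltfu: bool
    degenerate: bool  # no dated events at all


@dataclass
class ContinuumStatus:
    study_id: str
    eligible: bool
    ric: bool
    on_art: bool
    vs: bool | None  # None = not in the VS denominator
    ever_vs: bool
    ltfu: bool
    ltfu_degenerate: bool
    site_category: SiteCategory


def filter_eligible(
    records: Sequence[MergedRecord], window: AnalysisWindow
) -> tuple[list[MergedRecord], Counter]:
    """Active, non-withdrawn, non-transferred, alive-at-window-start persons
    with at least one year of follow-up by window end.

    Returns the eligible subset and a tally of exclusion reasons (first
    matching reason per person, checked in a fixed order).
    """
    eligible: list[MergedRecord] = []
    reasons: Counter = Counter()
    followup_cutoff = window.end - timedelta(days=365)
    for rec in records:
        if rec.withdrawn_date is not None:
            reasons["withdrawn"] += 1
        elif rec.transferred_date is not None:
            reasons["transferred"] += 1
        elif rec.vital_status is Vital.DECEASED and (
            rec.death_date is None or rec.death_date < window.start
        ):
            reasons["died_before_window"] += 1
        elif rec.enrollment_date > followup_cutoff:
            reasons["insufficient_followup"] += 1
        else:
            eligible.append(rec)
    return eligible, reasons


def encounter_dates(record: MergedRecord) -> list[date]:
    """Deduplicated dates of HIV-related encounters (visits and labs)."""
    dates = {v.visit_date for v in record.visits}
    dates.update(l.collection_date for l in record.labs)
    return sorted(dates)


def is_ltfu(record: MergedRecord, as_of: date, ltfu_months: int = 18) -> LtfuStatus:
    """Lost to follow-up: no lab or visit within ltfu_months calendar months
    of as_of (inclusive at exactly the boundary).  A person with no dated
    events at all is LTFU and flagged degenerate."""
    dates = encounter_dates(record)
    if not dates:
        return LtfuStatus(True, True)
    anchor = as_of - relativedelta(months=ltfu_months)
    return LtfuStatus(max(dates) <= anchor, False)


def retained_in_care(events: Iterable[date], window: AnalysisWindow) -> bool:
    """Two encounter dates within the window at least min_gap_days apart."""
    in_window = sorted({d for d in events if window.start <= d <= window.end})
    return bool(in_window) and (in_window[-1] - in_window[0]).days >= window.min_gap_days


def on_art(prescriptions: Iterable[ArtPrescription], window: AnalysisWindow) -> bool:
    """Any prescription interval overlapping the window (inclusive ends;
    open-ended prescriptions overlap iff they start by window end)."""
    for rx in prescriptions:
        if rx.start <= window.end and (rx.end is None or rx.end >= window.start):
            return True
    return False


def _last_vl(labs: Sequence[LabResult], cutoff: date) -> LabResult | None:
    """Latest VL on file by the cutoff; same-date ties keep the cohort-origin
    value, then the lower value (documented tie-break)."""
    vls = [l for l in labs if l.test_type is TestType.VL and l.collection_date <= cutoff]
    if not vls:
        return None
    return max(
        vls,
        key=lambda l: (
            l.collection_date,
            0 if l.origin is Origin.COHORT else -1,  # cohort outranks surveillance
            -l.value,  # then the lower value wins
        ),
    )


def virally_suppressed(
    labs: Sequence[LabResult], ric: bool, art: bool, window: AnalysisWindow
) -> bool | None:
    """Last VL on file <200 copies/mL among persons retained and on ART.

    Returns None (not in the denominator) unless ric and art hold and at
    least one VL is on file by window end.
    """
    if not (ric and art):
        return None
    last = _last_vl(labs, window.end)
    if last is None:
        return None
    return last.suppressed


def ever_suppressed(labs: Sequence[LabResult], enrollment_date: date, as_of: date) -> bool:
    """Any VL <200 copies/mL dated between enrollment and as_of."""
    return any(
        l.test_type is TestType.VL
        and enrollment_date <= l.collection_date <= as_of
        and l.suppressed
        for l in labs
    )


def classify_care_sites(labs: Sequence[LabResult], enrollment_site: str) -> SiteCategory:
    """Care-site category from lab source facilities.

    one: all labs (or none) from the enrollment site; three_plus: >=2 labs
    from >=2 distinct non-enrollment facilities; two: otherwise.
    """
    external = [l for l in labs if l.source_facility != enrollment_site]
    if not external:
        return SiteCategory.ONE
    facilities = {l.source_facility for l in external}
    if len(external) >= 2 and len(facilities) >= 2:
        return SiteCategory.THREE_PLUS
    return SiteCategory.TWO


def compute_status(record: MergedRecord, window: AnalysisWindow, eligible: bool = True) -> ContinuumStatus:
    """All continuum flags for one person on one (pre- or post-linkage) dataset."""
    events = encounter_dates(record)
    ric = retained_in_care(events, window)
    art = on_art(record.art_prescriptions, window)
    vs = virally_suppressed(record.labs, ric, art, window)
    ever = ever_suppressed(record.labs, record.enrollment_date, window.as_of)
    ltfu = is_ltfu(record, window.as_of, window.ltfu_months)
    return ContinuumStatus(
        study_id=record.study_id,
        eligible=eligible,
        ric=ric,
        on_art=art,
        vs=vs,
        ever_vs=ever,
        ltfu=ltfu.ltfu,
        ltfu_degenerate=ltfu.degenerate,
        site_category=classify_care_sites(record.labs, record.enrollment_site),
    )


def compute_statuses(
    records: Sequence[MergedRecord], window: AnalysisWindow
) -> tuple[list[ContinuumStatus], Counter]:
    """Eligibility filter + per-person continuum flags for a whole dataset."""
    eligible, reasons = filter_eligible(records, window)
    statuses = [compute_status(rec, window) for rec in eligible]
    return statuses, reasons
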