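"""Post-linkage reconciliation of matched cohort + surveillance records.

Field rules: the earlier HIV/AIDS diagnosis date wins regardless of source;
vital status is deceased if either source says so; transmission risk is
reconciled through the CDC-style hierarchy; demographics prefer the cohort
value when sources conflict (conflict recorded in provenance).  Laboratory
results from the two sources are deduplicated with a fuzzy date/value rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Sequence

from .types import (
    ArtPrescription,
    CohortRecord,
    LabResult,
    Origin,
    PersonIdentity,
    Race,
    Risk,
    DEFAULT_RISK_HIERARCHY,
    State,
    StdEvent,
    SurveillanceRecord,
    TestType,
    Visit,
    Vital,
)


@dataclass(frozen=True)
class FuzzyLabRule:
    """Tolerances under which two labs are considered the same measurement.

    Two results collapse iff they share a test type, their dates differ by
    at most ``date_window_days``, and their values agree: viral loads within
    ``vl_log10_tolerance`` on the log10 scale (or both below 200 copies/mL,
    which covers below-detection codings), CD4 within ``cd4_abs_tolerance``
    cells/mm3.
    """

    date_window_days: int = 7
    vl_log10_tolerance: float = 0.1
    cd4_abs_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.date_window_days < 0 or self.vl_log10_tolerance < 0 or self.cd4_abs_tolerance < 0:
            raise ValueError("tolerances must be non-negative")

    def values_match(self, a: LabResult, b: LabResult) -> bool:
        if a.test_type is TestType.CD4:
            return abs(a.value - b.value) <= self.cd4_abs_tolerance
        a_supp = a.below_detection or a.value < 200
        b_supp = b.below_detection or b.value < 200
        if a_supp and b_supp:
            return True
        if a.value <= 0 or b.value <= 0:
            return False
        return abs(math.log10(a.value / b.value)) <= self.vl_log10_tolerance


def dedup_labs(labs: Iterable[LabResult], rule: FuzzyLabRule | None = None) -> list[LabResult]:
    """Collapse fuzzy-duplicate labs across sources for one person.

    Greedy chronological pass per test type: each lab either merges into an
    already-kept lab it matches (keeping the earlier date; the cohort-origin
    value wins when origins differ) or starts a new kept lab.  Deterministic:
    input order is irrelevant because labs are sorted first (date, then
    cohort before surveillance, then value).
    """
    rule = rule or FuzzyLabRule()
    order = sorted(
        labs,
        key=lambda l: (
            l.test_type.value,
            l.collection_date,
            0 if l.origin is Origin.COHORT else 1,
            l.value,
            l.source_facility,
        ),
    )
    kept: list[LabResult] = []
    for lab in order:
        merged = False
        for i, base in enumerate(kept):
            if base.test_type is not lab.test_type:
                continue
            if abs((lab.collection_date - base.collection_date).days) > rule.date_window_days:
                continue
            if not rule.values_match(base, lab):
                continue
            # base is the earlier lab (sorted); prefer the cohort value
            if base.origin is Origin.SURVEILLANCE and lab.origin is Origin.COHORT:
                kept[i] = replace(
                    lab, collection_date=base.collection_date, origin=Origin.COHORT
                )
            merged = True
            break
        if not merged:
            kept.append(lab)
    kept.sort(key=lambda l: (l.test_type.value, l.collection_date, l.value))
    return kept


def reconcile_risk(
    risks: Sequence[Risk], hierarchy: Sequence[Risk] = DEFAULT_RISK_HIERARCHY
) -> Risk:
    """Highest-priority reported category; never synthesizes a category.

    Order-independent and idempotent.  E.g. {msm, idu} resolves to idu under
    the default hierarchy — msm_idu is returned only if a source recorded it.
    """
    if not risks:
        raise ValueError("at least one risk category required")
    rank = {r: i for i, r in enumerate(hierarchy)}
    return min(risks, key=lambda r: rank[r])


@dataclass
class MergedRecord:
    """The reconciled post-linkage view of one person.

    ``provenance`` maps field name -> "cohort" | "surveillance" | "both" |
    "both_conflict" (cohort value kept).  ``review_flags`` lists fields whose
    conflict requires manual review (e.g. sex at birth, a matching variable).
    """

    study_id: str
    ehars_id: str | None
    identity: PersonIdentity
    enrollment_site: str
    enrollment_date: date
    race_ethnicity: Race
    state_of_residence: State
    transmission_risk: Risk | None
    hiv_dx_date: date | None
    aids_ever: bool
    aids_dx_date: date | None
    oi_at_aids: bool | None
    vital_status: Vital
    death_date: date | None
    withdrawn_date: date | None
    transferred_date: date | None
    labs: list[LabResult]
    art_prescriptions: list[ArtPrescription]
    std_events: list[StdEvent]
    visits: list[Visit]
    provenance: dict[str, str] = field(default_factory=dict)
    review_flags: list[str] = field(default_factory=list)


def _earlier(a: date | None, b: date | None) -> date | None:
    if a is None:
        return b
    if b is None:
        return a
    return min(a, b)


def reconcile_person(
    cohort: CohortRecord,
    surveillance: SurveillanceRecord | None,
    lab_rule: FuzzyLabRule | None = None,
    risk_hierarchy: Sequence[Risk] = DEFAULT_RISK_HIERARCHY,
) -> MergedRecord:
    """Merge one matched pair (or pass through an unmatched cohort person)."""
    prov: dict[str, str] = {}
    reviews: list[str] = []

    if surveillance is None:
        merged = MergedRecord(
            study_id=cohort.study_id,
            ehars_id=None,
            identity=cohort.identity,
            enrollment_site=cohort.enrollment_site,
            enrollment_date=cohort.enrollment_date,
            race_ethnicity=cohort.race_ethnicity,
            state_of_residence=cohort.state_of_residence,
            transmission_risk=cohort.transmission_risk,
            hiv_dx_date=cohort.hiv_dx_date,
            aids_ever=cohort.aids_ever,
            aids_dx_date=cohort.aids_dx_date,
            oi_at_aids=cohort.oi_at_aids,
            vital_status=cohort.vital_status,
            death_date=cohort.death_date,
            withdrawn_date=cohort.withdrawn_date,
            transferred_date=cohort.transferred_date,
            labs=dedup_labs(cohort.labs, lab_rule),
            art_prescriptions=list(cohort.art_prescriptions),
            std_events=list(cohort.std_events),
            visits=list(cohort.visits),
        )
        merged.provenance = {"all": "cohort"}
        return merged

    if cohort.identity.sex_at_birth != surveillance.identity.sex_at_birth:
        reviews.append("sex_at_birth")

    # demographics: cohort value wins, conflicts logged
    for fname, cval, sval in (
        ("race_ethnicity", cohort.race_ethnicity, None),
        ("state_of_residence", cohort.state_of_residence, surveillance.state_of_residence),
    ):
        prov[fname] = "both_conflict" if (sval is not None and sval != cval) else "cohort"

    risks = [r for r in (cohort.transmission_risk, surveillance.transmission_risk) if r is not None]
    risk = reconcile_risk(risks, risk_hierarchy) if risks else None
    prov["transmission_risk"] = (
        "both" if len(risks) == 2 else ("cohort" if cohort.transmission_risk else "surveillance")
    ) if risks else "none"

    hiv_dx = _earlier(cohort.hiv_dx_date, surveillance.hiv_dx_date)
    aids_dx = _earlier(cohort.aids_dx_date, surveillance.aids_dx_date)
    aids_ever = cohort.aids_ever or surveillance.aids_dx_date is not None
    oi_vals = [v for v in (cohort.oi_at_aids, surveillance.oi_at_aids) if v is not None]
    oi = (True in oi_vals) if oi_vals else None

    deceased = cohort.vital_status is Vital.DECEASED or surveillance.vital_status is Vital.DECEASED
    prov["vital_status"] = (
        "both"
        if cohort.vital_status == surveillance.vital_status
        else ("cohort" if cohort.vital_status is Vital.DECEASED else "surveillance")
    )

    labs = dedup_labs(list(cohort.labs) + list(surveillance.labs), lab_rule)

    merged = MergedRecord(
        study_id=cohort.study_id,
        ehars_id=surveillance.ehars_id,
        identity=cohort.identity,
        enrollment_site=cohort.enrollment_site,
        enrollment_date=cohort.enrollment_date,
        race_ethnicity=cohort.race_ethnicity,
        state_of_residence=cohort.state_of_residence,
        transmission_risk=risk,
        hiv_dx_date=hiv_dx,
        aids_ever=aids_ever,
        aids_dx_date=aids_dx,
        oi_at_aids=oi,
        vital_status=Vital.DECEASED if deceased else Vital.ALIVE,
        death_date=_earlier(cohort.death_date, surveillance.death_date),
        withdrawn_date=cohort.withdrawn_date,
        transferred_date=cohort.transferred_date,
        labs=labs,
        art_prescriptions=list(cohort.art_prescriptions),  # ART is cohort-only
        std_events=list(cohort.std_events),
        visits=list(cohort.visits),
        provenance=prov,
        review_flags=reviews,
    )
    return merged
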