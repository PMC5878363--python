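"""Synthetic dual-registry generator.

Draws a ground-truth population of persons in HIV care, then emits three
partially overlapping registry extracts derived from it — a clinical-cohort
extract, an HIV surveillance extract and an STD surveillance registry —
together with the true match set, so the linkage, reconciliation and
continuum stages can be verified end-to-end against known truth.

The two deliberate realism axes are identity corruption (misspellings,
nickname substitutions, surname changes, transposed day/month in the date
of birth, missing SSNs on the surveillance side) and differential capture
(surveillance rarely holds suppressed viral loads and misses non-resident
persons; the cohort misses most labs drawn at outside facilities).  Default
category frequencies follow the observed marginals of a large urban HIV
cohort: ~26% female, ~74% non-Hispanic black, ~74% in-jurisdiction
residents, ~77% receiving care at a single site, with per-stratum viral
suppression of 89.51% (one site) down to 72.3% (three or more sites).

Randomness is a single root seed with a documented per-person substream
derivation (generator seeded on ``[seed, person_uid, phase]``), so the
first k persons of a population are identical for any n >= k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np

from . import names
from .continuum import AnalysisWindow, SiteCategory
from .types import (
    ArtPrescription,
    CohortRecord,
    Disease,
    Employment,
    Housing,
    Insurance,
    LabResult,
    Origin,
    PersonIdentity,
    Race,
    Risk,
    Sex,
    State,
    StdEvent,
    StdRegistryRecord,
    SurveillanceRecord,
    TestType,
    Visit,
    Vital,
)

COHORT_SITES: tuple[str, ...] = tuple(f"SITE{i:02d}" for i in range(1, 14))
EXTERNAL_FACILITIES: tuple[str, ...] = tuple(f"EXT{i:02d}" for i in range(1, 13))


@dataclass(frozen=True)
class ErrorModel:
    """Per-field identity corruption probabilities (surveillance-side entry)."""

    p_typo_per_name: float = 0.05
    p_dob_day_month_swap: float = 0.02
    p_ssn_missing: float = 0.08
    p_nickname_substitution: float = 0.03
    p_last_name_change: float = 0.02

    def __post_init__(self) -> None:
        for name_, value in self.__dict__.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name_} must be a probability, got {value}")

    @classmethod
    def none(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CaptureModel:
    """Differential-capture probabilities for the two lab pipelines.

    Surveillance receives nearly all CD4 results but few suppressed viral
    loads; the cohort chart holds every enrollment-site lab but only a
    minority of outside labs.  Non-resident persons reach surveillance at a
    reduced rate.
    """

    p_surv_vl_capture_suppressed: float = 0.15
    p_surv_vl_capture_unsuppressed: float = 0.85
    p_surv_cd4_capture: float = 0.92
    p_nonresident_lab_reported: float = 0.75
    p_cohort_captures_external_lab: float = 0.25
    overlap_fraction: float = 0.99

    def __post_init__(self) -> None:
        for name_, value in self.__dict__.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name_} must be a probability, got {value}")


def _freq(counts: Sequence[int]) -> tuple[float, ...]:
    total = sum(counts)
    return tuple(c / total for c in counts)


@dataclass(frozen=True)
class Marginals:
    """Target category frequencies of the generated population."""

    # (female, male)
    sex: tuple[float, ...] = (1435 / 5521, 4086 / 5521)
    # (nh_black, nh_white, other_unknown)
    race: tuple[float, ...] = _freq((4069, 865, 587))
    # (DC, MD, VA, other)
    residence: tuple[float, ...] = _freq((4093, 1040, 314, 74))
    # (msm_idu, idu, msm, heterosexual, perinatal, other_unknown, missing)
    risk: tuple[float, ...] = _freq((75, 0, 2220, 1519, 223, 440, 1044))
    # (one, two, three_plus) care-site strata
    site_mixture: tuple[float, ...] = _freq((4242, 855, 424))
    # per-stratum probability of being a virally suppressed person
    suppression_by_stratum: tuple[float, ...] = (0.8951, 0.85, 0.723)

    def __post_init__(self) -> None:
        for name_ in ("sex", "race", "residence", "risk", "site_mixture"):
            vec = getattr(self, name_)
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"marginal {name_} must sum to 1, got {sum(vec)}")


@dataclass(frozen=True)
class SimConfig:
    n_persons: int = 2000
    seed: int = 0
    error_model: ErrorModel = field(default_factory=ErrorModel)
    capture_model: CaptureModel = field(default_factory=CaptureModel)
    marginals: Marginals = field(default_factory=Marginals)
    window: AnalysisWindow = field(default_factory=AnalysisWindow)


# conditional attribute tables by care-site stratum (one, two, three_plus)
_HOUSING_BY_STRATUM = {
    Housing.PERMANENT: (0.8121, 0.775, 0.738),
    Housing.TEMPORARY: (0.0785, 0.112, 0.130),
    Housing.HOMELESS: (0.0111, 0.012, 0.021),
    Housing.OTHER_UNKNOWN: (0.0983, 0.101, 0.111),
}
_EMPLOYMENT_BY_STRATUM = {
    Employment.FULL_TIME: (0.3112, 0.175, 0.066),
    Employment.PART_TIME: (0.0342, 0.033, 0.028),
    Employment.UNEMPLOYED: (0.2216, 0.316, 0.384),
    Employment.OTHER: (0.4330, 0.476, 0.522),
}
_INSURANCE_BY_STRATUM = {
    Insurance.PRIVATE: (0.3505, 0.208, 0.075),
    Insurance.PUBLIC: (0.5757, 0.719, 0.861),
    Insurance.OTHER: (0.0738, 0.073, 0.064),
}
_COMORBIDITY_BY_STRATUM = {
    "mental_health": (0.389, 0.509, 0.613),
    "hypertension": (0.2298, 0.305, 0.377),
    "cardiovascular": (0.156, 0.196, 0.257),
    "hepatitis_c": (0.0889, 0.149, 0.193),
    "diabetes": (0.0886, 0.135, 0.149),
}

_STRATA = (SiteCategory.ONE, SiteCategory.TWO, SiteCategory.THREE_PLUS)
# multi-site persons draw most encounters away from the enrollment site, so
# the cohort chart alone understates their care (the silent-transfer pattern)
_SITE_WEIGHTS = {SiteCategory.ONE: (1.0,), SiteCategory.TWO: (0.45, 0.55),
                 SiteCategory.THREE_PLUS: (0.30, 0.40, 0.30)}


@dataclass(frozen=True)
class TrueStdEvent:
    disease: Disease
    disease_date: date
    in_cohort: bool
    in_std_registry: bool


@dataclass
class TruePerson:
    """Ground truth for one person: clean identity, full care history, and
    the registry-membership facts the emitted extracts will only partially
    reflect."""

    person_uid: int
    identity: PersonIdentity
    race_ethnicity: Race
    state_of_residence: State
    resident: bool
    transmission_risk: Risk | None
    stratum: SiteCategory
    suppressed: bool
    engaged: bool
    housing: Housing
    employment: Employment
    insurance: Insurance
    comorbidities: set[str]
    enrollment_site: str
    care_sites: list[str]
    enrollment_date: date
    hiv_dx_date: date
    cohort_dx_date: date | None
    surv_has_dx: bool
    aids_ever: bool
    aids_dx_date: date | None
    oi_at_aids: bool | None
    cohort_knows_oi: bool
    surv_knows_oi: bool
    vital_status: Vital
    death_date: date | None
    cohort_knows_death: bool
    surv_knows_death: bool
    withdrawn_date: date | None
    transferred_date: date | None
    art_prescriptions: list[ArtPrescription]
    true_labs: list[LabResult]  # origin field is a placeholder until emission
    visits: list[Visit]
    std_events: list[TrueStdEvent]

    @property
    def study_id(self) -> str:
        return f"C{self.person_uid:06d}"

    @property
    def ehars_id(self) -> str:
        return f"E{self.person_uid:06d}"

    @property
    def std_id(self) -> str:
        return f"X{self.person_uid:06d}"


@dataclass
class TruthSet:
    """All cross-registry pairs that denote the same person, plus per-person
    ground truth keyed by study_id."""

    hiv_pairs: set[tuple[str, str]]
    std_pairs: set[tuple[str, str]]
    persons: dict[str, TruePerson]


def truth_record(person: TruePerson):
    """Project a TruePerson onto the complete (oracle) post-linkage record:
    every true lab, visit and STD event with no capture loss or identity
    corruption.  Continuum metrics computed on this record are the
    generator-truth values the observable pipeline tries to recover."""
    from .reconcile import MergedRecord

    return MergedRecord(
        study_id=person.study_id,
        ehars_id=person.ehars_id,
        identity=person.identity,
        enrollment_site=person.enrollment_site,
        enrollment_date=person.enrollment_date,
        race_ethnicity=person.race_ethnicity,
        state_of_residence=person.state_of_residence,
        transmission_risk=person.transmission_risk,
        hiv_dx_date=person.hiv_dx_date,
        aids_ever=person.aids_ever,
        aids_dx_date=person.aids_dx_date,
        oi_at_aids=person.oi_at_aids,
        vital_status=person.vital_status,
        death_date=person.death_date,
        withdrawn_date=person.withdrawn_date,
        transferred_date=person.transferred_date,
        labs=list(person.true_labs),
        art_prescriptions=list(person.art_prescriptions),
        std_events=[
            StdEvent(person.study_id, ev.disease, ev.disease_date)
            for ev in person.std_events
        ],
        visits=list(person.visits),
        provenance={"all": "truth"},
    )


def _person_rng(seed: int, uid: int, phase: int) -> np.random.Generator:
    """Documented substream derivation: one PCG64 stream per (person, phase)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, uid, phase])


def _uniform_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = max((end - start).days, 0)
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _pick(rng: np.random.Generator, options: Sequence, probs: Sequence[float]):
    return options[int(rng.choice(len(options), p=np.asarray(probs) / sum(probs)))]


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _typo(name_: str, rng: np.random.Generator) -> str:
    """One random single-edit typo (substitute/delete/insert): edit distance 1."""
    ops = ["substitute", "insert"] if len(name_) < 2 else ["substitute", "delete", "insert"]
    op = ops[int(rng.integers(len(ops)))]
    if op == "delete":
        pos = int(rng.integers(len(name_)))
        return name_[:pos] + name_[pos + 1:]
    if op == "insert":
        pos = int(rng.integers(len(name_) + 1))
        return name_[:pos] + _LETTERS[int(rng.integers(26))] + name_[pos:]
    pos = int(rng.integers(len(name_)))
    current = name_[pos].lower()
    choices = [c for c in _LETTERS if c != current]
    new = choices[int(rng.integers(len(choices)))]
    return name_[:pos] + new + name_[pos + 1:]


def corrupt_identity(
    identity: PersonIdentity, model: ErrorModel, rng: np.random.Generator
) -> tuple[PersonIdentity, list[str]]:
    """Apply the error model to a copy of the identity.

    At most one perturbation per field per call; the original is untouched.
    Returns the corrupted identity and a log of the perturbations applied.
    """
    log: list[str] = []
    first, last, dob, ssn = (
        identity.first_name,
        identity.last_name,
        identity.dob,
        identity.ssn,
    )

    nick = names.NICKNAMES.get(first) or names.NICKNAMES_REVERSE.get(first)
    if nick is not None and rng.random() < model.p_nickname_substitution:
        first = nick
        log.append("first_name:nickname")
    elif rng.random() < model.p_typo_per_name:
        first = _typo(first, rng)
        log.append("first_name:typo")

    if rng.random() < model.p_last_name_change:
        pool = [n for n in names.LAST_NAMES if n != last]
        last = pool[int(rng.integers(len(pool)))]
        log.append("last_name:change")
    elif rng.random() < model.p_typo_per_name:
        last = _typo(last, rng)
        log.append("last_name:typo")

    if (
        dob.day <= 12
        and dob.day != dob.month
        and rng.random() < model.p_dob_day_month_swap
    ):
        dob = date(dob.year, dob.day, dob.month)
        log.append("dob:day_month_swap")

    if ssn is not None and rng.random() < model.p_ssn_missing:
        ssn = None
        log.append("ssn:missing")

    return PersonIdentity(first, last, dob, identity.sex_at_birth, ssn), log


# ---------------------------------------------------------------------------
# population generation


def _generate_person(uid: int, config: SimConfig) -> TruePerson:
    rng = _person_rng(config.seed, uid, 0)
    m = config.marginals
    window = config.window
    as_of = window.as_of

    sex = Sex.FEMALE if rng.random() < m.sex[0] else Sex.MALE
    pool = names.FIRST_NAMES_FEMALE if sex is Sex.FEMALE else names.FIRST_NAMES_MALE
    first = pool[int(rng.integers(len(pool)))]
    last = names.LAST_NAMES[int(rng.integers(len(names.LAST_NAMES)))]
    age = float(np.clip(rng.normal(44.3, 13.2), 18.0, 85.0))
    dob = window.start - timedelta(days=int(age * 365.25) + int(rng.integers(0, 365)))
    ssn = f"{rng.integers(1000, 10000)}{uid:05d}" if rng.random() < 0.93 else None
    identity = PersonIdentity(first, last, dob, sex, ssn)

    race = _pick(rng, list(Race), m.race)
    residence = _pick(rng, list(State), m.residence)
    risk_options: list[Risk | None] = list(Risk) + [None]
    risk = _pick(rng, risk_options, m.risk)
    stratum = _pick(rng, list(_STRATA), m.site_mixture)
    k = _STRATA.index(stratum)
    # fragmented, clinic-invisible care tracks worse virologic control: the
    # engagement offsets cancel in the mixture (0.62 * 0.08 ~= 0.38 * 0.13)
    # so the per-stratum suppression marginals are preserved
    engaged = rng.random() < 0.62
    p_suppressed = m.suppression_by_stratum[k] + (0.08 if engaged else -0.13)
    suppressed = rng.random() < min(max(p_suppressed, 0.02), 0.97)

    housing = _pick(rng, list(_HOUSING_BY_STRATUM), [v[k] for v in _HOUSING_BY_STRATUM.values()])
    employment = _pick(
        rng, list(_EMPLOYMENT_BY_STRATUM), [v[k] for v in _EMPLOYMENT_BY_STRATUM.values()]
    )
    insurance = _pick(
        rng, list(_INSURANCE_BY_STRATUM), [v[k] for v in _INSURANCE_BY_STRATUM.values()]
    )
    comorbidities = {c for c, p in _COMORBIDITY_BY_STRATUM.items() if rng.random() < p[k]}

    enrollment_site = COHORT_SITES[int(rng.integers(len(COHORT_SITES)))]
    n_external = {SiteCategory.ONE: 0, SiteCategory.TWO: 1, SiteCategory.THREE_PLUS: 2}[stratum]
    external_universe = [s for s in COHORT_SITES if s != enrollment_site] + list(
        EXTERNAL_FACILITIES
    )
    # outside care happens mostly at non-cohort facilities
    ext_probs = [0.3 / 12] * 12 + [0.7 / 12] * 12
    externals = list(
        np.array(external_universe)[
            rng.choice(len(external_universe), size=n_external, replace=False, p=ext_probs)
        ]
    )
    care_sites = [enrollment_site] + [str(s) for s in externals]

    enrollment = _uniform_date(rng, date(2011, 1, 1), date(2015, 5, 31))

    # diagnosis history: surveillance tends to hold the earlier (true) date
    duration_days = int(rng.gamma(2.0, 7.0) * 365.25)
    hiv_dx = max(enrollment - timedelta(days=duration_days), dob + timedelta(days=90))
    cohort_dx: date | None = hiv_dx
    if rng.random() < 0.35:
        cohort_dx = min(hiv_dx + timedelta(days=int(rng.uniform(180, 1825))), enrollment)
    if rng.random() >= 0.95:
        cohort_dx = None
    surv_has_dx = rng.random() < 0.9

    aids_ever = rng.random() < 0.6334
    aids_dx = None
    oi: bool | None = None
    if aids_ever:
        aids_dx = min(hiv_dx + timedelta(days=int(rng.uniform(0, 2190))), as_of)
        oi = rng.random() < 0.30
    cohort_knows_oi = rng.random() < 0.5
    surv_knows_oi = rng.random() < 0.75

    deceased = rng.random() < 0.032
    death_date = None
    if deceased:
        death_date = _uniform_date(rng, enrollment + timedelta(days=30), as_of)
        if death_date > as_of:
            death_date = as_of
    cohort_knows_death = rng.random() < 0.65
    surv_knows_death = rng.random() < 0.95

    withdrawn = _uniform_date(rng, enrollment, as_of) if rng.random() < 0.04 else None
    transferred = _uniform_date(rng, enrollment, as_of) if rng.random() < 0.03 else None

    art: list[ArtPrescription] = []
    if rng.random() < 0.93:
        start = enrollment + timedelta(days=int(rng.integers(0, 91)))
        end = None if rng.random() < 0.88 else start + timedelta(days=int(rng.uniform(180, 1095)))
        art.append(ArtPrescription(start, end))

    # encounter process over the active period
    period_end = min(as_of, death_date) if death_date else as_of
    period_end = max(period_end, enrollment + timedelta(days=1))
    encounter_dates: list[date] = []
    if engaged:
        t = enrollment + timedelta(days=int(rng.integers(0, 45)))
        while t <= period_end:
            encounter_dates.append(t)
            t = t + timedelta(days=int(rng.uniform(70, 130)))
    else:
        years = max((period_end - enrollment).days / 365.25, 0.05)
        for _ in range(rng.poisson(0.8 * years)):
            encounter_dates.append(_uniform_date(rng, enrollment, period_end))
    weights = _SITE_WEIGHTS[stratum]
    encounters = [
        (d, care_sites[int(rng.choice(len(care_sites), p=weights))])
        for d in sorted(encounter_dates)
    ]
    # guarantee the stratum is recoverable from the true labs: at least one
    # encounter at every external care site
    seen = {site for _, site in encounters}
    for site in care_sites[1:]:
        if site not in seen:
            encounters.append((_uniform_date(rng, enrollment, period_end), site))
    encounters.sort()

    labs: list[LabResult] = []
    for i, (when, site) in enumerate(encounters):
        uid_base = uid * 1000 + 2 * i
        if suppressed:
            below = rng.random() < 0.6
            vl_value = 0.0 if below else float(rng.uniform(20, 199))
        else:
            below = False
            if rng.random() < 0.10:
                vl_value = float(rng.uniform(20, 199))
            else:
                vl_value = float(10 ** rng.uniform(2.35, 5.7))
        cd4_mean = 520 if suppressed else 380
        cd4_value = float(max(rng.normal(cd4_mean, 250), 5.0))
        labs.append(
            LabResult(TestType.VL, round(vl_value), when, site, Origin.COHORT, below, uid_base)
        )
        labs.append(
            LabResult(TestType.CD4, round(cd4_value), when, site, Origin.COHORT, False, uid_base + 1)
        )

    years = max((period_end - enrollment).days / 365.25, 0.05)
    n_visits = rng.poisson((1.0 if engaged else 0.3) * years)
    visits = sorted(
        (Visit(_uniform_date(rng, enrollment, period_end), enrollment_site) for _ in range(n_visits)),
        key=lambda v: v.visit_date,
    )

    std_events = []
    for _ in range(rng.poisson(0.55)):
        std_events.append(
            TrueStdEvent(
                disease=_pick(rng, list(Disease), (0.30, 0.35, 0.35)),
                disease_date=_uniform_date(rng, enrollment, period_end),
                in_cohort=rng.random() < 0.7,
                in_std_registry=rng.random() < 0.75,
            )
        )

    return TruePerson(
        person_uid=uid,
        identity=identity,
        race_ethnicity=race,
        state_of_residence=residence,
        resident=residence is State.DC,
        transmission_risk=risk,
        stratum=stratum,
        suppressed=suppressed,
        engaged=engaged,
        housing=housing,
        employment=employment,
        insurance=insurance,
        comorbidities=comorbidities,
        enrollment_site=enrollment_site,
        care_sites=care_sites,
        enrollment_date=enrollment,
        hiv_dx_date=hiv_dx,
        cohort_dx_date=cohort_dx,
        surv_has_dx=surv_has_dx,
        aids_ever=aids_ever,
        aids_dx_date=aids_dx,
        oi_at_aids=oi,
        cohort_knows_oi=cohort_knows_oi,
        surv_knows_oi=surv_knows_oi,
        vital_status=Vital.DECEASED if deceased else Vital.ALIVE,
        death_date=death_date,
        cohort_knows_death=cohort_knows_death,
        surv_knows_death=surv_knows_death,
        withdrawn_date=withdrawn,
        transferred_date=transferred,
        art_prescriptions=art,
        true_labs=labs,
        visits=visits,
        std_events=std_events,
    )


def generate_population(config: SimConfig) -> list[TruePerson]:
    """Deterministic ground-truth population under the configured marginals."""
    if config.n_persons < 0:
        raise ValueError("n_persons must be non-negative")
    return [_generate_person(uid, config) for uid in range(config.n_persons)]


# ---------------------------------------------------------------------------
# registry emission


def emit_registries(
    population: Sequence[TruePerson], config: SimConfig
) -> tuple[list[CohortRecord], list[SurveillanceRecord], list[StdRegistryRecord], TruthSet]:
    """Project the ground truth onto the three registries.

    Every cohort person yields a cohort record (clean identity).  A person
    reaches surveillance with probability overlap_fraction if resident, or
    p_nonresident_lab_reported otherwise, with a corrupted identity.  Labs
    land in each extract per the capture model; the truth set records every
    cross-registry pair denoting the same person.
    """
    cap = config.capture_model
    cohort: list[CohortRecord] = []
    surveillance: list[SurveillanceRecord] = []
    std_registry: list[StdRegistryRecord] = []
    hiv_pairs: set[tuple[str, str]] = set()
    std_pairs: set[tuple[str, str]] = set()
    persons: dict[str, TruePerson] = {}

    for person in population:
        rng = _person_rng(config.seed, person.person_uid, 1)
        persons[person.study_id] = person

        cohort_labs = [
            replace(lab, origin=Origin.COHORT)
            for lab in person.true_labs
            if lab.source_facility == person.enrollment_site
            or rng.random() < cap.p_cohort_captures_external_lab
        ]
        cohort_std = [
            StdEvent(person.study_id, ev.disease, ev.disease_date)
            for ev in person.std_events
            if ev.in_cohort
        ]
        cohort.append(
            CohortRecord(
                study_id=person.study_id,
                enrollment_site=person.enrollment_site,
                enrollment_date=person.enrollment_date,
                identity=person.identity,
                race_ethnicity=person.race_ethnicity,
                state_of_residence=person.state_of_residence,
                transmission_risk=person.transmission_risk,
                hiv_dx_date=person.cohort_dx_date,
                aids_ever=person.aids_ever,
                aids_dx_date=person.aids_dx_date,
                oi_at_aids=person.oi_at_aids if person.cohort_knows_oi else None,
                housing=person.housing,
                employment=person.employment,
                insurance=person.insurance,
                vital_status=(
                    Vital.DECEASED
                    if person.vital_status is Vital.DECEASED and person.cohort_knows_death
                    else Vital.ALIVE
                ),
                death_date=(
                    person.death_date
                    if person.vital_status is Vital.DECEASED and person.cohort_knows_death
                    else None
                ),
                withdrawn_date=person.withdrawn_date,
                transferred_date=person.transferred_date,
                labs=cohort_labs,
                art_prescriptions=list(person.art_prescriptions),
                std_events=cohort_std,
                visits=list(person.visits),
                comorbidities=set(person.comorbidities),
            )
        )

        p_present = cap.overlap_fraction if person.resident else cap.p_nonresident_lab_reported
        if rng.random() < p_present:
            surv_identity, _ = corrupt_identity(person.identity, config.error_model, rng)
            surv_labs = []
            for lab in person.true_labs:
                if lab.test_type is TestType.CD4:
                    p_capture = cap.p_surv_cd4_capture
                elif lab.below_detection or lab.value < 200:
                    p_capture = cap.p_surv_vl_capture_suppressed
                else:
                    p_capture = cap.p_surv_vl_capture_unsuppressed
                if rng.random() < p_capture:
                    surv_labs.append(replace(lab, origin=Origin.SURVEILLANCE))
            surveillance.append(
                SurveillanceRecord(
                    ehars_id=person.ehars_id,
                    identity=surv_identity,
                    hiv_dx_date=person.hiv_dx_date if person.surv_has_dx else None,
                    aids_dx_date=person.aids_dx_date,
                    oi_at_aids=person.oi_at_aids if person.surv_knows_oi else None,
                    transmission_risk=person.transmission_risk,
                    state_of_residence=person.state_of_residence,
                    vital_status=(
                        Vital.DECEASED
                        if person.vital_status is Vital.DECEASED and person.surv_knows_death
                        else Vital.ALIVE
                    ),
                    death_date=(
                        person.death_date
                        if person.vital_status is Vital.DECEASED and person.surv_knows_death
                        else None
                    ),
                    labs=surv_labs,
                )
            )
            hiv_pairs.add((person.study_id, person.ehars_id))

        registry_events = [
            StdEvent(person.std_id, ev.disease, ev.disease_date)
            for ev in person.std_events
            if ev.in_std_registry
        ]
        if registry_events:
            std_identity, _ = corrupt_identity(person.identity, config.error_model, rng)
            std_registry.append(
                StdRegistryRecord(person.std_id, std_identity, registry_events)
            )
            std_pairs.add((person.study_id, person.std_id))

    truth = TruthSet(hiv_pairs=hiv_pairs, std_pairs=std_pairs, persons=persons)
    return cohort, surveillance, std_registry, truth
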