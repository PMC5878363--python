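"""Domain types shared by the three registries.

The pipeline joins three views of one person: a clinical-cohort record, an
HIV surveillance (eHARS-like) record, and STD surveillance events.  Identity
fields are stored verbatim; all normalization happens at key-construction
time so that nothing destructive ever touches the source data.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Race(str, enum.Enum):
    NH_BLACK = "nh_black"
    NH_WHITE = "nh_white"
    OTHER_UNKNOWN = "other_unknown"


class State(str, enum.Enum):
    DC = "DC"
    MD = "MD"
    VA = "VA"
    OTHER = "other"


class Risk(str, enum.Enum):
    """HIV transmission-risk category (one per record per source)."""

    MSM_IDU = "msm_idu"
    IDU = "idu"
    MSM = "msm"
    HETEROSEXUAL = "heterosexual"
    PERINATAL = "perinatal"
    OTHER_UNKNOWN = "other_unknown"


#: CDC-convention priority order used when sources disagree: the
#: highest-priority category present among the reported ones wins.
DEFAULT_RISK_HIERARCHY: tuple[Risk, ...] = (
    Risk.MSM_IDU,
    Risk.IDU,
    Risk.MSM,
    Risk.HETEROSEXUAL,
    Risk.PERINATAL,
    Risk.OTHER_UNKNOWN,
)


class Vital(str, enum.Enum):
    ALIVE = "alive"
    DECEASED = "deceased"


class Housing(str, enum.Enum):
    PERMANENT = "permanent"
    TEMPORARY = "temporary"
    HOMELESS = "homeless"
    OTHER_UNKNOWN = "other_unknown"


class Employment(str, enum.Enum):
    FULL_TIME = "full_time"
    PART_TIME = "part_time"
    UNEMPLOYED = "unemployed"
    OTHER = "other"


class Insurance(str, enum.Enum):
    PRIVATE = "private"
    PUBLIC = "public"
    OTHER = "other"


class Disease(str, enum.Enum):
    SYPHILIS = "syphilis"
    GONORRHEA = "gonorrhea"
    CHLAMYDIA = "chlamydia"


class TestType(str, enum.Enum):
    __test__ = False  # not a pytest class, despite the name

    CD4 = "CD4"  # cells/mm3
    VL = "VL"  # copies/mL


class Origin(str, enum.Enum):
    COHORT = "cohort"
    SURVEILLANCE = "surveillance"


_SSN_SEP = re.compile(r"[\s\-]")


@dataclass(frozen=True)
class PersonIdentity:
    """Identifying fields feeding match-key construction.

    Names are kept verbatim.  The SSN is stored as exactly nine digits
    (separators are stripped at construction) or is absent.
    """

    first_name: str
    last_name: str
    dob: date
    sex_at_birth: Sex
    ssn: str | None = None

    def __post_init__(self) -> None:
        if self.ssn is not None:
            digits = _SSN_SEP.sub("", self.ssn)
            if not (len(digits) == 9 and digits.isdigit()):
                raise ValueError(f"SSN must be 9 digits after stripping separators: {self.ssn!r}")
            object.__setattr__(self, "ssn", digits)


@dataclass(frozen=True)
class LabResult:
    """One CD4 or VL measurement with its source-facility provenance.

    ``below_detection`` marks a viral load reported as undetectable; it is
    encoded as value 0 and counts as <200 copies/mL everywhere.  ``lab_uid``
    is synthetic-truth bookkeeping (the identity of the underlying true
    measurement); it is ignored by all reconciliation logic.
    """

    test_type: TestType
    value: float
    collection_date: date
    source_facility: str
    origin: Origin
    below_detection: bool = False
    lab_uid: int | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("lab value must be non-negative")
        if not self.source_facility:
            raise ValueError("source_facility must be non-empty")

    @property
    def suppressed(self) -> bool:
        """Viral suppression at this measurement (VL < 200 copies/mL)."""
        if self.test_type is not TestType.VL:
            raise ValueError("suppression is defined for VL results only")
        return self.below_detection or self.value < 200


@dataclass(frozen=True)
class ArtPrescription:
    start: date
    end: date | None = None  # None = ongoing


@dataclass(frozen=True)
class Visit:
    visit_date: date
    facility: str


@dataclass(frozen=True)
class StdEvent:
    """An STD diagnosis; (person, disease, disease_date) is its dedup identity."""

    person_native_id: str
    disease: Disease
    disease_date: date


@dataclass
class CohortRecord:
    """One participant-enrollment row of the clinical-cohort extract."""

    study_id: str
    enrollment_site: str
    enrollment_date: date
    identity: PersonIdentity
    race_ethnicity: Race
    state_of_residence: State
    transmission_risk: Risk | None = None
    hiv_dx_date: date | None = None
    aids_ever: bool = False
    aids_dx_date: date | None = None
    oi_at_aids: bool | None = None
    housing: Housing = Housing.OTHER_UNKNOWN
    employment: Employment = Employment.OTHER
    insurance: Insurance = Insurance.OTHER
    vital_status: Vital = Vital.ALIVE
    death_date: date | None = None
    withdrawn_date: date | None = None
    transferred_date: date | None = None
    labs: list[LabResult] = field(default_factory=list)
    art_prescriptions: list[ArtPrescription] = field(default_factory=list)
    std_events: list[StdEvent] = field(default_factory=list)
    visits: list[Visit] = field(default_factory=list)
    comorbidities: set[str] = field(default_factory=set)


@dataclass
class SurveillanceRecord:
    """One person row of the HIV surveillance (eHARS-like) extract."""

    ehars_id: str
    identity: PersonIdentity
    hiv_dx_date: date | None = None
    aids_dx_date: date | None = None
    oi_at_aids: bool | None = None
    transmission_risk: Risk | None = None
    state_of_residence: State = State.OTHER
    vital_status: Vital = Vital.ALIVE
    death_date: date | None = None
    labs: list[LabResult] = field(default_factory=list)


@dataclass
class StdRegistryRecord:
    """One person of the STD surveillance registry with their events."""

    std_id: str
    identity: PersonIdentity
    events: list[StdEvent] = field(default_factory=list)
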