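"""Delimited-text readers and writers for the three registry extracts.

Each registry is a directory of UTF-8 CSV files with mandatory headers and
ISO-8601 dates, one file per entity, joined on the registry's native ID:

cohort/        persons.csv labs.csv art.csv std_events.csv visits.csv
surveillance/  persons.csv labs.csv
std/           persons.csv events.csv

Readers never mutate identity strings and never silently drop data: a row
that fails to parse is collected as a line-numbered error; a missing
mandatory column raises ``SchemaError``.  Writers and readers round-trip
every field, and output is byte-deterministic given equal input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .stats import ComparisonReport, proportion
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


class SchemaError(Exception):
    """A file's header does not match the documented schema."""


@dataclass(frozen=True)
class ParseError:
    file: str
    line: int  # 1-based line number (header is line 1)
    message: str


@dataclass(frozen=True)
class CsvDialect:
    delimiter: str = ","
    encoding: str = "utf-8"


@dataclass
class ReadResult:
    records: list
    errors: list[ParseError] = field(default_factory=list)


# ---------------------------------------------------------------------------
# field codecs


def _opt(value: str, parse: Callable):
    return None if value == "" else parse(value)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, date):
        return value.isoformat()
    if hasattr(value, "value"):  # enums
        return value.value
    return str(value)


def _parse_bool(value: str) -> bool:
    if value in ("true", "false"):
        return value == "true"
    raise ValueError(f"invalid boolean: {value!r}")


def _rows(path: Path, required: Sequence[str], dialect: CsvDialect):
    with open(path, newline="", encoding=dialect.encoding) as handle:
        reader = csv.DictReader(handle, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing mandatory columns {missing}")
        for line, row in enumerate(reader, start=2):
            yield line, row


def _write_csv(path: Path, header: Sequence[str], rows: Iterable[Sequence], dialect: CsvDialect):
    with open(path, "w", newline="", encoding=dialect.encoding) as handle:
        writer = csv.writer(handle, delimiter=dialect.delimiter)
        writer.writerow(header)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


_IDENTITY_COLS = ("first_name", "last_name", "dob", "sex_at_birth", "ssn")


def _identity_from_row(row: dict) -> PersonIdentity:
    return PersonIdentity(
        first_name=row["first_name"],
        last_name=row["last_name"],
        dob=date.fromisoformat(row["dob"]),
        sex_at_birth=Sex(row["sex_at_birth"]),
        ssn=_opt(row["ssn"], str),
    )


def _identity_row(identity: PersonIdentity) -> list:
    return [
        identity.first_name,
        identity.last_name,
        identity.dob,
        identity.sex_at_birth,
        identity.ssn,
    ]


def _lab_from_row(row: dict, origin: Origin) -> LabResult:
    return LabResult(
        test_type=TestType(row["test_type"]),
        value=float(row["value"]),
        collection_date=date.fromisoformat(row["collection_date"]),
        source_facility=row["source_facility"],
        origin=origin,
        below_detection=_parse_bool(row["below_detection"]),
        lab_uid=_opt(row["lab_uid"], int),
    )


_LAB_COLS = ("test_type", "value", "below_detection", "collection_date", "source_facility", "lab_uid")


def _lab_row(lab: LabResult) -> list:
    return [
        lab.test_type,
        f"{lab.value:g}",
        lab.below_detection,
        lab.collection_date,
        lab.source_facility,
        lab.lab_uid,
    ]


def _read_children(
    path: Path, id_col: str, required: Sequence[str], dialect: CsvDialect,
    parse: Callable[[dict], object], errors: list[ParseError],
) -> dict[str, list]:
    children: dict[str, list] = {}
    for line, row in _rows(path, (id_col, *required), dialect):
        try:
            children.setdefault(row[id_col], []).append(parse(row))
        except (ValueError, KeyError) as exc:
            errors.append(ParseError(path.name, line, str(exc)))
    return children


# ---------------------------------------------------------------------------
# cohort extract

_COHORT_PERSON_COLS = (
    "study_id", "enrollment_site", "enrollment_date", *_IDENTITY_COLS,
    "race_ethnicity", "state_of_residence", "transmission_risk", "hiv_dx_date",
    "aids_ever", "aids_dx_date", "oi_at_aids", "housing", "employment",
    "insurance", "vital_status", "death_date", "withdrawn_date",
    "transferred_date", "comorbidities",
)


def read_cohort_extract(path: str | Path, dialect: CsvDialect | None = None) -> ReadResult:
    """Read a cohort extract directory into CohortRecords sorted by study_id.

    Child tables (labs, ART, STD events, visits) are joined on study_id.
    Unparseable rows are collected as errors, never silently dropped.
    """
    path = Path(path)
    dialect = dialect or CsvDialect()
    errors: list[ParseError] = []

    labs = _read_children(
        path / "labs.csv", "study_id", _LAB_COLS, dialect,
        lambda r: _lab_from_row(r, Origin.COHORT), errors,
    )
    art = _read_children(
        path / "art.csv", "study_id", ("start_date", "end_date"), dialect,
        lambda r: ArtPrescription(
            date.fromisoformat(r["start_date"]), _opt(r["end_date"], date.fromisoformat)
        ),
        errors,
    )
    std = _read_children(
        path / "std_events.csv", "study_id", ("disease", "disease_date"), dialect,
        lambda r: StdEvent(r["study_id"], Disease(r["disease"]), date.fromisoformat(r["disease_date"])),
        errors,
    )
    visits = _read_children(
        path / "visits.csv", "study_id", ("visit_date", "facility"), dialect,
        lambda r: Visit(date.fromisoformat(r["visit_date"]), r["facility"]), errors,
    )

    records: list[CohortRecord] = []
    seen: set[str] = set()
    for line, row in _rows(path / "persons.csv", _COHORT_PERSON_COLS, dialect):
        sid = row["study_id"]
        try:
            if sid in seen:
                raise ValueError(f"duplicate study_id {sid!r}")
            records.append(
                CohortRecord(
                    study_id=sid,
                    enrollment_site=row["enrollment_site"],
                    enrollment_date=date.fromisoformat(row["enrollment_date"]),
                    identity=_identity_from_row(row),
                    race_ethnicity=Race(row["race_ethnicity"]),
                    state_of_residence=State(row["state_of_residence"]),
                    transmission_risk=_opt(row["transmission_risk"], Risk),
                    hiv_dx_date=_opt(row["hiv_dx_date"], date.fromisoformat),
                    aids_ever=_parse_bool(row["aids_ever"]),
                    aids_dx_date=_opt(row["aids_dx_date"], date.fromisoformat),
                    oi_at_aids=_opt(row["oi_at_aids"], _parse_bool),
                    housing=Housing(row["housing"]),
                    employment=Employment(row["employment"]),
                    insurance=Insurance(row["insurance"]),
                    vital_status=Vital(row["vital_status"]),
                    death_date=_opt(row["death_date"], date.fromisoformat),
                    withdrawn_date=_opt(row["withdrawn_date"], date.fromisoformat),
                    transferred_date=_opt(row["transferred_date"], date.fromisoformat),
                    labs=labs.get(sid, []),
                    art_prescriptions=art.get(sid, []),
                    std_events=std.get(sid, []),
                    visits=visits.get(sid, []),
                    comorbidities=set(filter(None, row["comorbidities"].split(";"))),
                )
            )
            seen.add(sid)
        except ValueError as exc:
            errors.append(ParseError("persons.csv", line, str(exc)))
    records.sort(key=lambda r: r.study_id)
    return ReadResult(records, errors)


def write_cohort_extract(
    records: Sequence[CohortRecord], path: str | Path, dialect: CsvDialect | None = None
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dialect = dialect or CsvDialect()
    records = sorted(records, key=lambda r: r.study_id)
    _write_csv(
        path / "persons.csv", _COHORT_PERSON_COLS,
        (
            [
                r.study_id, r.enrollment_site, r.enrollment_date, *_identity_row(r.identity),
                r.race_ethnicity, r.state_of_residence, r.transmission_risk, r.hiv_dx_date,
                r.aids_ever, r.aids_dx_date, r.oi_at_aids, r.housing, r.employment,
                r.insurance, r.vital_status, r.death_date, r.withdrawn_date,
                r.transferred_date, ";".join(sorted(r.comorbidities)),
            ]
            for r in records
        ),
        dialect,
    )
    _write_csv(
        path / "labs.csv", ("study_id", *_LAB_COLS),
        ([r.study_id, *_lab_row(l)] for r in records for l in r.labs), dialect,
    )
    _write_csv(
        path / "art.csv", ("study_id", "start_date", "end_date"),
        ([r.study_id, rx.start, rx.end] for r in records for rx in r.art_prescriptions), dialect,
    )
    _write_csv(
        path / "std_events.csv", ("study_id", "disease", "disease_date"),
        ([r.study_id, e.disease, e.disease_date] for r in records for e in r.std_events), dialect,
    )
    _write_csv(
        path / "visits.csv", ("study_id", "visit_date", "facility"),
        ([r.study_id, v.visit_date, v.facility] for r in records for v in r.visits), dialect,
    )


# ---------------------------------------------------------------------------
# surveillance extract

_SURV_PERSON_COLS = (
    "ehars_id", *_IDENTITY_COLS, "hiv_dx_date", "aids_dx_date", "oi_at_aids",
    "transmission_risk", "state_of_residence", "vital_status", "death_date",
)


def read_surveillance_extract(path: str | Path, dialect: CsvDialect | None = None) -> ReadResult:
    """Read a surveillance extract directory, keyed and sorted on ehars_id."""
    path = Path(path)
    dialect = dialect or CsvDialect()
    errors: list[ParseError] = []
    labs = _read_children(
        path / "labs.csv", "ehars_id", _LAB_COLS, dialect,
        lambda r: _lab_from_row(r, Origin.SURVEILLANCE), errors,
    )
    records: list[SurveillanceRecord] = []
    seen: set[str] = set()
    for line, row in _rows(path / "persons.csv", _SURV_PERSON_COLS, dialect):
        eid = row["ehars_id"]
        try:
            if eid in seen:
                raise ValueError(f"duplicate ehars_id {eid!r}")
            records.append(
                SurveillanceRecord(
                    ehars_id=eid,
                    identity=_identity_from_row(row),
                    hiv_dx_date=_opt(row["hiv_dx_date"], date.fromisoformat),
                    aids_dx_date=_opt(row["aids_dx_date"], date.fromisoformat),
                    oi_at_aids=_opt(row["oi_at_aids"], _parse_bool),
                    transmission_risk=_opt(row["transmission_risk"], Risk),
                    state_of_residence=State(row["state_of_residence"]),
                    vital_status=Vital(row["vital_status"]),
                    death_date=_opt(row["death_date"], date.fromisoformat),
                    labs=labs.get(eid, []),
                )
            )
            seen.add(eid)
        except ValueError as exc:
            errors.append(ParseError("persons.csv", line, str(exc)))
    records.sort(key=lambda r: r.ehars_id)
    return ReadResult(records, errors)


def write_surveillance_extract(
    records: Sequence[SurveillanceRecord], path: str | Path, dialect: CsvDialect | None = None
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dialect = dialect or CsvDialect()
    records = sorted(records, key=lambda r: r.ehars_id)
    _write_csv(
        path / "persons.csv", _SURV_PERSON_COLS,
        (
            [
                r.ehars_id, *_identity_row(r.identity), r.hiv_dx_date, r.aids_dx_date,
                r.oi_at_aids, r.transmission_risk, r.state_of_residence,
                r.vital_status, r.death_date,
            ]
            for r in records
        ),
        dialect,
    )
    _write_csv(
        path / "labs.csv", ("ehars_id", *_LAB_COLS),
        ([r.ehars_id, *_lab_row(l)] for r in records for l in r.labs), dialect,
    )


# ---------------------------------------------------------------------------
# STD registry

_STD_PERSON_COLS = ("std_id", *_IDENTITY_COLS)


def read_std_extract(path: str | Path, dialect: CsvDialect | None = None) -> ReadResult:
    path = Path(path)
    dialect = dialect or CsvDialect()
    errors: list[ParseError] = []
    events = _read_children(
        path / "events.csv", "std_id", ("disease", "disease_date"), dialect,
        lambda r: StdEvent(r["std_id"], Disease(r["disease"]), date.fromisoformat(r["disease_date"])),
        errors,
    )
    records: list[StdRegistryRecord] = []
    seen: set[str] = set()
    for line, row in _rows(path / "persons.csv", _STD_PERSON_COLS, dialect):
        xid = row["std_id"]
        try:
            if xid in seen:
                raise ValueError(f"duplicate std_id {xid!r}")
            records.append(StdRegistryRecord(xid, _identity_from_row(row), events.get(xid, [])))
            seen.add(xid)
        except ValueError as exc:
            errors.append(ParseError("persons.csv", line, str(exc)))
    records.sort(key=lambda r: r.std_id)
    return ReadResult(records, errors)


def write_std_extract(
    records: Sequence[StdRegistryRecord], path: str | Path, dialect: CsvDialect | None = None
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dialect = dialect or CsvDialect()
    records = sorted(records, key=lambda r: r.std_id)
    _write_csv(
        path / "persons.csv", _STD_PERSON_COLS,
        ([r.std_id, *_identity_row(r.identity)] for r in records), dialect,
    )
    _write_csv(
        path / "events.csv", ("std_id", "disease", "disease_date"),
        ([r.std_id, e.disease, e.disease_date] for r in records for e in r.events), dialect,
    )


# ---------------------------------------------------------------------------
# link results


def write_link_result(result, path: str | Path, dialect: CsvDialect | None = None) -> None:
    from .linkage import LinkResult  # noqa: F401  (type of `result`)

    dialect = dialect or CsvDialect()
    _write_csv(
        Path(path),
        ("study_id", "ehars_id", "matched_key_ids", "review_flag"),
        (
            [p.study_id, p.ehars_id, ";".join(map(str, sorted(p.matched_key_ids))), p.review_flag]
            for p in sorted(result.pairs, key=lambda p: (p.study_id, p.ehars_id))
        ),
        dialect,
    )


def read_link_result(
    path: str | Path, cohort_ids: Iterable[str], surveillance_ids: Iterable[str],
    dialect: CsvDialect | None = None,
):
    from .linkage import LinkedPair, LinkResult

    dialect = dialect or CsvDialect()
    pairs = []
    for _, row in _rows(Path(path), ("study_id", "ehars_id", "matched_key_ids", "review_flag"), dialect):
        pairs.append(
            LinkedPair(
                row["study_id"],
                row["ehars_id"],
                frozenset(int(k) for k in row["matched_key_ids"].split(";") if k),
                _parse_bool(row["review_flag"]),
            )
        )
    matched_sids = {p.study_id for p in pairs if not p.review_flag}
    matched_eids = {p.ehars_id for p in pairs if not p.review_flag}
    return LinkResult(
        pairs=pairs,
        unmatched_cohort=set(cohort_ids) - matched_sids,
        unmatched_surveillance=set(surveillance_ids) - matched_eids,
    )


# ---------------------------------------------------------------------------
# report tables


def _pct_cell(numerator: int, denominator: int, decimals: int = 2) -> str:
    value = proportion(numerator, denominator, decimals)
    return "" if value is None else f"{value:.{decimals}f}"


def write_report_tables(report: ComparisonReport, out_dir: str | Path) -> list[Path]:
    """Write the comparison report as deterministic CSV tables.

    Stable row ordering and fixed number formatting (percentages to two
    decimals) make output byte-identical for identical input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dialect = CsvDialect()
    paths = []

    path = out / "outcomes.csv"
    _write_csv(
        path,
        (
            "variable", "pre_numerator", "pre_denominator", "pre_pct",
            "post_numerator", "post_denominator", "post_pct",
            "kappa", "chi2_statistic", "chi2_p",
        ),
        (
            [
                o.variable, o.pre_numerator, o.pre_denominator,
                _pct_cell(o.pre_numerator, o.pre_denominator),
                o.post_numerator, o.post_denominator,
                _pct_cell(o.post_numerator, o.post_denominator),
                "" if o.kappa is None else f"{o.kappa:.4f}",
                "" if o.chi2 is None else f"{o.chi2.statistic:.4f}",
                "" if o.chi2 is None else f"{o.chi2.p_value:.6g}",
            ]
            for o in report.outcomes
        ),
        dialect,
    )
    paths.append(path)

    for mode, cascade in (("pre", report.pre_cascade), ("post", report.post_cascade)):
        path = out / f"cascade_{mode}.csv"
        _write_csv(
            path,
            ("stratum", "stage", "numerator", "denominator", "pct"),
            (
                [stratum, s.stage, s.numerator, s.denominator,
                 _pct_cell(s.numerator, s.denominator)]
                for stratum in sorted(cascade)
                for s in cascade[stratum]
            ),
            dialect,
        )
        paths.append(path)
    return paths
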