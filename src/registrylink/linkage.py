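"""Deterministic multi-key record linkage between registries.

The matcher builds a fixed catalogue of identity keys per record — exact
composites of normalized name / date-of-birth / sex / SSN components, plus
phonetic (Soundex), initial, truncation, name-swap and date-transposition
variants — matches each key separately by exact equality, then merges the
per-key candidate sets and deduplicates them into a person-level match map.
The HIV variant uses 11 keys; the STD variant drops the full-SSN key.

A pair is accepted when it agrees on at least ``min_keys`` distinct keys or
on the full-SSN key alone.  One-to-many collisions are resolved in favour of
the pair with the most agreeing keys; ties are flagged for manual review and
excluded from automated downstream merging.
"""

from __future__ import annotations

import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date
from typing import Callable, Iterable, Mapping, Sequence

from .types import (
    CohortRecord,
    Disease,
    PersonIdentity,
    Sex,
    StdEvent,
    StdRegistryRecord,
    SurveillanceRecord,
)

SEP = "|"

# ---------------------------------------------------------------------------
# component normalization


def normalize_component(raw: str | date | Sex | None, kind: str) -> str:
    """Normalize one identity component; empty output means "missing".

    name  -> uppercased, diacritics folded, non-alphabetic stripped
    ssn   -> digits only (must end up 9 digits, else missing)
    date  -> YYYYMMDD
    sex   -> single letter M/F; unknown sex is treated as missing

    Idempotent for every kind.
    """
    if raw is None:
        return ""
    if kind == "name":
        text = unicodedata.normalize("NFKD", str(raw))
        return "".join(c for c in text.upper() if "A" <= c <= "Z")
    if kind == "ssn":
        digits = "".join(c for c in str(raw) if c.isdigit())
        return digits if len(digits) == 9 else ""
    if kind == "date":
        if isinstance(raw, date):
            return f"{raw.year:04d}{raw.month:02d}{raw.day:02d}"
        return "".join(c for c in str(raw) if c.isdigit())
    if kind == "sex":
        value = raw.value if isinstance(raw, Sex) else str(raw)
        value = value.strip().upper()
        if value.startswith("M"):
            return "M"
        if value.startswith("F"):
            return "F"
        return ""  # unknown sex never matches a sex-bearing key
    raise ValueError(f"unknown component kind: {kind}")


_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


def soundex(name: str) -> str:
    """American Soundex code (letter + 3 digits) of an alphabetic string.

    Vowels and Y separate codes; H and W do not (standard rule), so e.g.
    ASHCRAFT -> A261.  Empty input gives an empty code.
    """
    letters = normalize_component(name, "name")
    if not letters:
        return ""
    out = [letters[0]]
    prev = _SOUNDEX_CODES.get(letters[0], "")
    for ch in letters[1:]:
        code = _SOUNDEX_CODES.get(ch, "")
        if code and code != prev:
            out.append(code)
            if len(out) == 4:
                break
        if ch not in "HW":
            prev = code
    return "".join(out).ljust(4, "0")


# ---------------------------------------------------------------------------
# key catalogue


@dataclass(frozen=True)
class MatchKey:
    key_id: int
    key_string: str  # empty => non-matchable (a required component missing)


@dataclass(frozen=True)
class _Parts:
    first: str
    last: str
    dob: str
    dob_canon: str  # day/month sorted when ambiguous (day <= 12)
    sex: str
    ssn: str

    @property
    def year(self) -> str:
        return self.dob[:4] if self.dob else ""

    @property
    def ssn4(self) -> str:
        return self.ssn[-4:] if self.ssn else ""


def _parts(identity: PersonIdentity) -> _Parts:
    dob = normalize_component(identity.dob, "date")
    day, month = identity.dob.day, identity.dob.month
    if day <= 12:
        a, b = sorted((month, day))
        canon = f"{identity.dob.year:04d}{a:02d}{b:02d}"
    else:
        canon = dob
    return _Parts(
        first=normalize_component(identity.first_name, "name"),
        last=normalize_component(identity.last_name, "name"),
        dob=dob,
        dob_canon=canon,
        sex=normalize_component(identity.sex_at_birth, "sex"),
        ssn=normalize_component(identity.ssn, "ssn"),
    )


def _join(*components: str) -> str:
    """Composite key; empty if any required component is missing."""
    if any(not c for c in components):
        return ""
    return SEP.join(components)


# Each builder maps normalized parts to a key string ("" = non-matchable).
# K4 sorts an ambiguous day/month pair so a one-sided transposition still
# matches; K6 sorts the name pair so a one-sided first/last swap matches.
DEFAULT_KEY_CATALOGUE: dict[int, Callable[[_Parts], str]] = {
    1: lambda p: p.ssn,
    2: lambda p: _join(p.last, p.first, p.dob, p.sex),
    3: lambda p: _join(soundex(p.last), soundex(p.first), p.dob),
    4: lambda p: _join(p.last, p.first, p.dob_canon, p.sex),
    5: lambda p: _join(p.last, p.first[:1], p.dob, p.sex),
    6: lambda p: _join(*sorted((p.first, p.last)), p.dob, p.sex),
    7: lambda p: _join(p.last, p.year, p.sex, p.ssn4),
    8: lambda p: _join(soundex(p.last), p.first, p.year, p.sex),
    9: lambda p: _join(p.last, p.first, p.dob),
    10: lambda p: _join(p.last[:3], p.first[:3], p.dob, p.sex),
    11: lambda p: _join(p.ssn4, p.dob, p.sex),
}

SSN_KEY_ID = 1
HIV11_KEY_IDS: tuple[int, ...] = tuple(range(1, 12))
STD10_KEY_IDS: tuple[int, ...] = tuple(range(2, 12))  # hiv11 minus the SSN key


def build_keys(
    identity: PersonIdentity,
    variant: str = "hiv11",
    catalogue: Mapping[int, Callable[[_Parts], str]] | None = None,
) -> list[MatchKey]:
    """Build the fixed, ordered key set for one identity.

    variant "hiv11" yields 11 keys; "std10" yields the same set minus the
    full-SSN key.  Keys whose required components are missing carry an empty
    key_string and never match.
    """
    if variant == "hiv11":
        ids: Sequence[int] = HIV11_KEY_IDS
    elif variant == "std10":
        ids = STD10_KEY_IDS
    else:
        raise ValueError(f"unknown variant: {variant}")
    cat = DEFAULT_KEY_CATALOGUE if catalogue is None else catalogue
    p = _parts(identity)
    return [MatchKey(i, cat[i](p)) for i in ids]


# ---------------------------------------------------------------------------
# matching


def match_single_key(
    cohort_keys: Mapping[str, Sequence[MatchKey]],
    surveillance_keys: Mapping[str, Sequence[MatchKey]],
    key_id: int,
) -> set[tuple[str, str]]:
    """Exact equality join on one key across the two registries.

    Empty key strings never match.  Returns all candidate (cohort id,
    surveillance id) pairs for this key; one-to-many collisions survive here
    and are resolved at merge time.
    """
    by_string: dict[str, list[str]] = defaultdict(list)
    for sid, keys in cohort_keys.items():
        for k in keys:
            if k.key_id == key_id and k.key_string:
                by_string[k.key_string].append(sid)
    pairs: set[tuple[str, str]] = set()
    for eid, keys in surveillance_keys.items():
        for k in keys:
            if k.key_id == key_id and k.key_string:
                for sid in by_string.get(k.key_string, ()):
                    pairs.add((sid, eid))
    return pairs


@dataclass(frozen=True)
class LinkedPair:
    study_id: str
    ehars_id: str
    matched_key_ids: frozenset[int]
    review_flag: bool = False


@dataclass
class LinkResult:
    pairs: list[LinkedPair]
    unmatched_cohort: set[str]
    unmatched_surveillance: set[str]

    def accepted_map(self) -> dict[str, str]:
        """study_id -> ehars_id over non-flagged pairs."""
        return {p.study_id: p.ehars_id for p in self.pairs if not p.review_flag}


def merge_and_dedup(
    candidate_sets: Mapping[int, set[tuple[str, str]]],
    cohort_ids: Iterable[str],
    surveillance_ids: Iterable[str],
    min_keys: int = 2,
    ssn_key_id: int | None = SSN_KEY_ID,
) -> LinkResult:
    """Merge per-key candidate sets into a one-to-one person match map.

    A pair is accepted when it agrees on >= min_keys distinct keys, or on
    the full-SSN key alone.  One-to-many conflicts keep the pair with the
    most agreeing keys; ties are flagged for review and excluded from the
    automated match map.  Deterministic regardless of input ordering.
    """
    key_sets: dict[tuple[str, str], set[int]] = defaultdict(set)
    for key_id, pairs in candidate_sets.items():
        for pair in pairs:
            key_sets[pair].add(key_id)

    accepted = {
        pair: frozenset(keys)
        for pair, keys in key_sets.items()
        if len(keys) >= min_keys or (ssn_key_id is not None and ssn_key_id in keys)
    }

    by_sid: dict[str, list[tuple[str, str]]] = defaultdict(list)
    by_eid: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for sid, eid in accepted:
        by_sid[sid].append((sid, eid))
        by_eid[eid].append((sid, eid))

    def winners(groups: dict[str, list[tuple[str, str]]]) -> tuple[set, set]:
        won, tied = set(), set()
        for cands in groups.values():
            best = max(len(accepted[p]) for p in cands)
            top = [p for p in cands if len(accepted[p]) == best]
            if len(top) == 1:
                won.add(top[0])
            else:
                tied.update(top)
        return won, tied

    sid_winners, sid_ties = winners(by_sid)
    eid_winners, eid_ties = winners(by_eid)

    pairs: list[LinkedPair] = []
    for pair in sorted(accepted):
        sid, eid = pair
        if pair in sid_ties or pair in eid_ties:
            pairs.append(LinkedPair(sid, eid, accepted[pair], review_flag=True))
        elif pair in sid_winners and pair in eid_winners:
            pairs.append(LinkedPair(sid, eid, accepted[pair]))
        # else: lost a conflict outright -> dropped

    matched_sids = {p.study_id for p in pairs if not p.review_flag}
    matched_eids = {p.ehars_id for p in pairs if not p.review_flag}
    return LinkResult(
        pairs=pairs,
        unmatched_cohort=set(cohort_ids) - matched_sids,
        unmatched_surveillance=set(surveillance_ids) - matched_eids,
    )


def link_registries(
    cohort: Sequence[CohortRecord],
    surveillance: Sequence[SurveillanceRecord],
    min_keys: int = 2,
    catalogue: Mapping[int, Callable] | None = None,
) -> LinkResult:
    """Full 11-key HIV linkage of a cohort extract to a surveillance extract."""
    ckeys = {r.study_id: build_keys(r.identity, "hiv11", catalogue) for r in cohort}
    skeys = {r.ehars_id: build_keys(r.identity, "hiv11", catalogue) for r in surveillance}
    candidates = {i: match_single_key(ckeys, skeys, i) for i in HIV11_KEY_IDS}
    return merge_and_dedup(candidates, ckeys, skeys, min_keys=min_keys)


# ---------------------------------------------------------------------------
# STD linkage (10-key variant + event dedup)


def _dedup_std_events(
    study_id: str, events: Iterable[StdEvent], window_days: int
) -> list[StdEvent]:
    """Dedup on (disease, date); near-duplicates within the window collapse
    to the earlier date (greedy chronological pass per disease)."""
    out: list[StdEvent] = []
    by_disease: dict[Disease, list[date]] = defaultdict(list)
    for ev in sorted(set((e.disease, e.disease_date) for e in events)):
        disease, when = ev
        kept = by_disease[disease]
        if kept and (when - kept[-1]).days <= window_days:
            continue  # fuzzy duplicate of the last kept event of this disease
        kept.append(when)
        out.append(StdEvent(study_id, disease, when))
    return out


def link_std(
    cohort: Sequence[CohortRecord],
    std_registry: Sequence[StdRegistryRecord],
    min_keys: int = 2,
    dedup_window_days: int = 14,
    catalogue: Mapping[int, Callable] | None = None,
) -> tuple[dict[str, list[StdEvent]], LinkResult]:
    """10-key linkage to the STD registry and per-person event reconciliation.

    Returns the per-person deduplicated event lists (cohort events unioned
    with matched registry events) and the underlying match map.
    """
    ckeys = {r.study_id: build_keys(r.identity, "std10", catalogue) for r in cohort}
    xkeys = {r.std_id: build_keys(r.identity, "std10", catalogue) for r in std_registry}
    candidates = {i: match_single_key(ckeys, xkeys, i) for i in STD10_KEY_IDS}
    result = merge_and_dedup(candidates, ckeys, xkeys, min_keys=min_keys, ssn_key_id=None)

    registry_events = {r.std_id: r.events for r in std_registry}
    matched = result.accepted_map()
    merged: dict[str, list[StdEvent]] = {}
    for rec in cohort:
        events = list(rec.std_events)
        if rec.study_id in matched:
            events.extend(registry_events[matched[rec.study_id]])
        merged[rec.study_id] = _dedup_std_events(rec.study_id, events, dedup_window_days)
    return merged, result


# ---------------------------------------------------------------------------
# evaluation against a truth set


@dataclass
class LinkageEvaluation:
    precision: float
    recall: float
    f1: float
    false_pairs: list[tuple[str, str]] = field(default_factory=list)
    missed_pairs: list[tuple[str, str]] = field(default_factory=list)
    zero_denominator: bool = False


def evaluate_linkage(result: LinkResult, truth: set[tuple[str, str]]) -> LinkageEvaluation:
    """Precision/recall of the accepted (non-flagged) pairs against truth.

    An empty accepted set reports precision 1 with the zero-denominator flag
    set (documented convention).
    """
    if not truth:
        raise ValueError("empty truth set")
    accepted = {(p.study_id, p.ehars_id) for p in result.pairs if not p.review_flag}
    true_found = accepted & truth
    zero = not accepted
    precision = 1.0 if zero else len(true_found) / len(accepted)
    recall = len(true_found) / len(truth)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return LinkageEvaluation(
        precision=precision,
        recall=recall,
        f1=f1,
        false_pairs=sorted(accepted - truth),
        missed_pairs=sorted(truth - accepted),
        zero_denominator=zero,
    )
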