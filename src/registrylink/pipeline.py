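"""End-to-end driver: simulate -> link -> merge -> continuum -> compare.

The pre-linkage dataset is the cohort extract alone; the post-linkage
dataset merges each matched person's surveillance record into their cohort
record and unions STD-registry events.  Both continuum computations run on
the same person universe (matched cohort persons passing the eligibility
filter), so the pre/post comparison is paired, mirroring how a clinic-only
care continuum is re-estimated after surveillance linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .continuum import AnalysisWindow, ContinuumStatus, compute_status, filter_eligible
from .linkage import LinkResult, LinkageEvaluation, evaluate_linkage, link_registries, link_std
from .reconcile import FuzzyLabRule, MergedRecord, reconcile_person
from .stats import ComparisonReport, compare_pre_post
from .synth import SimConfig, TruthSet, emit_registries, generate_population
from .types import CohortRecord, StdRegistryRecord, SurveillanceRecord


@dataclass
class PipelineResult:
    config: SimConfig
    truth: TruthSet
    cohort: list[CohortRecord]
    surveillance: list[SurveillanceRecord]
    std_registry: list[StdRegistryRecord]
    link_result: LinkResult
    evaluation: LinkageEvaluation
    merged_pre: list[MergedRecord]
    merged_post: list[MergedRecord]
    statuses_pre: list[ContinuumStatus] = field(default_factory=list)
    statuses_post: list[ContinuumStatus] = field(default_factory=list)
    exclusion_reasons: dict = field(default_factory=dict)
    report: ComparisonReport | None = None
    std_added_events: int = 0


def merge_datasets(
    cohort: Sequence[CohortRecord],
    surveillance: Sequence[SurveillanceRecord],
    link_result: LinkResult,
    std_registry: Sequence[StdRegistryRecord] = (),
    lab_rule: FuzzyLabRule | None = None,
    min_keys: int = 2,
) -> tuple[list[MergedRecord], list[MergedRecord], int]:
    """Build the pre- and post-linkage datasets for matched cohort persons.

    Returns (pre, post, n_std_events_added).  "Pre" records pass the cohort
    data through unchanged (surveillance contribution empty); "post" records
    apply the reconciliation rules to each matched pair.
    """
    surv_by_id = {r.ehars_id: r for r in surveillance}
    matched = link_result.accepted_map()

    std_events_by_person, _ = (
        link_std(cohort, std_registry, min_keys=min_keys)
        if std_registry
        else ({}, None)
    )

    pre: list[MergedRecord] = []
    post: list[MergedRecord] = []
    added = 0
    for rec in cohort:
        if rec.study_id not in matched:
            continue
        pre.append(reconcile_person(rec, None, lab_rule))
        merged = reconcile_person(rec, surv_by_id[matched[rec.study_id]], lab_rule)
        if rec.study_id in std_events_by_person:
            events = std_events_by_person[rec.study_id]
            cohort_keys = {(e.disease, e.disease_date) for e in rec.std_events}
            added += sum(1 for e in events if (e.disease, e.disease_date) not in cohort_keys)
            merged.std_events = events
        post.append(merged)
    return pre, post, added


def run_pipeline(config: SimConfig, min_keys: int = 2) -> PipelineResult:
    """Simulate two registries from one ground truth and run every stage."""
    population = generate_population(config)
    cohort, surveillance, std_registry, truth = emit_registries(population, config)

    link_result = link_registries(cohort, surveillance, min_keys=min_keys)
    evaluation = evaluate_linkage(link_result, truth.hiv_pairs)

    merged_pre, merged_post, std_added = merge_datasets(
        cohort, surveillance, link_result, std_registry, min_keys=min_keys
    )

    window = config.window
    # one shared universe: matched persons passing the eligibility filter
    # (eligibility uses the post-linkage record, where vital status is the
    # more complete of the two sources)
    eligible_post, reasons = filter_eligible(merged_post, window)
    eligible_ids = {r.study_id for r in eligible_post}
    statuses_post = [compute_status(r, window) for r in eligible_post]
    statuses_pre = [
        compute_status(r, window) for r in merged_pre if r.study_id in eligible_ids
    ]

    report = compare_pre_post(statuses_pre, statuses_post)
    return PipelineResult(
        config=config,
        truth=truth,
        cohort=cohort,
        surveillance=surveillance,
        std_registry=std_registry,
        link_result=link_result,
        evaluation=evaluation,
        merged_pre=merged_pre,
        merged_post=merged_post,
        statuses_pre=statuses_pre,
        statuses_post=statuses_post,
        exclusion_reasons=dict(reasons),
        report=report,
        std_added_events=std_added,
    )
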