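"""Assemble the pre/post comparison report and cascade tables.

Pairs the two continuum computations over the shared eligible universe,
computes per-outcome kappa agreement and chi-square contrasts, builds the
nested cascade (matched -> retained -> on ART -> suppressed) overall and by
care-site category, and writes the deterministic CSV tables.
"""

import argparse
from pathlib import Path

from registrylink.continuum import compute_status, filter_eligible
from registrylink.io import (
    read_cohort_extract,
    read_link_result,
    read_std_extract,
    read_surveillance_extract,
    write_report_tables,
)
from registrylink.pipeline import merge_datasets
from registrylink.stats import compare_pre_post, format_p, kappa_band
from registrylink.synth import SimConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--links", type=Path, default=Path("results/link_pairs.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()
    window = SimConfig().window

    cohort = read_cohort_extract(args.data / "cohort").records
    surveillance = read_surveillance_extract(args.data / "surveillance").records
    std_registry = read_std_extract(args.data / "std").records
    link_result = read_link_result(
        args.links, (r.study_id for r in cohort), (r.ehars_id for r in surveillance)
    )
    pre, post, _ = merge_datasets(cohort, surveillance, link_result, std_registry)
    eligible_post, _ = filter_eligible(post, window)
    eligible_ids = {r.study_id for r in eligible_post}
    statuses_post = [compute_status(r, window) for r in eligible_post]
    statuses_pre = [compute_status(r, window) for r in pre if r.study_id in eligible_ids]

    report = compare_pre_post(statuses_pre, statuses_post)
    paths = write_report_tables(report, args.out)

    print(f"comparison over {len(eligible_ids)} eligible matched persons")
    for o in report.outcomes:
        direction = "rose" if o.post_pct > o.pre_pct else "fell"
        p = "" if o.chi2 is None else f"  (chi-square P {format_p(o.chi2.p_value)})"
        kappa = "" if o.kappa is None else f", kappa {o.kappa:.2f} ({kappa_band(o.kappa)})"
        print(
            f"{o.variable:8s} {direction} {o.pre_pct:.2f}% -> {o.post_pct:.2f}%{p}{kappa}"
        )
    print("tables: " + ", ".join(str(p) for p in paths))


if __name__ == "__main__":
    main()
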