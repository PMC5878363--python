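"""Compute care-continuum outcomes on the pre- and post-linkage datasets.

Applies the eligibility filter (active, not withdrawn/transferred, alive at
window start, >=1 year of follow-up), then per-person retention in care,
on-ART, viral suppression, ever-suppression, LTFU and care-site category
over the June 2014 - June 2015 window, on both dataset views.
"""

import argparse
import csv
import json
from pathlib import Path

from registrylink.continuum import compute_status, filter_eligible
from registrylink.io import (
    read_cohort_extract,
    read_link_result,
    read_std_extract,
    read_surveillance_extract,
)
from registrylink.pipeline import merge_datasets
from registrylink.synth import SimConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--links", type=Path, default=Path("results/link_pairs.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    window = SimConfig().window

    cohort = read_cohort_extract(args.data / "cohort").records
    surveillance = read_surveillance_extract(args.data / "surveillance").records
    std_registry = read_std_extract(args.data / "std").records
    link_result = read_link_result(
        args.links, (r.study_id for r in cohort), (r.ehars_id for r in surveillance)
    )
    pre, post, _ = merge_datasets(cohort, surveillance, link_result, std_registry)

    eligible_post, reasons = filter_eligible(post, window)
    eligible_ids = {r.study_id for r in eligible_post}
    statuses = {
        "post": [compute_status(r, window) for r in eligible_post],
        "pre": [compute_status(r, window) for r in pre if r.study_id in eligible_ids],
    }

    args.out.mkdir(parents=True, exist_ok=True)
    aggregate = {"excluded": dict(reasons), "eligible": len(eligible_ids)}
    for mode, rows in statuses.items():
        with open(args.out / f"continuum_{mode}.csv", "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(
                ["study_id", "ric", "on_art", "vs", "ever_vs", "ltfu", "site_category"]
            )
            for s in sorted(rows, key=lambda s: s.study_id):
                writer.writerow([
                    s.study_id, s.ric, s.on_art,
                    "" if s.vs is None else s.vs, s.ever_vs, s.ltfu,
                    s.site_category.value,
                ])
        vs_denom = [s for s in rows if s.vs is not None]
        aggregate[mode] = {
            "ric_pct": round(100 * sum(s.ric for s in rows) / len(rows), 2),
            "vs_pct": round(100 * sum(s.vs for s in vs_denom) / len(vs_denom), 2),
            "ltfu_pct": round(100 * sum(s.ltfu for s in rows) / len(rows), 2),
        }
    (args.out / "continuum_aggregate.json").write_text(json.dumps(aggregate, indent=2) + "\n")

    print(f"eligible persons: {len(eligible_ids)} (excluded: {dict(reasons)})")
    for mode in ("pre", "post"):
        a = aggregate[mode]
        print(f"{mode:4s} RIC {a['ric_pct']:.2f}%  VS {a['vs_pct']:.2f}%  LTFU {a['ltfu_pct']:.2f}%")


if __name__ == "__main__":
    main()
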