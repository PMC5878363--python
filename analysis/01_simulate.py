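"""Generate the synthetic dual-registry study data.

Draws a ground-truth population under the default marginals (26% female,
74% non-Hispanic black, 77% single-site care, per-stratum suppression
89.5%/85%/72.3%) and writes the three registry extracts — clinical cohort,
HIV surveillance, STD surveillance — plus the true match set.
"""

import argparse
import csv
from pathlib import Path

from registrylink.io import (
    write_cohort_extract,
    write_std_extract,
    write_surveillance_extract,
)
from registrylink.synth import SimConfig, emit_registries, generate_population


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=5000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()

    config = SimConfig(n_persons=args.n, seed=args.seed)
    population = generate_population(config)
    cohort, surveillance, std_registry, truth = emit_registries(population, config)

    write_cohort_extract(cohort, args.out / "cohort")
    write_surveillance_extract(surveillance, args.out / "surveillance")
    write_std_extract(std_registry, args.out / "std")
    with open(args.out / "truth_pairs.csv", "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["study_id", "ehars_id"])
        writer.writerows(sorted(truth.hiv_pairs))

    print(f"population: {args.n} persons (seed {args.seed})")
    print(f"cohort extract:       {len(cohort)} persons")
    print(
        f"surveillance extract: {len(surveillance)} persons "
        f"({100 * len(truth.hiv_pairs) / len(cohort):.1f}% of cohort present)"
    )
    print(f"STD registry:         {len(std_registry)} persons with events")
    print(f"written under {args.out}/")


if __name__ == "__main__":
    main()
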