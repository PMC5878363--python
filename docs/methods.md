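# Methods

## Linkage model

The matcher is deterministic (rule-based): two records link only through
exact agreement on composite identity keys, never through probabilistic
weights. Identity components are normalized first — names uppercased,
diacritics folded (NFKD), non-alphabetic characters stripped; SSNs reduced
to digits (anything other than nine digits counts as missing); dates
canonicalized to YYYYMMDD; sex to a single letter, with unknown sex treated
as missing. Normalization is idempotent and never touches the stored
records.

The default key catalogue (`linkage.DEFAULT_KEY_CATALOGUE`, drop-in
replaceable):

| # | composite |
|---|-----------|
| 1 | SSN (9 digits) |
| 2 | last + first + DOB + sex |
| 3 | soundex(last) + soundex(first) + DOB |
| 4 | last + first + DOB with (day, month) sorted when day ≤ 12 + sex |
| 5 | last + first initial + DOB + sex |
| 6 | sorted{first, last} + DOB + sex |
| 7 | last + birth year + sex + SSN last-4 |
| 8 | soundex(last) + first + birth year + sex |
| 9 | last + first + DOB (no sex) |
| 10 | last[:3] + first[:3] + DOB + sex |
| 11 | SSN last-4 + DOB + sex |

Keys 3 and 8 absorb misspellings that preserve the Soundex class; key 4
absorbs a day/month transposition on either side (both sides canonicalize
the ambiguous pair, so a one-sided transposition still matches); key 6
absorbs a first/last swap the same way; keys 5, 9, 10, 11 are partial keys
that tolerate a wrong or missing single component. The STD-registry variant
is the same catalogue minus key 1, since full SSNs are not carried there.
A key with any missing component gets an empty key string and is excluded
from matching — this is what prevents two records with absent SSNs from
"agreeing" on SSN.

Acceptance and conflict handling: a candidate pair is accepted with
≥ `min_keys` agreeing keys (default 2) or the full-SSN key alone. Whether a
production deterministic matcher should accept single-key matches is
genuinely open; both the threshold and the catalogue are parameters, and
the default is this package's choice, with precision/recall measurable
against the generator's truth set. One-to-many collisions resolve to the
pair with the most agreeing keys; ties are flagged `review_flag` and
excluded from automated merging (a manual-review queue in a real
deployment). The resolution is single-pass and deterministic: a pair must
win on both its cohort and surveillance side to be kept.

Phonetic encoder: American Soundex (letter + 3 digits; H/W do not separate
codes). The builder functions are plain callables, so a Metaphone or other
encoder can be substituted per key without touching the engine.

## Reconciliation

- HIV and AIDS diagnosis dates: the earlier date wins regardless of source.
- Vital status: deceased if either source reports it; earliest death date.
- Transmission risk: the highest-priority *recorded* category under the
  hierarchy MSM+IDU > IDU > MSM > heterosexual > perinatal > other/unknown
  (configurable; the combined category is never synthesized from separate
  MSM and IDU reports).
- Race/ethnicity and residence: cohort value wins; a disagreement is
  recorded as `both_conflict` in the field provenance. Sex at birth is a
  matching variable, so a conflict raises a review flag rather than a
  silent override.
- Labs: fuzzy deduplication with a greedy chronological pass per test type.
  Two results collapse iff dates differ ≤ 7 days and values agree — VL
  within 0.1 log10 or both < 200 copies/mL (which also covers
  below-detection codings, stored as value 0), CD4 exactly. The survivor
  keeps the earlier date and the cohort-origin value. These tolerances are
  this package's defaults (`FuzzyLabRule`), chosen conservative: ±7 days
  spans courier/reporting lag without bridging distinct quarterly draws,
  and 0.1 log10 is well inside assay variability.

## Continuum definitions and boundary conventions

Window: 2014-06-15 to 2015-06-15, endpoints inclusive. Eligibility keeps
active, non-withdrawn, non-transferred persons, alive at window start, with
≥ 365 days of follow-up by window end (enrollment 364 days before the end
is excluded). Exclusion reasons are tallied in that fixed order.

- RIC: two deduplicated encounter dates in the window with a gap ≥ 90 days
  ("at least 90 days apart" read inclusively; two encounters on one date
  count once). Encounters are visits and labs from any site.
- On ART: prescription interval overlaps the window, inclusive ends;
  open-ended prescriptions overlap iff they start by window end.
- VS: defined only for persons with RIC ∧ on-ART ∧ ≥1 VL on file by window
  end; true iff the last such VL < 200 copies/mL (strict: 199 suppressed,
  200 not). Same-date ties keep the cohort-origin value, then the lower
  value.
- LTFU: latest event ≥ 18 calendar months (same day-of-month anchor,
  inclusive at exactly 18) before the reference date; a person with no
  dated events is LTFU and flagged degenerate.
- Care sites: one = no lab away from the enrollment site; three-plus = ≥2
  labs from ≥2 distinct other facilities; two = anything in between.

These conventions make the metrics monotone under data augmentation: adding
labs can only raise RIC and ever-VS and move the site category away from
"one", which is what makes the pre/post comparison interpretable.

## Statistics

Cohen's kappa from the square pre-vs-post table, with the degenerate
all-mass-in-one-cell case returned as 1. Verbal bands are labels only:
≥ .60 strong, .40–.59 moderate, < .40 poor to fair. Pearson chi-square
without continuity correction; a zero expected cell is an error naming the
cell. The Wilcoxon rank-sum uses midranks; exact enumeration of all
C(n, n₁) rank assignments when n₁+n₂ ≤ 12, otherwise a normal approximation
with tie correction and continuity correction (matching R's `wilcox.test`
default; measured against exact enumeration the corrected approximation
stays within 0.02 even at n₁=n₂=6, where the uncorrected version strays to
0.06). Zero pooled variance reports p = 1. The chi-square permutation
cross-check in the tests resamples a 2×2 table conditional on its margins
(hypergeometric) at n=2000, where asymptotic-vs-conditional agreement to
0.01 is realistic; at small n the two genuinely differ and the comparison
would be meaningless. Whether the pre/post outcome contrast should be a
paired (McNemar-type) or independent test is open; the report gives the
independent chi-square with the paired kappa alongside.

## Synthetic data: what it emulates

One ground-truth population is projected onto three registries. Per-person
randomness derives from `[seed, person_uid, phase]`, so person k is
identical in any population of size > k and regeneration is bit-identical.

Attribute marginals default to those of a large urban HIV cohort: 26%
female; race 73.7 / 15.7 / 10.6% (non-Hispanic Black / White / other);
residence 74.1 / 18.8 / 5.7 / 1.3% (in-jurisdiction / MD / VA / other);
transmission risk 1.4 / 0 / 40.2 / 27.5 / 4.0 / 8.0% with 18.9% missing;
care-site mixture 76.83 / 15.49 / 7.68% (one / two / three-plus sites);
per-stratum viral suppression 89.51 / 85 / 72.3%. Age ~ N(44.3, 13.2²)
clipped to [18, 85]; enrollment uniform 2011-01 to 2015-05; time from
diagnosis to enrollment ~ Gamma(2, 7) years (mean 14); 63.3% ever-AIDS;
3.2% deceased; 4% withdrawn, 3% transferred.

Care process: 62% of persons are "engaged" (encounters every 70–130 days);
the rest average 0.8 encounters/year. Every encounter yields a same-day VL
and CD4 at its facility. Multi-site persons draw 55–70% of encounters away
from the enrollment site, and at least one encounter at every external care
site is guaranteed, so the true site category is always recoverable from
the full lab history. Suppression probability couples to engagement
(+0.08 / −0.13; the offsets cancel in the 0.62/0.38 mixture so the stratum
marginals above are preserved): fragmented, clinic-invisible care tracks
worse virologic control, which is what makes the post-linkage suppression
estimate fall below the pre-linkage one once the silently-transferred
encounters appear — the directional pattern the pipeline exists to expose.

Identity corruption applies to the surveillance-side (and STD-side) copy
only, at most one perturbation per field: single-edit typos (5%/name),
nickname substitution (3%, via a packaged two-way map), surname change
(2%), day/month transposition (2% when the day is ≤ 12), SSN dropped (8%);
7% of persons have no SSN anywhere. These rates leave ~98.5–99.5% of
corrupted records with at least two agreeing keys; the irreducible
remainder (missing SSN combined with a nickname or surname change) has
*zero* agreeing exact keys and bounds what any deterministic catalogue can
recover.

Differential capture: residents appear in surveillance with probability
0.99, non-residents 0.75 (overall ≈ 93% of the cohort, with non-residents
dominating the unmatched); surveillance captures 92% of CD4s, 85% of
unsuppressed VLs but only 15% of suppressed VLs; the cohort holds all
enrollment-site labs and 25% of outside labs. This reproduces the
registry-level signature — surveillance VL counts far below cohort VL
counts while CD4 counts are comparable — and the person-level one
(surveillance-only persons ever-suppressed far less often).

What it does **not** emulate: disease progression or VL/CD4 trajectories
(values are drawn i.i.d. per encounter given the person's suppression
state), transmission dynamics, geographic structure, duplicate enrollment
(every synthetic person is singly enrolled; a real pipeline collapses
co-enrollees first), record-level twins (two distinct persons sharing a
name and DOB), or correlated comorbidity structure (conditionally
independent given stratum). Passing tests therefore show the machinery is
correct under realistic noise and capture patterns, not that real-world
precision/recall will match: real registries contain twin-like identities
that cost precision, and messier free-text fields that cost recall.

## Problem sizes

The test suite runs the full pipeline at n=400–2,500 and the recovery check
at n=10,000 (the package's chosen reference size: large enough that all
category proportions are stable to well under a percentage point); the
directional pre/post check uses 20 seeds at n=2,500, where the suppression
drop's sign is stable. The acceptance script runs n=10,000 once plus
n=2,000 and n=400 linkage runs, about 15 s total.

## Known limitations

- The key catalogue, acceptance threshold and conflict policy are faithful
  to deterministic-linkage practice but are one reasonable instantiation;
  all are configurable, and reported precision/recall always refer to the
  generator's truth set under the configured error model.
- Fuzzy-lab tolerances and the cohort-wins tie-breaks are defaults, not
  estimates; sensitivity to them can be explored through `FuzzyLabRule`.
- `proportion` uses half-up decimal rounding to match how published tables
  round; Python's default banker's rounding would disagree on exact halves.
- Real eHARS / STD*MIS export formats, HL7 messaging, PHI transport and
  manual-review tooling are out of scope; readers expect this package's
  documented CSV schemas.
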