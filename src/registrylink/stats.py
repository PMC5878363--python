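"""Comparison statistics and report assembly.

Cohen's kappa, Pearson chi-square (no continuity correction), and the
Wilcoxon rank-sum test (midranks, tie-corrected normal approximation, exact
enumeration at small n) are computed from first principles; the chi-square
tail probability comes from scipy's chi-square distribution.  Cascade and
pre/post comparison builders keep every percentage with its numerator and
denominator so reported values always recompute exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .continuum import ContinuumStatus, SiteCategory


def proportion(numerator: int, denominator: int, decimals: int = 2) -> float | None:
    """Percentage 100*n/d rounded half-up to the requested decimals.

    A zero denominator returns None (explicit undefined marker).
    """
    if denominator == 0:
        return None
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    exact = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# agreement and hypothesis tests


def cohen_kappa(table: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Chance-corrected agreement from a square contingency table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal fraction and p_e
    the product of the margins.  The degenerate case p_e = 1 (all mass in a
    single row and column, so p_o = 1) returns 1 by convention.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("kappa requires a square table")
    total = t.sum()
    if total <= 0:
        raise ValueError("table total must be positive")
    p_o = np.trace(t) / total
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / total**2
    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1 - p_e))


def kappa_band(kappa: float) -> str:
    """Verbal agreement label: strong >= .60, moderate .40-.59, else poor to fair."""
    if kappa >= 0.60:
        return "strong"
    if kappa >= 0.40:
        return "moderate"
    return "poor to fair"


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_test(table: np.ndarray | Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0:
        raise ValueError("table total must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    zeros = np.argwhere(expected == 0)
    if len(zeros):
        r, c = zeros[0]
        raise ValueError(f"expected count is zero in cell ({r}, {c})")
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return ChiSquareResult(stat, df, float(sps.chi2.sf(stat, df)))


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample
    p_value: float
    method: str  # "exact" or "normal"


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> RankSumResult:
    """Wilcoxon rank-sum test with midrank ties.

    Exact enumeration over all rank assignments when n1 + n2 <= 12 (or when
    forced); otherwise a tie-corrected normal approximation with continuity
    correction (matching R's wilcox.test default).  Samples with zero pooled
    variance (all values identical) report p = 1 by convention.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative: {alternative}")
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sps.rankdata(x + y)
    w = float(ranks[:n1].sum())
    if method == "auto":
        method = "exact" if n <= 12 else "normal"

    if method == "exact":
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n1)), dtype=float
        )
        mean = sums.mean()
        eps = 1e-9
        p_less = float((sums <= w + eps).mean())
        p_greater = float((sums >= w - eps).mean())
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = float((np.abs(sums - mean) >= abs(w - mean) - eps).mean())
        return RankSumResult(w, min(p, 1.0), "exact")

    mean = n1 * (n + 1) / 2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return RankSumResult(w, 1.0, "normal")
    sd = np.sqrt(var)
    if alternative == "less":
        p = float(sps.norm.cdf((w - mean + 0.5) / sd))
    elif alternative == "greater":
        p = float(sps.norm.sf((w - mean - 0.5) / sd))
    else:
        p = float(2 * sps.norm.sf((abs(w - mean) - 0.5) / sd))
    return RankSumResult(w, min(p, 1.0), "normal")


def format_p(p: float) -> str:
    """Report-style p value: '<.001' below 0.001, else 3 decimals without
    the leading zero."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")


# ---------------------------------------------------------------------------
# cascade and pre/post comparison


@dataclass(frozen=True)
class CascadeStage:
    stage: str
    numerator: int
    denominator: int

    @property
    def pct(self) -> float | None:
        return proportion(self.numerator, self.denominator)


def build_cascade(
    statuses: Sequence[ContinuumStatus], stratify_by_sites: bool = False
) -> dict[str, list[CascadeStage]]:
    """Nested continuum counts: matched -> RIC -> on-ART (among RIC) -> VS
    (among RIC and on-ART with a VL on file).  Each stage's denominator is
    the prior stage's numerator; the VS denominator additionally requires a
    VL on file, mirroring how the suppression percentage is defined.
    """

    def one(group: Sequence[ContinuumStatus]) -> list[CascadeStage]:
        matched = len(group)
        ric = [s for s in group if s.ric]
        ric_art = [s for s in ric if s.on_art]
        vs_denom = [s for s in ric_art if s.vs is not None]
        vs = [s for s in vs_denom if s.vs]
        return [
            CascadeStage("matched", matched, matched),
            CascadeStage("ric", len(ric), matched),
            CascadeStage("on_art", len(ric_art), len(ric)),
            CascadeStage("vs", len(vs), len(vs_denom)),
        ]

    cascades = {"overall": one(statuses)}
    if stratify_by_sites:
        for cat in SiteCategory:
            cascades[cat.value] = one([s for s in statuses if s.site_category is cat])
    return cascades


@dataclass
class OutcomeComparison:
    variable: str
    pre_numerator: int
    pre_denominator: int
    post_numerator: int
    post_denominator: int
    kappa: float | None
    chi2: ChiSquareResult | None

    @property
    def pre_pct(self) -> float | None:
        return proportion(self.pre_numerator, self.pre_denominator)

    @property
    def post_pct(self) -> float | None:
        return proportion(self.post_numerator, self.post_denominator)

    @property
    def significant(self) -> bool | None:
        return None if self.chi2 is None else self.chi2.p_value < 0.05


@dataclass
class ComparisonReport:
    outcomes: list[OutcomeComparison]
    pre_cascade: dict[str, list[CascadeStage]] = field(default_factory=dict)
    post_cascade: dict[str, list[CascadeStage]] = field(default_factory=dict)


_BINARY_VARIABLES = ("ric", "vs", "ever_vs")


def _flag(status: ContinuumStatus, variable: str) -> bool | None:
    value = getattr(status, variable)
    return value


def compare_pre_post(
    pre: Sequence[ContinuumStatus],
    post: Sequence[ContinuumStatus],
    variables: Sequence[str] = _BINARY_VARIABLES,
) -> ComparisonReport:
    """Pre- vs post-linkage outcome comparison over one person universe.

    Per variable: numerators/denominators in each dataset, the paired kappa
    (pre vs post classification of the persons defined in both), and an
    independent chi-square on the two outcome distributions.  Persons with
    an undefined flag (e.g. outside the VS denominator) drop out of that
    variable's counts.
    """
    pre_by_id = {s.study_id: s for s in pre}
    post_by_id = {s.study_id: s for s in post}
    if set(pre_by_id) != set(post_by_id):
        diff = sorted(set(pre_by_id) ^ set(post_by_id))
        raise ValueError(f"pre/post person universes differ: {diff[:10]}")

    outcomes = []
    for var in variables:
        pre_flags = {i: _flag(s, var) for i, s in pre_by_id.items()}
        post_flags = {i: _flag(s, var) for i, s in post_by_id.items()}
        pre_defined = {i: v for i, v in pre_flags.items() if v is not None}
        post_defined = {i: v for i, v in post_flags.items() if v is not None}

        both = sorted(set(pre_defined) & set(post_defined))
        kappa = None
        if both:
            agreement = np.zeros((2, 2))
            for i in both:
                agreement[int(pre_defined[i]), int(post_defined[i])] += 1
            kappa = cohen_kappa(agreement)

        chi2 = None
        pre_n, pre_d = sum(pre_defined.values()), len(pre_defined)
        post_n, post_d = sum(post_defined.values()), len(post_defined)
        table = np.array([[pre_n, pre_d - pre_n], [post_n, post_d - post_n]])
        if pre_d and post_d and (table.sum(axis=0) > 0).all():
            chi2 = chi_square_test(table)

        outcomes.append(
            OutcomeComparison(var, pre_n, pre_d, post_n, post_d, kappa, chi2)
        )

    return ComparisonReport(
        outcomes=outcomes,
        pre_cascade=build_cascade(pre, stratify_by_sites=True),
        post_cascade=build_cascade(post, stratify_by_sites=True),
    )
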