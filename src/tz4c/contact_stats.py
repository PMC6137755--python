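"""Contact statistics for 4C profiles and their significance tests.

Three scale-free summaries of a masked raw-count profile:

* **invasion ratio** — reads landing beyond the boundary in the adjacent
  domain ("invasion reads") divided by reads on the viewpoint's own side
  ("control reads"); quantifies inter-domain contact.
* **directionality score** — (right − left) / (right + left) read counts
  within a fixed window (default 200 kb) on each side of the viewpoint;
  negative means centromere-biased folding, positive telomere-biased.
* **four-area proportions** — percentage of reads in four named areas
  tiling the locus, plus the telomeric/centromeric intra-domain ratio.

Group comparisons use a one-sided permutation test on the per-replicate
values (exact enumeration at these replicate numbers) and one-way ANOVA
with Tukey's HSD post hoc.  All statistics consume raw masked counts, never
RPM-normalized or smoothed values: the summaries are ratios, so library
size cancels, and smoothing would correlate adjacent fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .fourc_processing import ContactProfile, count_in_intervals
from .locus_model import GenomicInterval, Viewpoint

__all__ = [
    "InvasionResult",
    "DirectionalityResult",
    "ProportionResult",
    "TestResult",
    "invasion_ratio",
    "directionality_score",
    "interval_proportions",
    "permutation_test_one_sided",
    "anova_tukey",
]


@dataclass(frozen=True)
class InvasionResult:
    viewpoint: str
    allele: str
    replicate: int
    invasion_count: int
    control_count: int
    ratio: float


@dataclass(frozen=True)
class DirectionalityResult:
    viewpoint: str
    allele: str
    left_count: int
    right_count: int
    score: float


@dataclass(frozen=True)
class ProportionResult:
    viewpoint: str
    allele: str
    counts: dict[str, int]
    percentages: dict[str, float]
    tel_cen_ratio: float | None


@dataclass(frozen=True)
class TestResult:
    method: str  # permutation_one_sided | anova | tukey
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    min_p: float | None = None  # resolution floor of an exact test


def invasion_ratio(
    profile: ContactProfile,
    invasion: GenomicInterval,
    control: GenomicInterval,
) -> InvasionResult:
    """Ratio of reads in the invasion interval (beyond the boundary, in the
    adjacent domain) to reads in the control interval (the viewpoint's own
    side).  Intervals must be disjoint; a zero control count leaves the
    ratio undefined and raises."""
    if invasion.overlaps(control):
        raise ValueError("invasion and control intervals must be disjoint")
    inv = GenomicInterval(invasion.chrom, invasion.start, invasion.end, "invasion")
    ctl = GenomicInterval(control.chrom, control.start, control.end, "control")
    counts = count_in_intervals(profile, [inv, ctl])
    ci = counts["control"]
    if ci == 0:
        raise ZeroDivisionError("control interval has zero reads; ratio undefined")
    return InvasionResult(
        profile.viewpoint.name,
        profile.allele,
        profile.replicate,
        counts["invasion"],
        ci,
        counts["invasion"] / ci,
    )


def directionality_score(
    profile: ContactProfile,
    viewpoint: Viewpoint | None = None,
    window: int = 200_000,
) -> DirectionalityResult:
    """(right − left) / (right + left) raw masked read counts within
    ``window`` bp on each side of the viewpoint, clipped to the modeled
    span (no renormalization at the edges)."""
    vp = profile.viewpoint if viewpoint is None else viewpoint
    span = profile.fragment_map.span
    chrom = span.chrom
    left_lo = max(vp.position - window, span.start)
    right_hi = min(vp.position + window, span.end)
    regions = []
    if left_lo < vp.position:
        regions.append(GenomicInterval(chrom, left_lo, vp.position, "left"))
    if vp.position < right_hi:
        regions.append(GenomicInterval(chrom, vp.position, right_hi, "right"))
    counts = count_in_intervals(profile, regions)
    left = counts.get("left", 0)
    right = counts.get("right", 0)
    if left + right == 0:
        raise ZeroDivisionError("no reads within the window; score undefined")
    score = (right - left) / (right + left)
    return DirectionalityResult(vp.name, profile.allele, left, right, score)


def interval_proportions(
    profile: ContactProfile,
    areas: Sequence[GenomicInterval],
    tel_area: str = "Tfap2c-tel",
    cen_area: str = "Tfap2c-cen",
) -> ProportionResult:
    """Percentage of masked raw reads in each named area (summing to 100
    over the areas) and the telomeric/centromeric intra-domain ratio."""
    counts = count_in_intervals(profile, areas)
    total = sum(counts.values())
    if total == 0:
        raise ZeroDivisionError("no reads in any area; proportions undefined")
    percentages = {k: 100.0 * v / total for k, v in counts.items()}
    ratio = None
    if tel_area in counts and cen_area in counts and counts[cen_area] > 0:
        ratio = counts[tel_area] / counts[cen_area]
    return ProportionResult(
        profile.viewpoint.name, profile.allele, counts, percentages, ratio
    )


def permutation_test_one_sided(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "greater",
    max_exact: int = 20_000,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """One-sided two-sample permutation test on the difference of means.

    The statistic is mean(group_b) − mean(group_a); ``alternative="greater"``
    asks whether group_b exceeds group_a.  All C(n_a+n_b, n_a) label
    reassignments are enumerated when that count is at most ``max_exact``;
    otherwise ``n_resamples`` Monte Carlo reassignments are drawn with a
    fixed seed and the observed assignment is included.  The p-value counts
    reassignments whose statistic is at least as extreme as the observed one
    (ties count as extreme), so p is never 0; ``min_p`` reports the exact
    test's resolution floor 1/#reassignments.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    pooled = np.concatenate([a, b])
    n_a, n_b = len(a), len(b)
    obs = b.mean() - a.mean()
    tol = 1e-12 * max(1.0, abs(obs))

    def extreme(stat: float) -> bool:
        if alternative == "greater":
            return stat >= obs - tol
        return stat <= obs + tol

    n_total = math.comb(n_a + n_b, n_a)
    if n_total <= max_exact:
        hits = 0
        idx_all = range(n_a + n_b)
        total_sum = pooled.sum()
        for a_idx in combinations(idx_all, n_a):
            sa = pooled[list(a_idx)].sum()
            stat = (total_sum - sa) / n_b - sa / n_a
            hits += extreme(stat)
        p = hits / n_total
        floor = 1 / n_total
    else:
        rng = np.random.default_rng(seed)
        hits = 1  # the observed assignment
        for _ in range(n_resamples):
            perm = rng.permutation(pooled)
            stat = perm[n_a:].mean() - perm[:n_a].mean()
            hits += extreme(stat)
        p = hits / (n_resamples + 1)
        floor = 1 / (n_resamples + 1)
    return TestResult(
        "permutation_one_sided", obs, p, ("a", "b"), (n_a, n_b), min_p=floor
    )


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    reference: str | None = None,
) -> list[TestResult]:
    """One-way fixed-effects ANOVA followed by Tukey's HSD post hoc.

    Returns the ANOVA result first, then one TestResult per pair with the
    Tukey-adjusted p-value; pairs involving ``reference`` come first.  Each
    group needs at least two values.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least two values")
    ns = tuple(len(g) for g in arrays)

    grand = np.concatenate(arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in arrays)
    results: list[TestResult] = []
    if ss_within == 0:
        # degenerate: no residual variance
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
        results.append(TestResult("anova", f_stat, p, tuple(names), ns))
        pairs = _ordered_pairs(names, reference)
        for x, y in pairs:
            diff = float(np.mean(groups[y]) - np.mean(groups[x]))
            p_pair = 1.0 if diff == 0 else 0.0
            results.append(
                TestResult(
                    "tukey", diff, p_pair, (x, y), (len(groups[x]), len(groups[y]))
                )
            )
        return results

    f_stat, p = sps.f_oneway(*arrays)
    results.append(TestResult("anova", float(f_stat), float(p), tuple(names), ns))

    hsd = sps.tukey_hsd(*arrays)
    for x, y in _ordered_pairs(names, reference):
        i, j = names.index(x), names.index(y)
        results.append(
            TestResult(
                "tukey",
                float(hsd.statistic[j, i]),  # mean(y) - mean(x)
                float(hsd.pvalue[i, j]),
                (x, y),
                (ns[i], ns[j]),
            )
        )
    return results


def _ordered_pairs(
    names: Sequence[str], reference: str | None
) -> list[tuple[str, str]]:
    pairs = list(combinations(names, 2))
    if reference is None or reference not in names:
        return pairs
    ref_pairs = [p for p in pairs if reference in p]
    ref_pairs = [(reference, a if b == reference else b) for a, b in ref_pairs]
    other = [p for p in pairs if reference not in p]
    return ref_pairs + other
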