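"""Range-size comparison statistics across taxon classes and threat groups.

Nonparametric tests mirror the field's standard workflow: a Kruskal-Wallis
rank-sum test across all groups, followed by pairwise two-sided Wilcoxon
rank-sum (Mann-Whitney U) tests with continuity correction and tie-corrected
normal approximation.  The "majority protectable" counting rule asks how many
species could have most of their range covered by a single reserve of a given
area.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .core import SpeciesRange, THREATENED_OR_EXTINCT


@dataclass
class RankTestResult:
    """Outcome of a rank test: statistic, p-value, group sizes, method label."""

    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
        if self.statistic < 0:
            raise ValueError(f"negative rank statistic: {self.statistic}")


def median_range_areas(
    groups: dict[str, list[float] | np.ndarray],
) -> dict[str, float]:
    """Exact sample median of range area per group (midpoint rule at even n)."""
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = float(np.median(arr))
    return out


def rank_sum_test(x, y) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test with continuity correction.

    Mann-Whitney U with midranks for ties; the p-value comes from the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction (the conventional large-sample recipe) at every sample size.
    When every value in both samples is identical, the statistic is its null
    mean n_x*n_y/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return RankTestResult(
            statistic=x.size * y.size / 2.0,
            p_value=1.0,
            n_per_group=(x.size, y.size),
            method="wilcoxon-rank-sum",
        )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(x.size, y.size),
        method="wilcoxon-rank-sum",
    )


def kruskal_wallis(groups: list) -> RankTestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square on k-1 df.

    All-identical data across groups yields H = 0, p = 1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    if np.ptp(np.concatenate(arrays)) == 0.0:
        return RankTestResult(
            statistic=0.0,
            p_value=1.0,
            n_per_group=tuple(a.size for a in arrays),
            method="kruskal-wallis",
        )
    h, p = stats.kruskal(*arrays)
    return RankTestResult(
        statistic=float(h),
        p_value=float(p),
        n_per_group=tuple(a.size for a in arrays),
        method="kruskal-wallis",
    )


def pairwise_rank_sum(
    groups: dict[str, list[float] | np.ndarray],
) -> dict[tuple[str, str], RankTestResult]:
    """All pairwise rank-sum tests between named groups (unadjusted)."""
    return {
        (a, b): rank_sum_test(groups[a], groups[b])
        for a, b in combinations(sorted(groups), 2)
    }


def count_majority_protectable(
    ranges: list[SpeciesRange],
    reserve_area_km2: float,
    status_filter: set[str] | frozenset[str] | None = None,
) -> int:
    """Count species for which one reserve covers a strict majority of range.

    A reserve of ``reserve_area_km2`` covers more than half of a range
    exactly when the range area is strictly below twice the reserve area.
    ``status_filter`` restricts the count to species in those statuses (e.g.
    ``{"EN"}`` or the threatened-or-extinct set); ``None`` counts everything.
    """
    if reserve_area_km2 <= 0:
        raise ValueError("reserve_area_km2 must be > 0")
    threshold = 2.0 * reserve_area_km2
    return sum(
        1
        for r in ranges
        if (status_filter is None or r.status in status_filter)
        and r.area_km2 < threshold
    )


def range_stats_report(
    ranges: list[SpeciesRange], reserve_area_km2: float = 10.0
) -> dict:
    """JSON-ready report: per-class medians and tests, threat-group contrast.

    Covers the standard comparisons: medians per taxon class, the global
    Kruskal-Wallis test, pairwise rank-sum tests, the same restricted to
    threatened-or-extinct species, the within-class threatened vs
    non-threatened contrast, and the majority-protectable counts for the
    given reserve area (all statuses, T&E, and EN only).
    """
    by_class: dict[str, list[float]] = {}
    for r in ranges:
        by_class.setdefault(r.taxon_class, []).append(r.area_km2)

    report: dict = {"medians_km2": median_range_areas(by_class)}
    if len(by_class) >= 2:
        kw = kruskal_wallis(list(by_class.values()))
        report["kruskal_wallis"] = {"H": kw.statistic, "p": kw.p_value}
        report["pairwise"] = {
            f"{a}|{b}": {"U": t.statistic, "p": t.p_value}
            for (a, b), t in pairwise_rank_sum(by_class).items()
        }

    te_by_class: dict[str, list[float]] = {}
    for r in ranges:
        if r.status in THREATENED_OR_EXTINCT:
            te_by_class.setdefault(r.taxon_class, []).append(r.area_km2)
    if len(te_by_class) >= 2 and all(te_by_class.values()):
        report["medians_te_km2"] = median_range_areas(te_by_class)
        report["pairwise_te"] = {
            f"{a}|{b}": {"U": t.statistic, "p": t.p_value}
            for (a, b), t in pairwise_rank_sum(te_by_class).items()
        }

    threatened = [r.area_km2 for r in ranges if r.status in THREATENED_OR_EXTINCT]
    non_threatened = [
        r.area_km2
        for r in ranges
        if r.status not in THREATENED_OR_EXTINCT and r.status not in {"DD", "NE"}
    ]
    if threatened and non_threatened:
        t = rank_sum_test(threatened, non_threatened)
        report["threatened_vs_nonthreatened"] = {
            "median_threatened": float(np.median(threatened)),
            "median_nonthreatened": float(np.median(non_threatened)),
            "U": t.statistic,
            "p": t.p_value,
        }

    report["majority_protectable"] = {
        "reserve_area_km2": reserve_area_km2,
        "all": count_majority_protectable(ranges, reserve_area_km2),
        "threatened_or_extinct": count_majority_protectable(
            ranges, reserve_area_km2, THREATENED_OR_EXTINCT
        ),
        "EN_only": count_majority_protectable(ranges, reserve_area_km2, {"EN"}),
    }
    return report
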