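"""Power-to-detect-change and between-location/over-time statistics.

Two power procedures sit at the heart of index monitoring with replicated
street counts:

*Minimum detectable change in density.*  Each route is surveyed twice on
consecutive days; the per-route differences ``d_i`` between the two
replicate densities estimate day-to-day noise.  Their mean divided by its
standard error follows a Student-t distribution with n−1 degrees of freedom
(n = number of routes), so a future survey must differ from the baseline
mean by more than ``t_{1−α/2, n−1} · SE`` before the change is
distinguishable from replicate noise.

*Change in a composition fraction.*  With ``n`` females counted and a
fraction ``p`` lactating, the observed fraction is approximately normal
with sd ``sqrt(p(1−p)/n)``.  Two surveys are compared with the pooled
two-proportion z test: under the null the difference of fractions has sd
``sqrt((1/n1 + 1/n2) · p(1−p))`` with ``p`` pooled over both surveys, and a
change is significant when the fractions differ by more than ``z_{1−α/2}``
times that sd.

Location comparisons use one-way ANOVA (density) and the tie-corrected
Kruskal–Wallis H test (percentage indicators), both computed from their
defining formulas; trends over repeat surveys use ordinary least squares on
decimal-year time.  No multiple-testing correction is applied across
indicators.
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .indicators import SurveyEvent, dogs_per_km
from .survey_io import Route

__all__ = [
    "PowerResult",
    "CompositionChangeResult",
    "RequiredSampleResult",
    "GroupComparisonResult",
    "TrendResult",
    "replicate_differences",
    "min_detectable_change",
    "composition_change_test",
    "required_second_sample",
    "one_way_anova",
    "kruskal_wallis",
    "linear_trend",
    "decimal_year",
]


@dataclass(frozen=True)
class PowerResult:
    """Minimum detectable change in density from replicate differences."""

    n_routes: int
    diffs: Optional[tuple[float, ...]]
    mean_diff: float
    se_diff: float
    t_crit: float
    min_detectable_abs: float
    min_detectable_pct: float
    baseline_mean: float
    alpha: float


@dataclass(frozen=True)
class CompositionChangeResult:
    """Pooled two-proportion z test between two composition fractions."""

    n1: int
    n2: int
    p1: float
    p2: float
    p_pooled: float
    sd_null: float
    z_crit: float
    significant: bool
    alpha: float


@dataclass(frozen=True)
class RequiredSampleResult:
    """Smallest second-survey count that makes a fraction change significant.

    ``reachable`` is False when the difference is too small ever to reach
    significance given the first survey's size, however large the second
    survey grows; ``limit_diff`` is the asymptotic detection threshold as
    n2 → ∞.
    """

    n2: Optional[int]
    reachable: bool
    limit_diff: float


@dataclass(frozen=True)
class GroupComparisonResult:
    """F or H statistic with degrees of freedom and p-value."""

    statistic: float
    df: tuple[int, ...]
    p_value: float
    method: str


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of an indicator on decimal-year time."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


# ---------------------------------------------------------------------------
# Power procedures
# ---------------------------------------------------------------------------

def replicate_differences(
    events: Iterable[SurveyEvent], routes: Mapping[str, Route]
) -> list[float]:
    """Per-route difference between the densities of the first two replicates.

    Replicates are ordered by survey date; events with more than two
    replicates contribute the earliest pair (the statistic is defined for
    pairs, keeping the t-distribution's n−1 degrees of freedom valid).
    """
    diffs = []
    for event in events:
        if len(event.replicates) < 2:
            raise ValueError(
                f"route {event.route_id!r}: event {event.event_label!r} has fewer than "
                "2 replicates; the day-to-day variance estimate needs a pair"
            )
        first, second = sorted(event.replicates, key=lambda r: r.survey_date)[:2]
        route = routes[event.route_id]
        diffs.append(dogs_per_km(first, route) - dogs_per_km(second, route))
    return diffs


def min_detectable_change(
    diffs: Optional[Sequence[float]] = None,
    baseline_mean: float = 0.0,
    alpha: float = 0.05,
    *,
    n: Optional[int] = None,
    se_diff: Optional[float] = None,
    mean_diff: Optional[float] = None,
) -> PowerResult:
    """Minimum change in mean density detectable at two-sided level alpha.

    Either pass the per-route replicate ``diffs`` directly, or — for
    published summaries — pass the route count ``n`` together with the
    pre-computed standard error ``se_diff`` of their mean.

    The threshold is ``t_{1−α/2, n−1} × se_diff`` in absolute dogs/km and,
    relative to the baseline mean density, ``100 ×`` that as a percentage.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    if diffs is not None:
        if n is not None or se_diff is not None:
            raise ValueError("pass either diffs or (n, se_diff), not both")
        d = np.asarray(diffs, dtype=float)
        if d.size < 2:
            raise ValueError("need at least 2 replicate differences")
        n = int(d.size)
        mean_diff = float(d.mean())
        se_diff = float(d.std(ddof=1) / math.sqrt(n))
        kept: Optional[tuple[float, ...]] = tuple(float(x) for x in d)
    else:
        if n is None or se_diff is None:
            raise ValueError("without diffs, both n and se_diff are required")
        if n < 2:
            raise ValueError("need at least 2 routes")
        if se_diff < 0:
            raise ValueError("se_diff must be non-negative")
        mean_diff = 0.0 if mean_diff is None else float(mean_diff)
        kept = None
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    mda = se_diff * t_crit
    return PowerResult(
        n_routes=n,
        diffs=kept,
        mean_diff=mean_diff,
        se_diff=float(se_diff),
        t_crit=t_crit,
        min_detectable_abs=mda,
        min_detectable_pct=100.0 * mda / baseline_mean,
        baseline_mean=float(baseline_mean),
        alpha=alpha,
    )


def composition_change_test(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> CompositionChangeResult:
    """Pooled two-proportion z test for a change in a composition fraction.

    ``k1 of n1`` (e.g. lactating of females counted) in the first survey
    versus ``k2 of n2`` in the second.  The change is significant when
    ``|p1 − p2| > z_{1−α/2} · sqrt((1/n1 + 1/n2) · p(1−p))`` with ``p``
    pooled across both surveys.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n1 < 1 or n2 < 1:
        raise ValueError("both surveys must have counted at least one individual")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    p_pooled = (k1 + k2) / (n1 + n2)
    sd_null = math.sqrt((1.0 / n1 + 1.0 / n2) * p_pooled * (1.0 - p_pooled))
    z_crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    significant = abs(p1 - p2) > z_crit * sd_null
    return CompositionChangeResult(
        n1=n1, n2=n2, p1=p1, p2=p2, p_pooled=p_pooled, sd_null=sd_null,
        z_crit=z_crit, significant=significant, alpha=alpha,
    )


def required_second_sample(
    n1: int,
    p1: float,
    p2: float,
    alpha: float = 0.05,
    max_n2: int = 1_000_000,
) -> RequiredSampleResult:
    """Smallest n2 making the observed fraction change significant.

    Searches ascending integer n2, recomputing the pooled fraction at each
    candidate with expected counts rounded to the nearest integer
    (``k1 = round(p1·n1)``, ``k2 = round(p2·n2)``).  As n2 → ∞ the pooled
    fraction tends to p2 and the null sd to ``sqrt(p2(1−p2)/n1)``; if
    ``|p1 − p2|`` does not exceed ``z_{1−α/2}`` times that limit, no finite
    second survey can reach significance and the result is flagged
    unreachable.  ``max_n2`` caps the search as a safety net.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("p1 and p2 must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    if n1 < 1:
        raise ValueError("n1 must be at least 1")
    z_crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    k1 = round(p1 * n1)
    limit_diff = z_crit * math.sqrt(p2 * (1.0 - p2) / n1)
    if abs(k1 / n1 - p2) <= limit_diff:
        return RequiredSampleResult(n2=None, reachable=False, limit_diff=limit_diff)
    for n2 in range(1, max_n2 + 1):
        k2 = round(p2 * n2)
        if composition_change_test(k1, n1, k2, n2, alpha=alpha).significant:
            return RequiredSampleResult(n2=n2, reachable=True, limit_diff=limit_diff)
    return RequiredSampleResult(n2=None, reachable=False, limit_diff=limit_diff)


# ---------------------------------------------------------------------------
# Between-location comparisons
# ---------------------------------------------------------------------------

def _clean_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    cleaned = []
    for g in groups:
        arr = np.asarray([v for v in g if v is not None], dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size:
            cleaned.append(arr)
    return cleaned


def one_way_anova(groups: Sequence[Sequence[float]]) -> GroupComparisonResult:
    """Classical one-way fixed-effects ANOVA from its sums of squares.

    ``F = (SSB/(k−1)) / (SSW/(N−k))`` with k groups and N values in total.
    If every value is identical (zero within- and between-group variation)
    the statistic is defined as 0 with p = 1.
    """
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups")
    all_v = np.concatenate(cleaned)
    k, N = len(cleaned), all_v.size
    if N - k < 1:
        raise ValueError("need at least one group with 2 or more values")
    grand = all_v.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in cleaned)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in cleaned)
    if ssw == 0.0 and ssb == 0.0:
        return GroupComparisonResult(0.0, (k - 1, N - k), 1.0, "anova")
    if ssw == 0.0:
        return GroupComparisonResult(math.inf, (k - 1, N - k), 0.0, "anova")
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = float(stats.f.sf(F, k - 1, N - k))
    return GroupComparisonResult(float(F), (k - 1, N - k), p, "anova")


def _kw_statistic(values: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    """Tie-corrected Kruskal–Wallis H for values with integer group labels."""
    N = values.size
    ranks = stats.rankdata(values)  # mid-ranks for ties
    H = 0.0
    for g in range(n_groups):
        r = ranks[labels == g]
        H += r.sum() ** 2 / r.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - float(((counts ** 3 - counts).sum())) / (N ** 3 - N)
    if correction == 0.0:  # every value identical
        return 0.0
    return H / correction


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    p_method: str = "chi2",
    max_permutation_n: int = 10,
) -> GroupComparisonResult:
    """Kruskal–Wallis H test with mid-ranks and the standard tie correction.

    Missing values (``None``/NaN — undefined percentages) are dropped before
    ranking; groups left empty are dropped, and at least two groups must
    remain.  ``p_method="chi2"`` (default) uses the chi-square approximation
    with k−1 degrees of freedom; ``p_method="permutation"`` enumerates every
    distinct assignment of the observed values to the group sizes and is
    exact, but is limited to ``max_permutation_n`` total values.
    """
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups after missing-value removal")
    values = np.concatenate(cleaned)
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(cleaned)])
    k, N = len(cleaned), values.size
    H = _kw_statistic(values, labels, k)

    if p_method == "chi2":
        p = float(stats.chi2.sf(H, k - 1)) if H > 0 else 1.0
    elif p_method == "permutation":
        if N > max_permutation_n:
            raise ValueError(
                f"exact permutation p limited to {max_permutation_n} values, got {N}"
            )
        ge = total = 0
        for perm in _distinct_label_permutations(labels):
            total += 1
            if _kw_statistic(values, perm, k) >= H - 1e-12:
                ge += 1
        p = ge / total
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return GroupComparisonResult(float(H), (k - 1,), p, f"kruskal-wallis[{p_method}]")


def _distinct_label_permutations(labels: np.ndarray):
    """Yield each distinct multiset permutation of the label vector once."""
    seen = set()
    for perm in itertools.permutations(labels.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


# ---------------------------------------------------------------------------
# Trends over repeat surveys
# ---------------------------------------------------------------------------

def decimal_year(date: dt.date) -> float:
    """Calendar date as a decimal year (day-of-year fraction)."""
    start = dt.date(date.year, 1, 1)
    days = (dt.date(date.year + 1, 1, 1) - start).days
    return date.year + (date - start).days / days


def linear_trend(dates: Sequence[dt.date], values: Sequence[float]) -> TrendResult:
    """OLS regression of an indicator on decimal-year survey time.

    Returns the slope per year, intercept, R², and the two-sided p-value for
    slope = 0.  Requires at least 3 points on distinct dates (Table-style
    monitoring series have unequal spacing, hence real dates, not indices).
    """
    if len(dates) != len(values):
        raise ValueError("dates and values must have equal length")
    if len(dates) < 3:
        raise ValueError("need at least 3 time points for a trend")
    if len(set(dates)) != len(dates):
        raise ValueError("survey dates must be distinct")
    x = np.asarray([decimal_year(d) for d in dates], dtype=float)
    y = np.asarray(values, dtype=float)
    if np.allclose(y, y[0]):
        return TrendResult(0.0, float(y[0]), 0.0, 1.0, len(dates))
    res = stats.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n_points=len(dates),
    )
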