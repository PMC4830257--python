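"""Caliper bump test for p-values just below a significance threshold.

Under any mixture of true and null effects the density of p-values is
monotone non-increasing, so of the p-values falling in two adjacent narrow
intervals below .05 at most half should lie in the upper interval.  The
Caliper test is the exact one-tailed binomial test of H0: Pr <= .5 against
H1: Pr > .5, where Pr is the share of the upper interval; Pr > .5 signals
a "bump" of just-significant results.  A per-year sequence of Pr values,
centred and shifted by .5, supports a linear trend test for growth of the
bump over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["CaliperResult", "TrendFit", "caliper_test", "caliper_by_year", "bump_trend"]

#: interval widths used in the journal analyses
DEFAULT_BINWIDTHS = (0.00125, 0.0025, 0.005, 0.01)

#: spacing of the reported-p grid (p-values are preferentially reported
#: to two decimals, so reported-mode intervals sit just below .04 and .05)
REPORTED_GRID_STEP = 0.01


@dataclass(frozen=True)
class CaliperResult:
    """Counts and exact binomial test for one pair of caliper intervals.

    ``x`` is the count in the upper interval, ``N`` the total across both.
    ``p_binomial`` is P(X >= x | N, 1/2), one-tailed; ``None`` when N = 0
    ("no test").
    """

    x: int
    N: int
    binwidth: float
    upper_bound: float
    bins: tuple[tuple[float, float], tuple[float, float]]

    @property
    def Pr(self) -> float | None:
        return self.x / self.N if self.N > 0 else None

    @property
    def p_binomial(self) -> float | None:
        if self.N == 0:
            return None
        return stats.binomtest(self.x, self.N, 0.5, alternative="greater").pvalue


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of (Pr - .5) on centred year.

    The intercept estimates the bump at ``center_year`` (0 = no bump); the
    slope is the change per year.  P-values are two-tailed.
    """

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_t: float
    slope_t: float
    intercept_p: float
    slope_p: float
    n_years: int
    center_year: int
    timespan: tuple[int, int]


def _caliper_bins(
    binwidth: float, upper: float, mode: str
) -> tuple[tuple[float, float], tuple[float, float]]:
    if mode == "recalculated":
        return ((upper - 2 * binwidth, upper - binwidth), (upper - binwidth, upper))
    if mode == "reported":
        lower_anchor = upper - REPORTED_GRID_STEP
        return ((lower_anchor - binwidth, lower_anchor), (upper - binwidth, upper))
    raise ValueError(f"unknown caliper mode: {mode}")


def caliper_test(
    p_values: Iterable[float],
    binwidth: float = 0.00125,
    upper: float = 0.05,
    mode: str = "recalculated",
) -> CaliperResult:
    """Compare p-value counts in two caliper intervals below ``upper``.

    In ``recalculated`` mode the intervals are the two adjacent half-open
    bins [upper-2w, upper-w) and [upper-w, upper).  In ``reported`` mode
    they honour the rounding conventions of reported p-values: the lower
    interval ends at the two-decimal gridpoint one reporting step below
    ``upper`` and *includes* it, i.e. (.04-w, .04] versus [.05-w, .05) for
    the default threshold; a value exactly equal to ``upper`` is excluded
    in both modes.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    if upper - 2 * binwidth < 0 and mode == "recalculated":
        raise ValueError("binwidth too large for upper bound")
    (lo_l, hi_l), (lo_u, hi_u) = bins = _caliper_bins(binwidth, upper, mode)
    if mode == "reported":
        in_lower = (p > lo_l) & (p <= hi_l)
    else:
        in_lower = (p >= lo_l) & (p < hi_l)
    in_upper = (p >= lo_u) & (p < hi_u)
    x = int(in_upper.sum())
    return CaliperResult(
        x=x, N=x + int(in_lower.sum()), binwidth=binwidth, upper_bound=upper, bins=bins
    )


def caliper_by_year(
    p_values: Iterable[float],
    years: Iterable[int],
    binwidth: float = 0.00125,
    upper: float = 0.05,
    mode: str = "recalculated",
) -> list[tuple[int, CaliperResult]]:
    """One caliper test per calendar year; years with N = 0 are omitted."""
    p = np.asarray(list(p_values), dtype=float)
    yr = np.asarray(list(years), dtype=int)
    if p.shape != yr.shape:
        raise ValueError("p_values and years must have equal length")
    out = []
    for year in np.unique(yr):
        res = caliper_test(p[yr == year], binwidth=binwidth, upper=upper, mode=mode)
        if res.N > 0:
            out.append((int(year), res))
    return out


def bump_trend(
    yearly: Sequence[tuple[int, float]], center_year: int | None = None
) -> TrendFit:
    """Fit a linear time trend to yearly caliper proportions.

    ``yearly`` is a sequence of (year, Pr) pairs; .5 is subtracted from Pr
    and years are centred at ``center_year`` (default: the earliest year),
    so the intercept measures the bump at the start of the period.
    Requires at least three yearly points.
    """
    pts = [(int(y), float(pr)) for y, pr in yearly if pr is not None and np.isfinite(pr)]
    if len(pts) < 3:
        raise ValueError("insufficient years: trend requires >= 3 yearly proportions")
    years = np.array([y for y, _ in pts], dtype=float)
    prs = np.array([pr for _, pr in pts], dtype=float)
    if center_year is None:
        center_year = int(years.min())
    X = sm.add_constant(years - center_year)
    fit = sm.OLS(prs - 0.5, X).fit()
    return TrendFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        intercept_se=float(fit.bse[0]),
        slope_se=float(fit.bse[1]),
        intercept_t=float(fit.tvalues[0]),
        slope_t=float(fit.tvalues[1]),
        intercept_p=float(fit.pvalues[0]),
        slope_p=float(fit.pvalues[1]),
        n_years=len(pts),
        center_year=center_year,
        timespan=(int(years.min()), int(years.max())),
    )
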