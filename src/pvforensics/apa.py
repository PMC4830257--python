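"""Parsing and auditing of APA-style reported test results.

APA style reports a test statistic with its degrees of freedom in
parentheses, followed by the p-value, e.g. ``t(85) = 2.86, p = .005``.
Because both the statistic and the p-value are reported, the p-value can be
recalculated from the statistic and checked against the reported one.  A
mismatch that flips statistical significance at the .05 level (a *gross
inconsistency*) is direct evidence of misreporting, such as the
questionable research practice of rounding p-values down to .05.

This module provides the record type :class:`TestResult`, a text parser for
the APA grammar, p-value recalculation for the five supported test families
(t, F, r, chi-square, Z), consistency classification, removal of impossible
results (e.g. ``F(0, 55)`` or ``|r| > 1``), and the standard subset
selections used throughout the analyses.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestFamily",
    "Operator",
    "TestResult",
    "ConsistencyVerdict",
    "IncomputableError",
    "ImpossibleResultError",
    "parse_apa_result",
    "format_apa_result",
    "recalculate_p",
    "consistency_check",
    "filter_impossible",
    "select_subset",
    "results_to_frame",
    "frame_to_results",
    "read_results_csv",
    "write_results_csv",
    "SUBSETS",
]

logger = logging.getLogger(__name__)


class TestFamily(str, Enum):
    t = "t"
    F = "F"
    r = "r"
    chi2 = "chi2"
    Z = "Z"


class Operator(str, Enum):
    eq = "eq"
    lt = "lt"
    gt = "gt"
    ns = "ns"  # p reported only as "not significant"


class IncomputableError(ValueError):
    """The p-value cannot be recalculated (e.g. missing degrees of freedom)."""


class ImpossibleResultError(ValueError):
    """The reported result is mathematically impossible (e.g. |r| >= 1)."""


@dataclass(frozen=True)
class TestResult:
    """One reported statistical test result.

    ``df1``/``df2`` follow the APA layout: F reports ``F(df1, df2)``, t and
    r report a single df stored in ``df2``, chi-square stores its df in
    ``df1`` (optionally with a sample size ``N``), and Z has no df.
    ``p_decimals`` is the number of decimals in the reported p string,
    which determines the rounding window of the consistency check.
    """

    test_family: TestFamily
    statistic: float
    df1: int | None = None
    df2: int | None = None
    sample_n: int | None = None
    stat_operator: Operator = Operator.eq
    reported_p: float | None = None
    p_operator: Operator = Operator.eq
    p_decimals: int | None = None
    journal: str = ""
    year: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.reported_p is not None and not 0 <= self.reported_p <= 1:
            raise ValueError(f"reported_p outside [0, 1]: {self.reported_p}")
        if self.reported_p is not None and self.p_operator != Operator.ns:
            if self.p_decimals is not None and self.p_decimals < 1:
                raise ValueError("p_decimals must be >= 1 for a reported p")


@dataclass(frozen=True)
class ConsistencyVerdict:
    recalculated_p: float
    consistent: bool
    gross_inconsistency: bool
    rounding_window_used: tuple[float, float]


# --- APA grammar -----------------------------------------------------------

_NUM = r"[-−]?\s*(?:\d+\.?\d*|\.\d+)"
_OP = r"[=<>]"
_CHI = r"(?:χ|Χ|chi|X)\s*(?:2|²)"
_P_TAIL = (
    rf",\s*(?:p\s*(?P<pop>{_OP})\s*(?P<pval>{_NUM})|(?P<ns>ns)\b)"
)

_PATTERNS = [
    (
        TestFamily.t,
        re.compile(
            rf"\bt\s*\(\s*(?P<df2>{_NUM})\s*\)\s*(?P<sop>{_OP})\s*(?P<stat>{_NUM}){_P_TAIL}",
        ),
    ),
    (
        TestFamily.F,
        re.compile(
            rf"\bF\s*\(\s*(?P<df1>{_NUM})\s*,\s*(?P<df2>{_NUM})\s*\)\s*"
            rf"(?P<sop>{_OP})\s*(?P<stat>{_NUM}){_P_TAIL}",
        ),
    ),
    (
        TestFamily.r,
        re.compile(
            rf"\br\s*\(\s*(?P<df2>{_NUM})\s*\)\s*(?P<sop>{_OP})\s*(?P<stat>{_NUM}){_P_TAIL}",
        ),
    ),
    (
        TestFamily.chi2,
        re.compile(
            rf"{_CHI}\s*\(\s*(?P<df1>{_NUM})\s*(?:,\s*N\s*=\s*(?P<n>{_NUM})\s*)?\)\s*"
            rf"(?P<sop>{_OP})\s*(?P<stat>{_NUM}){_P_TAIL}",
        ),
    ),
    (
        TestFamily.Z,
        re.compile(rf"\bZ\s*(?P<sop>{_OP})\s*(?P<stat>{_NUM}){_P_TAIL}"),
    ),
]

_OP_MAP = {"=": Operator.eq, "<": Operator.lt, ">": Operator.gt}


def _to_float(s: str) -> float:
    return float(s.replace("−", "-").replace(" ", ""))


def _p_decimals(s: str) -> int:
    s = s.strip()
    if "." not in s:
        return 0
    return len(s.split(".", 1)[1])


def parse_apa_result(
    text: str,
    journal: str = "",
    year: int | None = None,
    source_id: str = "",
) -> list[TestResult]:
    """Extract every APA-style test result from free-form text.

    Non-matching text yields nothing; a match with malformed numerics is
    skipped with a logged warning.  Results are returned in order of
    appearance.
    """
    found: list[tuple[int, TestResult]] = []
    claimed: list[tuple[int, int]] = []
    for family, pattern in _PATTERNS:
        for m in pattern.finditer(text):
            span = m.span()
            # Z's pattern is a suffix of none, but guard against overlap
            # between families sharing text (e.g. "F(" inside a chi2 hit).
            if any(s < span[1] and span[0] < e for s, e in claimed):
                continue
            try:
                result = _match_to_result(family, m, journal, year, source_id)
            except (ValueError, OverflowError) as exc:
                logger.warning("skipping malformed APA match %r: %s", m.group(0), exc)
                continue
            claimed.append(span)
            found.append((span[0], result))
    found.sort(key=lambda pair: pair[0])
    return [result for _, result in found]


def _match_to_result(
    family: TestFamily,
    m: re.Match,
    journal: str,
    year: int | None,
    source_id: str,
) -> TestResult:
    groups = m.groupdict()
    df1 = df2 = sample_n = None
    if groups.get("df1") is not None:
        df1 = int(_to_float(groups["df1"]))
    if groups.get("df2") is not None:
        df2 = int(_to_float(groups["df2"]))
    if groups.get("n") is not None:
        sample_n = int(_to_float(groups["n"]))
    if groups.get("ns") is not None:
        p_op, p_val, p_dec = Operator.ns, None, None
    else:
        p_op = _OP_MAP[groups["pop"]]
        p_val = _to_float(groups["pval"])
        p_dec = _p_decimals(groups["pval"])
    return TestResult(
        test_family=family,
        statistic=_to_float(groups["stat"]),
        df1=df1,
        df2=df2,
        sample_n=sample_n,
        stat_operator=_OP_MAP[groups["sop"]],
        reported_p=p_val,
        p_operator=p_op,
        p_decimals=p_dec,
        journal=journal,
        year=year,
        source_id=source_id,
    )


_OP_SYM = {Operator.eq: "=", Operator.lt: "<", Operator.gt: ">"}


def format_apa_result(result: TestResult, stat_decimals: int = 2) -> str:
    """Render a :class:`TestResult` back to its APA text form.

    The inverse of :func:`parse_apa_result` on the reported fields: the p
    string uses ``p_decimals`` decimals in APA leading-zero-free style and
    the statistic is printed with ``stat_decimals`` decimals.
    """
    fam = result.test_family
    stat = f"{result.statistic:.{stat_decimals}f}"
    if fam == TestFamily.t:
        head = f"t({result.df2})"
    elif fam == TestFamily.F:
        head = f"F({result.df1}, {result.df2})"
    elif fam == TestFamily.r:
        head = f"r({result.df2})"
    elif fam == TestFamily.chi2:
        if result.sample_n is not None:
            head = f"χ2({result.df1}, N = {result.sample_n})"
        else:
            head = f"χ2({result.df1})"
    else:
        head = "Z"
    body = f"{head} {_OP_SYM[result.stat_operator]} {stat}"
    if result.p_operator == Operator.ns:
        return f"{body}, ns"
    dec = result.p_decimals if result.p_decimals is not None else 3
    p_str = f"{result.reported_p:.{dec}f}"
    if p_str.startswith("0."):
        p_str = p_str[1:]
    return f"{body}, p {_OP_SYM[result.p_operator]} {p_str}"


# --- recalculation ---------------------------------------------------------


def recalculate_p(result: TestResult) -> float:
    """Recalculate the p-value implied by the reported statistic and df.

    Two-tailed for t, r (via the exact t equivalent) and Z; upper-tail for
    F and chi-square.  Raises :class:`IncomputableError` when required df
    are missing and :class:`ImpossibleResultError` for |r| >= 1.
    """
    fam = result.test_family
    stat = result.statistic
    if not math.isfinite(stat):
        raise IncomputableError("non-finite statistic")
    if fam == TestFamily.t:
        if result.df2 is None or result.df2 <= 0:
            raise IncomputableError("t-test requires df > 0")
        p = 2.0 * stats.t.sf(abs(stat), result.df2)
    elif fam == TestFamily.r:
        if result.df2 is None or result.df2 <= 0:
            raise IncomputableError("correlation requires df > 0")
        if abs(stat) >= 1:
            raise ImpossibleResultError(f"|r| >= 1: {stat}")
        t_equiv = stat * math.sqrt(result.df2) / math.sqrt(1.0 - stat * stat)
        p = 2.0 * stats.t.sf(abs(t_equiv), result.df2)
    elif fam == TestFamily.F:
        if result.df1 is None or result.df2 is None or result.df1 <= 0 or result.df2 <= 0:
            raise IncomputableError("F-test requires df1 > 0 and df2 > 0")
        p = float(stats.f.sf(stat, result.df1, result.df2))
    elif fam == TestFamily.chi2:
        if result.df1 is None or result.df1 <= 0:
            raise IncomputableError("chi-square requires df > 0")
        p = float(stats.chi2.sf(stat, result.df1))
    else:  # Z
        p = 2.0 * stats.norm.sf(abs(stat))
    return float(min(p, 1.0))


# --- consistency -----------------------------------------------------------

ALPHA = 0.05
WIDE_05_WINDOW = (0.045, 0.055)


def consistency_check(
    result: TestResult, window_policy: str = "half_decimal"
) -> ConsistencyVerdict:
    """Classify agreement between the reported and recalculated p-value.

    ``half_decimal`` allows rounding to the reported precision: a p reported
    as ``= v`` with k decimals is consistent when the recalculated value
    lies in ``[v - 5*10^-(k+1), v + 5*10^-(k+1))``.  ``wide_05`` applies the
    widened window [.045, .055] to p-values reported as exactly .05, giving
    the benefit of the doubt to two-decimal rounding around the threshold.

    A *gross inconsistency* is a flip of significance at .05 between the
    reported claim and the recalculated value; it always overrides the
    rounding window, so ``gross_inconsistency`` implies ``not consistent``.
    """
    if window_policy not in ("half_decimal", "wide_05"):
        raise ValueError(f"unknown window policy: {window_policy}")
    if result.reported_p is None or result.p_operator == Operator.ns:
        raise IncomputableError("result has no numeric reported p")
    recalc = recalculate_p(result)
    reported = result.reported_p
    op = result.p_operator

    wide = (
        window_policy == "wide_05"
        and op == Operator.eq
        and math.isclose(reported, ALPHA, abs_tol=1e-12)
    )
    if op == Operator.eq:
        if wide:
            window = WIDE_05_WINDOW
            in_window = window[0] <= recalc <= window[1]
        else:
            k = result.p_decimals if result.p_decimals is not None else 2
            half = 5.0 * 10.0 ** (-(k + 1))
            window = (reported - half, reported + half)
            in_window = window[0] <= recalc < window[1]
        reported_sig = reported <= ALPHA
    elif op == Operator.lt:
        window = (0.0, reported)
        in_window = recalc < reported
        reported_sig = reported <= ALPHA
    else:  # gt
        window = (reported, 1.0)
        in_window = recalc > reported
        reported_sig = False if reported >= ALPHA else recalc <= ALPHA

    recalc_sig = recalc <= ALPHA
    gross = reported_sig != recalc_sig
    if wide and WIDE_05_WINDOW[0] <= recalc <= WIDE_05_WINDOW[1]:
        gross = False
    return ConsistencyVerdict(
        recalculated_p=recalc,
        consistent=in_window and not gross,
        gross_inconsistency=gross,
        rounding_window_used=window,
    )


# --- impossible results ----------------------------------------------------


def _is_impossible(result: TestResult) -> bool:
    fam = result.test_family
    if fam == TestFamily.F:
        return result.df1 is None or result.df2 is None or result.df1 <= 0 or result.df2 <= 0
    if fam in (TestFamily.t, TestFamily.r):
        if result.df2 is None or result.df2 <= 0:
            return True
        return fam == TestFamily.r and abs(result.statistic) > 1
    if fam == TestFamily.chi2:
        return result.df1 is None or result.df1 <= 0
    return False


def filter_impossible(
    results: Iterable[TestResult],
) -> tuple[list[TestResult], list[TestResult]]:
    """Split results into (kept, removed), preserving order.

    Removed are exactly the mathematically impossible records: F or
    chi-square with a zero/missing df, t/r with a non-positive df, and
    correlations |r| > 1.
    """
    kept: list[TestResult] = []
    removed: list[TestResult] = []
    for result in results:
        (removed if _is_impossible(result) else kept).append(result)
    return kept, removed


# --- subsets ---------------------------------------------------------------

SUBSETS = (
    "all_reported",
    "exact_p",
    "reported_eq_05",
    "recalc_exact_stat",
    "recalc_exact_both",
    "model_fit_pool",
)


def select_subset(results: Sequence[TestResult], subset: str) -> list[TestResult]:
    """Select one of the standard analysis subsets.

    ``all_reported``
        every record with a numeric reported p (exact or inexact);
    ``exact_p``
        p reported as an exact value (``p = v``);
    ``reported_eq_05``
        exactly reported statistics with p reported exactly as .05;
    ``recalc_exact_stat``
        every exactly reported test statistic (recalculable records);
    ``recalc_exact_both``
        exactly reported statistic and exactly reported p;
    ``model_fit_pool``
        t, r and F(df1 = 1) records with exactly reported statistics whose
        recalculated p is at most .05 — the pool used for effect-size
        distribution modelling.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; choose from {SUBSETS}")
    exact_stat = lambda res: res.stat_operator == Operator.eq  # noqa: E731
    if subset == "all_reported":
        return [r for r in results if r.reported_p is not None and r.p_operator != Operator.ns]
    if subset == "exact_p":
        return [r for r in results if r.p_operator == Operator.eq]
    if subset == "reported_eq_05":
        return [
            r
            for r in results
            if exact_stat(r)
            and r.p_operator == Operator.eq
            and r.reported_p is not None
            and math.isclose(r.reported_p, 0.05, abs_tol=1e-12)
        ]
    if subset == "recalc_exact_stat":
        return [r for r in results if exact_stat(r)]
    if subset == "recalc_exact_both":
        return [r for r in results if exact_stat(r) and r.p_operator == Operator.eq]
    # model_fit_pool
    pool: list[TestResult] = []
    for r in results:
        if not exact_stat(r):
            continue
        if r.test_family in (TestFamily.t, TestFamily.r) or (
            r.test_family == TestFamily.F and r.df1 == 1
        ):
            try:
                if recalculate_p(r) <= ALPHA:
                    pool.append(r)
            except (IncomputableError, ImpossibleResultError):
                continue
    return pool


# --- CSV I/O ---------------------------------------------------------------

CSV_COLUMNS = [
    "source_id",
    "journal",
    "year",
    "test_family",
    "df1",
    "df2",
    "sample_n",
    "stat_operator",
    "statistic",
    "p_operator",
    "reported_p",
    "p_decimals",
]


def results_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "source_id": r.source_id,
                "journal": r.journal,
                "year": r.year,
                "test_family": r.test_family.value,
                "df1": r.df1,
                "df2": r.df2,
                "sample_n": r.sample_n,
                "stat_operator": r.stat_operator.value,
                "statistic": r.statistic,
                "p_operator": r.p_operator.value,
                "reported_p": r.reported_p,
                "p_decimals": r.p_decimals,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_results(frame: pd.DataFrame) -> list[TestResult]:
    def _opt_int(v):
        return None if pd.isna(v) else int(v)

    def _opt_float(v):
        return None if pd.isna(v) else float(v)

    results = []
    for row in frame.itertuples(index=False):
        results.append(
            TestResult(
                test_family=TestFamily(row.test_family),
                statistic=float(row.statistic),
                df1=_opt_int(row.df1),
                df2=_opt_int(row.df2),
                sample_n=_opt_int(row.sample_n),
                stat_operator=Operator(row.stat_operator),
                reported_p=_opt_float(row.reported_p),
                p_operator=Operator(row.p_operator),
                p_decimals=_opt_int(row.p_decimals),
                journal="" if pd.isna(row.journal) else str(row.journal),
                year=_opt_int(row.year),
                source_id="" if pd.isna(row.source_id) else str(row.source_id),
            )
        )
    return results


def write_results_csv(results: Iterable[TestResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False, encoding="utf-8")


def read_results_csv(path) -> list[TestResult]:
    return frame_to_results(pd.read_csv(path, encoding="utf-8"))
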