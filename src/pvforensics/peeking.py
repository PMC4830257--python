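"""Optional-stopping ("data peeking") simulator for two-sample t-tests.

Each simulated study compares two groups of standard-normal observations
whose mean difference d is drawn once per study from Normal(delta, tau) on
Cohen's d scale.  The study tests after ``n_per_group`` observations per
group; if the result is not significant, a round of additional sampling
adds ``add_fraction`` of the original per-group sample size to *both*
groups and the accumulated data are re-tested, up to ``max_rounds`` rounds.
The final p-value is the first significant one, or the last look's p-value
if no look reached significance.

Tests are pooled-variance Student t-tests.  By default the test is
one-sided in the hypothesized (positive) direction, ``alternative =
"greater"``; a two-sided option is available.  Under the null either
choice yields uniformly distributed p-values.

A "condition" mirrors the study-collection rule of the simulation design:
studies are generated until ``n_keep`` of them have a final p-value below
``keep_threshold`` (default .1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

__all__ = [
    "PeekingDesign",
    "StudyOutcome",
    "StudyOutcomes",
    "ConditionResult",
    "simulate_study",
    "simulate_studies",
    "simulate_condition",
    "pvalue_histogram",
]


@dataclass(frozen=True)
class PeekingDesign:
    """Configuration of one optional-stopping study design.

    ``delta`` and ``tau`` are the mean and SD of the true effect across
    studies on Cohen's d scale.  ``add_fraction`` of the original per-group
    sample size (rounded) is added per group in each peeking round.
    """

    n_per_group: int = 24
    add_fraction: float = 1.0 / 3.0
    max_rounds: int = 3
    alpha: float = 0.05
    delta: float = 0.0
    tau: float = 0.0
    keep_threshold: float = 0.1
    alternative: str = "greater"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.add_fraction <= 0:
            raise ValueError("add_fraction must be positive")
        if self.max_rounds < 0:
            raise ValueError("max_rounds must be >= 0")
        if self.alternative not in ("greater", "two-sided"):
            raise ValueError("alternative must be 'greater' or 'two-sided'")

    @property
    def added_per_round(self) -> int:
        """Observations added per group in each peeking round."""
        return int(round(self.add_fraction * self.n_per_group))

    @property
    def look_sizes(self) -> tuple[int, ...]:
        """Per-group sample size at each look (first look included)."""
        return tuple(
            self.n_per_group + r * self.added_per_round for r in range(self.max_rounds + 1)
        )


@dataclass(frozen=True)
class StudyOutcome:
    p_final: float
    t_final: float
    n_final_per_group: int
    rounds_used: int
    d_drawn: float
    alpha: float

    @property
    def peeked(self) -> bool:
        return self.rounds_used > 0

    @property
    def significant_via_peek(self) -> bool:
        return self.peeked and self.p_final <= self.alpha

    @property
    def df(self) -> int:
        return 2 * self.n_final_per_group - 2


@dataclass
class StudyOutcomes:
    """Column-wise container for many simulated studies."""

    p_final: np.ndarray
    t_final: np.ndarray
    n_final_per_group: np.ndarray
    rounds_used: np.ndarray
    d_drawn: np.ndarray
    alpha: float

    def __len__(self) -> int:
        return self.p_final.size

    @property
    def peeked(self) -> np.ndarray:
        return self.rounds_used > 0

    @property
    def significant_via_peek(self) -> np.ndarray:
        return self.peeked & (self.p_final <= self.alpha)

    @property
    def df(self) -> np.ndarray:
        return 2 * self.n_final_per_group - 2

    def __getitem__(self, index) -> "StudyOutcomes":
        return StudyOutcomes(
            self.p_final[index],
            self.t_final[index],
            self.n_final_per_group[index],
            self.rounds_used[index],
            self.d_drawn[index],
            self.alpha,
        )

    def __iter__(self) -> Iterator[StudyOutcome]:
        for i in range(len(self)):
            yield StudyOutcome(
                float(self.p_final[i]),
                float(self.t_final[i]),
                int(self.n_final_per_group[i]),
                int(self.rounds_used[i]),
                float(self.d_drawn[i]),
                self.alpha,
            )

    @staticmethod
    def concatenate(chunks: list["StudyOutcomes"]) -> "StudyOutcomes":
        return StudyOutcomes(
            np.concatenate([c.p_final for c in chunks]),
            np.concatenate([c.t_final for c in chunks]),
            np.concatenate([c.n_final_per_group for c in chunks]),
            np.concatenate([c.rounds_used for c in chunks]),
            np.concatenate([c.d_drawn for c in chunks]),
            chunks[0].alpha,
        )


@dataclass(frozen=True)
class ConditionResult:
    kept: StudyOutcomes
    n_attempted: int
    all_outcomes: StudyOutcomes | None = None


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic and its df for raw data."""
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), df


def _p_from_t(t, df, alternative: str):
    if alternative == "greater":
        return stats.t.sf(t, df)
    return 2.0 * stats.t.sf(np.abs(t), df)


def _looks_from_observations(
    obs1: np.ndarray, obs2: np.ndarray, look_sizes: tuple[int, ...], alternative: str
) -> tuple[np.ndarray, np.ndarray]:
    """t and p at each look from accumulated observations.

    ``obs1``/``obs2`` have shape (n_studies, n_max); look k uses the first
    ``look_sizes[k]`` columns, so later looks include all earlier data.
    Implemented with cumulative sufficient statistics, which agree exactly
    with recomputation from the raw slices.
    """
    s1, q1 = obs1.cumsum(axis=1), np.square(obs1).cumsum(axis=1)
    s2, q2 = obs2.cumsum(axis=1), np.square(obs2).cumsum(axis=1)
    t_looks, p_looks = [], []
    for n in look_sizes:
        m1, m2 = s1[:, n - 1] / n, s2[:, n - 1] / n
        ss1 = q1[:, n - 1] - s1[:, n - 1] ** 2 / n
        ss2 = q2[:, n - 1] - s2[:, n - 1] ** 2 / n
        df = 2 * n - 2
        sp2 = (ss1 + ss2) / df
        t = (m1 - m2) / np.sqrt(sp2 * 2.0 / n)
        t_looks.append(t)
        p_looks.append(_p_from_t(t, df, alternative))
    return np.stack(t_looks, axis=1), np.stack(p_looks, axis=1)


def simulate_studies(
    design: PeekingDesign,
    n_studies: int,
    rng: np.random.Generator,
    peeking: bool = True,
    d_values: np.ndarray | None = None,
) -> StudyOutcomes:
    """Simulate ``n_studies`` studies, vectorized.

    With ``peeking=False`` only the first look is performed (fixed-n
    studies).  Later looks reuse all earlier observations, exactly as if
    raw data were accumulated.  ``d_values`` optionally fixes each study's
    true effect instead of drawing from Normal(delta, tau).
    """
    look_sizes = design.look_sizes if peeking else design.look_sizes[:1]
    n_max = look_sizes[-1]
    if d_values is not None:
        d = np.asarray(d_values, dtype=float)
        if d.shape != (n_studies,):
            raise ValueError("d_values must have length n_studies")
    elif design.tau > 0:
        d = rng.normal(design.delta, design.tau, size=n_studies)
    else:
        d = np.full(n_studies, float(design.delta))
    obs1 = rng.standard_normal((n_studies, n_max)) + d[:, None]
    obs2 = rng.standard_normal((n_studies, n_max))
    t_looks, p_looks = _looks_from_observations(obs1, obs2, look_sizes, design.alternative)

    p_final = np.empty(n_studies)
    t_final = np.empty(n_studies)
    n_final = np.empty(n_studies, dtype=np.int64)
    rounds = np.empty(n_studies, dtype=np.int64)
    active = np.ones(n_studies, dtype=bool)
    last = len(look_sizes) - 1
    for k, n in enumerate(look_sizes):
        stop = active & ((p_looks[:, k] <= design.alpha) | (k == last))
        p_final[stop] = p_looks[stop, k]
        t_final[stop] = t_looks[stop, k]
        n_final[stop] = n
        rounds[stop] = k
        active &= ~stop
    return StudyOutcomes(p_final, t_final, n_final, rounds, d, design.alpha)


def simulate_study(design: PeekingDesign, rng: np.random.Generator) -> StudyOutcome:
    """Simulate a single study by explicit raw-data accumulation.

    Reference implementation of the optional-stopping procedure; the
    vectorized :func:`simulate_studies` agrees with it exactly for equal
    observations.
    """
    d = float(rng.normal(design.delta, design.tau)) if design.tau > 0 else design.delta
    n_max = design.look_sizes[-1]
    x = rng.standard_normal(n_max) + d
    y = rng.standard_normal(n_max)
    for k, n in enumerate(design.look_sizes):
        t, df = pooled_t(x[:n], y[:n])
        p = float(_p_from_t(t, df, design.alternative))
        if p <= design.alpha or k == design.max_rounds:
            return StudyOutcome(p, t, n, k, d, design.alpha)
    raise AssertionError("unreachable")


def simulate_condition(
    design: PeekingDesign,
    n_keep: int,
    peeking: bool = True,
    rng: np.random.Generator | None = None,
    return_all: bool = False,
    batch_size: int = 100_000,
) -> ConditionResult:
    """Run studies until ``n_keep`` have final p below ``keep_threshold``.

    Returns the kept outcomes (exactly ``n_keep`` of them), the total
    number of studies attempted and, with ``return_all``, every attempted
    study up to and including the one that completed the quota.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    chunks: list[StudyOutcomes] = []
    n_kept = 0
    while n_kept < n_keep:
        chunk = simulate_studies(design, batch_size, rng, peeking=peeking)
        chunks.append(chunk)
        n_kept += int((chunk.p_final < design.keep_threshold).sum())
    everything = StudyOutcomes.concatenate(chunks)
    keep_mask = everything.p_final < design.keep_threshold
    cutoff = int(np.searchsorted(np.cumsum(keep_mask), n_keep)) + 1
    everything = everything[:cutoff]
    kept = everything[everything.p_final < design.keep_threshold]
    return ConditionResult(
        kept=kept,
        n_attempted=cutoff,
        all_outcomes=everything if return_all else None,
    )


def pvalue_histogram(
    p_values: np.ndarray,
    binwidth: float,
    p_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of p-values with half-open bins of width ``binwidth``.

    Returns (edges, counts).  ``binwidth`` must divide the range length to
    within rounding; the final bin includes the right endpoint, so the
    counts sum to the number of in-range values.
    """
    lo, hi = p_range
    n_bins = (hi - lo) / binwidth
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("binwidth must divide the range length")
    edges = np.linspace(lo, hi, int(round(n_bins)) + 1)
    counts, _ = np.histogram(np.asarray(p_values, dtype=float), bins=edges)
    return edges, counts
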