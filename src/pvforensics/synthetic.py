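"""Synthetic literature generator with configurable questionable practices.

Generates a corpus of APA-style test results whose statistical structure
mimics an extracted journal corpus: a mixture of test families, exact and
inexact p-value reporting (roughly 3:1 inexact in real corpora), two- vs
three-decimal p-values depending on publication year, and two injected
questionable research practices —

* *data peeking* at the study level (two-sided optional stopping for
  two-sample designs), and
* *incorrect rounding* at the reporting level: a result whose recalculable
  p lies in (.05, .055] is reported as ``p = .05`` or ``p < .05``.

Every record carries ground-truth side annotations (true effect, whether
it was peeked, whether rounding was applied) in a separate table that the
analysis modules never read, enabling exact sensitivity evaluation of the
detectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .apa import (
    Operator,
    TestFamily,
    TestResult,
    format_apa_result,
    parse_apa_result,
)
from .peeking import PeekingDesign, simulate_studies

__all__ = ["CorpusConfig", "SyntheticCorpus", "generate_corpus", "corpus_to_apa_text", "corpus_roundtrip"]

#: per-group sample sizes available to two-sample designs
_GROUP_SIZES = np.array([10, 15, 20, 25, 30, 40, 50, 75])
_GROUP_SIZE_W = np.array([0.10, 0.17, 0.20, 0.18, 0.14, 0.10, 0.07, 0.04])

#: QRP rounding window: recalculable p here may be misreported as <= .05
_ROUNDING_WINDOW = (0.05, 0.055)


@dataclass(frozen=True)
class CorpusConfig:
    """Composition and questionable-practice rates of a synthetic corpus.

    ``effect_mixture`` lists (weight, delta_d, tau_d) components on
    Cohen's d scale: by default a mix of null effects, modest focal
    effects and large manipulation-check-like effects.
    ``inexact_report_rate`` defaults to the roughly 73% share of
    inexactly reported p-values seen in large extracted corpora.
    """

    n_articles: int = 200
    journals: tuple[tuple[str, int, int], ...] = (
        ("J_DEV", 1985, 2013),
        ("J_APP", 1985, 2013),
        ("J_SOC", 1985, 2013),
        ("J_GEN", 2000, 2013),
    )
    results_per_article_mean: float = 8.0
    effect_mixture: tuple[tuple[float, float, float], ...] = (
        (0.35, 0.0, 0.0),
        (0.45, 0.4, 0.15),
        (0.20, 0.9, 0.2),
    )
    test_family_weights: tuple[tuple[str, float], ...] = (
        ("t", 0.45),
        ("F", 0.30),
        ("r", 0.15),
        ("chi2", 0.07),
        ("Z", 0.03),
    )
    peeking_rate: float = 0.0
    incorrect_rounding_rate: float = 0.0
    inexact_report_rate: float = 0.73
    three_decimal_from_year: int = 2010
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.peeking_rate, self.incorrect_rounding_rate, self.inexact_report_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if abs(sum(w for w, _, _ in self.effect_mixture) - 1) > 1e-9:
            raise ValueError("effect mixture weights must sum to 1")
        if abs(sum(w for _, w in self.test_family_weights) - 1) > 1e-9:
            raise ValueError("test family weights must sum to 1")


@dataclass
class SyntheticCorpus:
    results: list[TestResult]
    truth: pd.DataFrame  # side table: true_d, peeked, rounding_qrp, true_p
    config: CorpusConfig


def _draw_effects(cfg: CorpusConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in cfg.effect_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    deltas = np.array([d for _, d, _ in cfg.effect_mixture])[comp]
    taus = np.array([t for _, _, t in cfg.effect_mixture])[comp]
    return rng.normal(deltas, taus)


def _two_sample_results(
    rng: np.random.Generator,
    d: np.ndarray,
    peek: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate t statistics and df for two-sample records; returns (t, df, n_final)."""
    n = len(d)
    n_group = rng.choice(_GROUP_SIZES, size=n, p=_GROUP_SIZE_W / _GROUP_SIZE_W.sum())
    t_out = np.empty(n)
    df_out = np.empty(n, dtype=np.int64)
    for group_n in np.unique(n_group):
        m = n_group == group_n
        design = PeekingDesign(
            n_per_group=int(group_n), alternative="two-sided", alpha=0.05
        )
        for is_peek in (False, True):
            mm = m & (peek == is_peek)
            if not mm.any():
                continue
            out = simulate_studies(
                design, int(mm.sum()), rng, peeking=is_peek, d_values=d[mm]
            )
            t_out[mm] = out.t_final
            df_out[mm] = out.df
    return t_out, df_out, None


def generate_corpus(config: CorpusConfig) -> SyntheticCorpus:
    """Generate a reproducible synthetic corpus of APA test results."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # article skeleton
    n_per_article = 1 + rng.poisson(max(cfg.results_per_article_mean - 1, 0), cfg.n_articles)
    journal_idx = rng.integers(0, len(cfg.journals), cfg.n_articles)
    years = np.array(
        [rng.integers(cfg.journals[j][1], cfg.journals[j][2] + 1) for j in journal_idx]
    )
    n_total = int(n_per_article.sum())
    art_of = np.repeat(np.arange(cfg.n_articles), n_per_article)

    fam_names = [f for f, _ in cfg.test_family_weights]
    fam_w = np.array([w for _, w in cfg.test_family_weights])
    fam = rng.choice(len(fam_names), size=n_total, p=fam_w)
    family = np.array([fam_names[i] for i in fam])

    d_true = _draw_effects(cfg, rng, n_total)
    peeked = rng.random(n_total) < cfg.peeking_rate

    stat = np.empty(n_total)
    df1 = np.full(n_total, -1, dtype=np.int64)
    df2 = np.full(n_total, -1, dtype=np.int64)
    sample_n = np.full(n_total, -1, dtype=np.int64)

    # two-sample designs: t and F(1, df); peeking applies here
    two_sample = np.isin(family, ("t", "F"))
    peeked &= two_sample
    if two_sample.any():
        t_stat, t_df, _ = _two_sample_results(rng, d_true[two_sample], peeked[two_sample])
        stat[two_sample] = t_stat
        df2[two_sample] = t_df
    is_f = family == "F"
    stat[is_f] = np.square(stat[is_f])
    df1[is_f] = 1

    # correlational r(df): Fisher-z sampling around the converted effect
    is_r = family == "r"
    if is_r.any():
        n_obs = rng.choice(_GROUP_SIZES * 2, size=int(is_r.sum()), p=_GROUP_SIZE_W / _GROUP_SIZE_W.sum())
        rho = d_true[is_r] / np.sqrt(np.square(d_true[is_r]) + 4.0)
        z_obs = rng.normal(np.arctanh(rho), 1.0 / np.sqrt(n_obs - 3.0))
        stat[is_r] = np.clip(np.tanh(z_obs), -0.99, 0.99)
        df2[is_r] = n_obs - 2

    # chi-square and Z fillers (no QRP machinery; excluded from model pools)
    is_c = family == "chi2"
    if is_c.any():
        k = int(is_c.sum())
        dfc = rng.integers(1, 5, k)
        ncp = np.square(d_true[is_c]) * 20.0
        stat[is_c] = stats.ncx2.rvs(dfc, np.maximum(ncp, 1e-9), random_state=rng)
        df1[is_c] = dfc
        with_n = rng.random(k) < 0.5
        ns = rng.integers(30, 200, k)
        sample_n[is_c] = np.where(with_n, ns, -1)
    is_z = family == "Z"
    if is_z.any():
        stat[is_z] = rng.normal(d_true[is_z] * math.sqrt(12.5), 1.0)

    # reporting layer: statistics rounded to 2 decimals, p recalculated
    # from the *rounded* statistic so reported p and statistic cohere
    stat = np.round(stat, 2)
    recalc = _recalc_vector(family, stat, df1, df2)

    in_window = (recalc > _ROUNDING_WINDOW[0]) & (recalc <= _ROUNDING_WINDOW[1])
    rounding_qrp = in_window & (rng.random(n_total) < cfg.incorrect_rounding_rate)
    inexact = rng.random(n_total) < cfg.inexact_report_rate

    results: list[TestResult] = []
    rows = []
    for i in range(n_total):
        year = int(years[art_of[i]])
        journal = cfg.journals[journal_idx[art_of[i]]][0]
        p_op, p_val, p_dec = _report_p(
            float(recalc[i]),
            bool(rounding_qrp[i]),
            bool(inexact[i]),
            year >= cfg.three_decimal_from_year,
            rng,
        )
        results.append(
            TestResult(
                test_family=TestFamily(family[i]),
                statistic=float(stat[i]),
                df1=int(df1[i]) if df1[i] >= 0 else None,
                df2=int(df2[i]) if df2[i] >= 0 else None,
                sample_n=int(sample_n[i]) if sample_n[i] >= 0 else None,
                stat_operator=Operator.eq,
                reported_p=p_val,
                p_operator=p_op,
                p_decimals=p_dec,
                journal=journal,
                year=year,
                source_id=f"a{art_of[i]:05d}",
            )
        )
        rows.append(
            {
                "true_d": float(d_true[i]),
                "peeked": bool(peeked[i]),
                "rounding_qrp": bool(rounding_qrp[i]),
                "recalculable_p": float(recalc[i]),
            }
        )
    return SyntheticCorpus(results=results, truth=pd.DataFrame(rows), config=cfg)


def _recalc_vector(family, stat, df1, df2) -> np.ndarray:
    p = np.ones(len(stat))
    m = family == "t"
    p[m] = 2 * stats.t.sf(np.abs(stat[m]), df2[m])
    m = family == "F"
    p[m] = stats.f.sf(stat[m], df1[m], df2[m])
    m = family == "r"
    with np.errstate(divide="ignore", invalid="ignore"):
        t_eq = stat[m] * np.sqrt(df2[m]) / np.sqrt(1 - np.square(stat[m]))
    p[m] = 2 * stats.t.sf(np.abs(t_eq), df2[m])
    m = family == "chi2"
    p[m] = stats.chi2.sf(stat[m], df1[m])
    m = family == "Z"
    p[m] = 2 * stats.norm.sf(np.abs(stat[m]))
    return np.minimum(p, 1.0)


def _report_p(
    p: float,
    rounding_qrp: bool,
    inexact: bool,
    three_decimals: bool,
    rng: np.random.Generator,
) -> tuple[Operator, float | None, int | None]:
    """Reporting rules for one record; returns (operator, value, decimals)."""
    if rounding_qrp:
        # the misreporting QRP: p in (.05, .055] presented as significant
        if rng.random() < 0.5:
            return Operator.eq, 0.05, 2
        return Operator.lt, 0.05, 2
    if inexact:
        if p <= 0.001:
            return Operator.lt, 0.001, 3
        if p <= 0.01:
            return Operator.lt, 0.01, 2
        if p <= 0.05:
            return Operator.lt, 0.05, 2
        if rng.random() < 0.3:
            return Operator.ns, None, None
        return Operator.gt, 0.05, 2
    dec = 3 if three_decimals else 2
    # honest exact reporting never rounds a non-significant p into .05:
    # values in the boundary window get a third decimal
    if dec == 2 and _ROUNDING_WINDOW[0] < p < _ROUNDING_WINDOW[1]:
        dec = 3
    if p < 0.5 * 10.0**-dec:
        return Operator.lt, 0.001, 3
    return Operator.eq, round(p, dec), dec


def corpus_to_apa_text(corpus: SyntheticCorpus) -> list[str]:
    """Render each record as one APA result line."""
    return [format_apa_result(res) for res in corpus.results]


def corpus_roundtrip(corpus: SyntheticCorpus) -> list[TestResult]:
    """Render to APA text and reparse; reproduces all reported fields.

    Provenance metadata (journal, year, source id) is reattached from the
    original records since plain APA strings do not carry it.
    """
    reparsed: list[TestResult] = []
    for orig, line in zip(corpus.results, corpus_to_apa_text(corpus)):
        hits = parse_apa_result(
            line, journal=orig.journal, year=orig.year, source_id=orig.source_id
        )
        if len(hits) != 1:
            raise ValueError(f"roundtrip failed for {line!r}: {len(hits)} matches")
        reparsed.append(hits[0])
    return reparsed
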