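"""End-to-end orchestration: corpus -> recalculation -> caliper/trend -> model fits.

A :class:`RunManifest` names the input (a results CSV or a synthetic-corpus
configuration), the analysis settings (caliper binwidths, fitting ranges,
the tiny-p cut), and an output directory.  :func:`run_pipeline` writes
CSV/JSON reports mirroring the journal-analysis tables: per-journal and
per-binwidth caliper counts (x, N, Pr, binomial p, one-tailed significance
flag), yearly trend fits (estimate, SE, t, two-tailed p), and effect-model
fits with the two excess measures.  Output is deterministic given the
manifest (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import apa
from .caliper import DEFAULT_BINWIDTHS, bump_trend, caliper_by_year, caliper_test
from .effect_model import DEFAULT_CUT, excess_measures, fit_effect_model, pool_from_results
from .synthetic import CorpusConfig, generate_corpus

__all__ = ["RunManifest", "run_pipeline"]


@dataclass(frozen=True)
class RunManifest:
    out_dir: str
    results_csv: str | None = None
    synth_config: CorpusConfig | None = None
    subset: str = "recalc_exact_stat"
    binwidths: tuple[float, ...] = DEFAULT_BINWIDTHS
    fit_ranges: tuple[tuple[float, float], ...] = ((0.0, 0.05), (0.0, DEFAULT_CUT))
    cut: float = DEFAULT_CUT
    center_year: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.results_csv is None) == (self.synth_config is None):
            raise ValueError("provide exactly one of results_csv or synth_config")
        if any(w <= 0 for w in self.binwidths):
            raise ValueError("binwidths must be positive")


def _caliper_row(journal: str, binwidth: float, res) -> dict:
    p = res.p_binomial
    return {
        "journal": journal,
        "binwidth": binwidth,
        "x": res.x,
        "N": res.N,
        "Pr": res.Pr,
        "p": p,
        "significant": bool(p is not None and p <= 0.05),
        "no_test": res.N == 0,
    }


def run_pipeline(manifest: RunManifest) -> dict:
    """Run the full analysis described by ``manifest``; returns the report.

    Writes ``caliper.csv``, ``trend.csv``, ``fits.json``, ``measures.json``
    and a copy of the manifest into ``out_dir``.
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if manifest.results_csv is not None:
        results = apa.read_results_csv(manifest.results_csv)
    else:
        results = generate_corpus(manifest.synth_config).results
    results, removed = apa.filter_impossible(results)
    subset = apa.select_subset(results, manifest.subset)

    recalc, years, journals = [], [], []
    for res in subset:
        try:
            recalc.append(apa.recalculate_p(res))
        except (apa.IncomputableError, apa.ImpossibleResultError):
            continue
        years.append(res.year)
        journals.append(res.journal)
    recalc = np.asarray(recalc)
    years = np.asarray([y if y is not None else -1 for y in years])
    journals = np.asarray(journals)

    # caliper tables, overall and per journal
    caliper_rows = []
    for binwidth in manifest.binwidths:
        caliper_rows.append(
            _caliper_row("ALL", binwidth, caliper_test(recalc, binwidth=binwidth))
        )
        for journal in sorted(set(journals)):
            res = caliper_test(recalc[journals == journal], binwidth=binwidth)
            caliper_rows.append(_caliper_row(journal, binwidth, res))
    caliper_frame = pd.DataFrame(caliper_rows)
    caliper_frame.to_csv(out / "caliper.csv", index=False)

    # yearly trend per binwidth (overall), skipped when < 3 usable years
    trend_rows = []
    for binwidth in manifest.binwidths:
        yearly = caliper_by_year(recalc, years, binwidth=binwidth)
        pts = [(y, r.Pr) for y, r in yearly]
        if len(pts) < 3:
            trend_rows.append({"binwidth": binwidth, "no_test": True})
            continue
        fit = bump_trend(pts, center_year=manifest.center_year)
        trend_rows.append(
            {
                "binwidth": binwidth,
                "no_test": False,
                "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
                "intercept_t": fit.intercept_t,
                "intercept_p": fit.intercept_p,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "slope_t": fit.slope_t,
                "slope_p": fit.slope_p,
                "center_year": fit.center_year,
                "timespan": f"{fit.timespan[0]}-{fit.timespan[1]}",
            }
        )
    pd.DataFrame(trend_rows).to_csv(out / "trend.csv", index=False)

    # effect-model fits and excess measures on the model pool
    pool = pool_from_results(apa.select_subset(results, "model_fit_pool"))
    fits = {}
    for fit_range in manifest.fit_ranges:
        tag = f"{fit_range[0]:g}-{fit_range[1]:g}"
        try:
            fit = fit_effect_model(pool, fit_range)
            fits[tag] = {
                "delta_hat": fit.model.delta,
                "tau_hat": fit.model.tau,
                "chi2": fit.chi2_misfit,
                "n": fit.n_records,
                "degenerate": fit.degenerate,
            }
        except ValueError as exc:
            fits[tag] = {"error": str(exc)}
    (out / "fits.json").write_text(json.dumps(fits, indent=2))

    try:
        meas = excess_measures(pool, cut=manifest.cut)
        measures = {
            "D": meas.D,
            "effect_drop": meas.effect_drop,
            "delta_all": meas.delta_all,
            "delta_small": meas.delta_small,
            "p_obs_below_cut": meas.p_obs_below_cut,
            "p_exp_below_cut": meas.p_exp_below_cut,
            "cut": meas.cut,
        }
    except ValueError as exc:
        measures = {"error": str(exc)}
    (out / "measures.json").write_text(json.dumps(measures, indent=2))

    manifest_dict = asdict(manifest)
    (out / "manifest.json").write_text(json.dumps(manifest_dict, indent=2, default=str))

    return {
        "n_results": len(results),
        "n_removed_impossible": len(removed),
        "n_subset": len(subset),
        "caliper": caliper_frame,
        "trend": trend_rows,
        "fits": fits,
        "measures": measures,
    }
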