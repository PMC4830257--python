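"""Effect-size distribution modelling of truncated significant p-values.

The model assumes the true effect size on the Fisher-z scale (the
atanh-transformed correlation, rho_F) is Normal(delta, tau) across
studies.  Each reported result is converted to an observed Fisher z with
sampling SD 1/sqrt(N-3), where the effective sample size is N = df + 2; the
observed z is then Normal(delta, sqrt(tau^2 + sd_z^2)).  A p-value interval
maps to a z interval through the inverse-normal transform, so the expected
distribution of p-values over any fitting range (all p-values, p <= .05,
or p <= .00125) has closed form.  Parameters are estimated by minimizing
the Pearson chi-square over 40 equal-width p-bins, with delta constrained
to be nonnegative (only positive observed effects are modelled).

Two excess measures quantify contamination of the just-significant region:

* the *effect-size drop* — the difference between delta estimated from
  very small p-values only (<= .00125) and from all significant p-values;
  practices inflating just-significant p-values lower the latter;
* the *D odds ratio* — observed versus model-expected odds of mass in the
  interval (.00125, .05] within the significant range, where the
  expectation comes from the fit to p <= .00125.  D > 1 signals an excess
  of just-significant p-values (a bump or monotonic excess).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .apa import ALPHA, IncomputableError, TestFamily, TestResult, recalculate_p
from .peeking import StudyOutcomes

__all__ = [
    "FisherZEffectModel",
    "PValuePool",
    "BinnedPValues",
    "FitResult",
    "ExcessMeasures",
    "d_to_fisher_z",
    "effective_normal_params",
    "pool_from_results",
    "pool_from_outcomes",
    "bin_pool",
    "expected_bin_proportions",
    "fit_effect_model",
    "excess_measures",
    "true_D_from_labels",
    "expected_significant_share",
]

#: cut point separating "tiny" p-values assumed uncontaminated by peeking
DEFAULT_CUT = 0.00125
DEFAULT_N_BINS = 40

# chi-square minimization grid (coarse pass before local refinement)
_DELTA_GRID = np.round(np.arange(0.0, 1.5 + 1e-9, 0.01), 10)
_TAU_GRID = np.round(np.arange(0.0, 0.6 + 1e-9, 0.005), 10)

#: chi-square margin within which grid solutions count as tied.  The
#: delta-tau surface has a near-flat ridge (a larger mean effect mimics a
#: larger spread); differences below the cost of the two fitted parameters
#: are statistically meaningless, so such near-ties are resolved toward
#: smaller tau (then smaller delta) to make the estimator deterministic.
_TIE_TOL = 2.0


@dataclass(frozen=True)
class FisherZEffectModel:
    """Normal effect-size distribution on the Fisher-z scale."""

    delta: float
    tau: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.tau < 0:
            raise ValueError("delta and tau must be nonnegative")


def d_to_fisher_z(d: float) -> float:
    """Fisher z of the point-biserial correlation equivalent of Cohen's d.

    For an equal-n two-group design r = d / sqrt(d^2 + 4); the returned
    value is atanh(r).  Odd function of d; e.g. d = .5 -> .247 and
    d = .8 -> .390 to three decimals.
    """
    d = float(d)
    return math.atanh(d / math.sqrt(d * d + 4.0))


def effective_normal_params(result: TestResult) -> tuple[float, float]:
    """Observed Fisher z and its sampling SD for a model-pool record.

    Supported families are t, r, and F with df1 = 1 (whose square root is
    a t statistic, taken positive).  The statistic is converted to
    r = t / sqrt(t^2 + df), then z = atanh(r); the effective sample size is
    N = df + 2 and sd_z = 1 / sqrt(N - 3).
    """
    fam = result.test_family
    if fam == TestFamily.t:
        if result.df2 is None or result.df2 <= 0:
            raise IncomputableError("t-test requires df > 0")
        df, t = result.df2, result.statistic
        r = t / math.sqrt(t * t + df)
    elif fam == TestFamily.r:
        if result.df2 is None or result.df2 <= 0:
            raise IncomputableError("correlation requires df > 0")
        df, r = result.df2, result.statistic
    elif fam == TestFamily.F and result.df1 == 1:
        if result.df2 is None or result.df2 <= 0:
            raise IncomputableError("F-test requires df2 > 0")
        df = result.df2
        t = math.sqrt(max(result.statistic, 0.0))
        r = t / math.sqrt(t * t + df)
    else:
        raise ValueError(f"unsupported family for effect model: {fam}")
    n_eff = df + 2
    if n_eff <= 3:
        raise IncomputableError("effective N <= 3")
    return math.atanh(r), 1.0 / math.sqrt(n_eff - 3.0)


@dataclass(frozen=True)
class PValuePool:
    """P-values with per-record sampling SDs on the Fisher-z scale.

    ``tails`` records the sidedness of the p-values (2 for recalculated
    APA results, 1 for one-sided simulation output) and fixes the p <-> z
    mapping used by all model computations.
    """

    p: np.ndarray
    sd_z: np.ndarray
    tails: int = 2

    def __post_init__(self) -> None:
        if self.p.shape != self.sd_z.shape:
            raise ValueError("p and sd_z must have equal length")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")

    def restrict(self, lo: float, hi: float) -> "PValuePool":
        m = (self.p > lo) & (self.p <= hi)
        return PValuePool(self.p[m], self.sd_z[m], self.tails)

    def __len__(self) -> int:
        return self.p.size


def pool_from_results(results: Iterable[TestResult]) -> PValuePool:
    """Build a two-tailed pool from APA records (model-fit families only).

    Negative observed effects (negative t or r statistics) are excluded;
    F(1, df) results are treated as positive-signed.
    """
    ps, sds = [], []
    for res in results:
        if res.test_family == TestFamily.F and res.df1 != 1:
            continue
        if res.test_family not in (TestFamily.t, TestFamily.r, TestFamily.F):
            continue
        if res.test_family in (TestFamily.t, TestFamily.r) and res.statistic < 0:
            continue
        try:
            _, sd = effective_normal_params(res)
            p = recalculate_p(res)
        except (IncomputableError, ValueError):
            continue
        ps.append(p)
        sds.append(sd)
    return PValuePool(np.asarray(ps), np.asarray(sds), tails=2)


def pool_from_outcomes(outcomes: StudyOutcomes, alternative: str = "greater") -> PValuePool:
    """Build a pool from simulated two-sample t-test studies.

    One-sided simulations keep every study (the negative direction appears
    as p > .5, which the one-sided mapping handles consistently);
    two-sided simulations keep positive-t studies only.
    """
    df = outcomes.df.astype(float)
    sd = 1.0 / np.sqrt(df - 1.0)  # N = df + 2, sd = 1/sqrt(N - 3)
    if alternative == "greater":
        return PValuePool(outcomes.p_final.copy(), sd, tails=1)
    m = outcomes.t_final > 0
    return PValuePool(outcomes.p_final[m], sd[m], tails=2)


def _z_of_p(q: np.ndarray, tails: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        if tails == 1:
            return special.ndtri(1.0 - q)
        return special.ndtri(1.0 - q / 2.0)


@dataclass(frozen=True)
class BinnedPValues:
    """Equal-width binning of a pool over a fitting range."""

    fit_range: tuple[float, float]
    edges: np.ndarray
    counts: np.ndarray
    sd_unique: np.ndarray
    sd_weights: np.ndarray
    tails: int
    n_records: int

    @property
    def n_bins(self) -> int:
        return self.counts.size


def bin_pool(
    pool: PValuePool,
    fit_range: tuple[float, float],
    n_bins: int = DEFAULT_N_BINS,
) -> BinnedPValues:
    """Bin in-range p-values into ``n_bins`` equal-width (lo, hi] bins."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = fit_range
    if not 0 <= lo < hi <= 1:
        raise ValueError("fit_range must satisfy 0 <= lo < hi <= 1")
    sub = pool.restrict(lo, hi)
    if len(sub) == 0:
        raise ValueError("no p-values in the fitting range")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, sub.p, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sd_unique, inverse = np.unique(sub.sd_z, return_inverse=True)
    weights = np.bincount(inverse).astype(float) / len(sub)
    return BinnedPValues(
        fit_range=(lo, hi),
        edges=edges,
        counts=counts,
        sd_unique=sd_unique,
        sd_weights=weights,
        tails=pool.tails,
        n_records=len(sub),
    )


def _bin_prop_grid(
    deltas: np.ndarray, taus: np.ndarray, bins: BinnedPValues
) -> np.ndarray:
    """Expected bin proportions, shape (len(deltas), len(taus), n_bins).

    Per-record bin probabilities are conditioned on the record lying in
    the fitting range (renormalized per record), then averaged with the
    pool's sd weights.
    """
    z_edges = _z_of_p(bins.edges, bins.tails)[None, :] * bins.sd_unique[:, None]
    sd_u = bins.sd_unique
    out = np.empty((deltas.size, taus.size, bins.n_bins))
    # chunk over deltas to bound memory for pools with many distinct df
    step = max(1, int(1e7 // max(1, taus.size * sd_u.size * z_edges.shape[1])))
    scale = np.sqrt(taus[None, :, None] ** 2 + sd_u[None, None, :] ** 2)[..., None]
    for start in range(0, deltas.size, step):
        dd = deltas[start : start + step, None, None, None]
        cdf = special.ndtr((z_edges[None, None, :, :] - dd) / scale)
        per_sd = cdf[..., :-1] - cdf[..., 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            per_sd = per_sd / per_sd.sum(axis=-1, keepdims=True)
        per_sd = np.nan_to_num(per_sd, nan=0.0)
        out[start : start + step] = np.einsum("u,dtub->dtb", bins.sd_weights, per_sd)
    return out


def expected_bin_proportions(
    model: FisherZEffectModel, bins: BinnedPValues
) -> np.ndarray:
    """Closed-form expected bin proportions; sums to 1 over the fit range."""
    props = _bin_prop_grid(np.array([model.delta]), np.array([model.tau]), bins)[0, 0]
    total = props.sum()
    if total <= 0:
        raise ValueError("model places no mass on the fitting range")
    return props / total


@dataclass(frozen=True)
class FitResult:
    model: FisherZEffectModel
    chi2_misfit: float
    expected_proportions: np.ndarray
    n_records: int
    fit_range: tuple[float, float]
    tails: int
    flagged_bins: tuple[int, ...] = ()
    degenerate: bool = False


def _chi2_grid(counts: np.ndarray, props: np.ndarray) -> np.ndarray:
    expected = counts.sum() * props
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.square(counts - expected) / np.maximum(expected, 1e-10)
    return chi2.sum(axis=-1)


def fit_effect_model(
    pool: PValuePool,
    fit_range: tuple[float, float] = (0.0, ALPHA),
    n_bins: int = DEFAULT_N_BINS,
) -> FitResult:
    """Estimate (delta, tau) by Pearson chi-square minimization.

    Deterministic: a coarse grid search (delta in [0, 1.5] step .01, tau in
    [0, .6] step .005) with near-ties — grid points within a fixed
    chi-square margin of the minimum — broken toward smaller tau and then
    smaller delta, followed by a bounded Nelder-Mead polish inside the
    chosen grid cell.  The tie rule pins down a unique solution on the
    delta-tau ridge, where a wide band of parameter pairs fits equally
    well within noise.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    bins = bin_pool(pool, fit_range, n_bins)
    degenerate = int((bins.counts > 0).sum()) <= 1

    grid = _chi2_grid(bins.counts, _bin_prop_grid(_DELTA_GRID, _TAU_GRID, bins))
    best = np.nanmin(grid)
    ties = np.argwhere(grid <= best + _TIE_TOL)
    i, j = min(ties.tolist(), key=lambda ij: (ij[1], ij[0]))
    x0 = np.array([_DELTA_GRID[i], _TAU_GRID[j]])

    def objective(x: np.ndarray) -> float:
        props = _bin_prop_grid(np.array([x[0]]), np.array([x[1]]), bins)[0, 0]
        return float(_chi2_grid(bins.counts, props[None, :])[0])

    bounds = [
        (max(x0[0] - 0.01, 0.0), min(x0[0] + 0.01, _DELTA_GRID[-1])),
        (max(x0[1] - 0.005, 0.0), min(x0[1] + 0.005, _TAU_GRID[-1])),
    ]
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 600},
    )
    delta_hat, tau_hat = max(res.x[0], 0.0), max(res.x[1], 0.0)
    chi2 = float(res.fun)
    model = FisherZEffectModel(delta_hat, tau_hat)
    props = expected_bin_proportions(model, bins)
    flagged = tuple(
        int(b)
        for b in np.nonzero((props * bins.n_records < 1e-8) & (bins.counts > 0))[0]
    )
    return FitResult(
        model=model,
        chi2_misfit=chi2,
        expected_proportions=props,
        n_records=bins.n_records,
        fit_range=bins.fit_range,
        tails=bins.tails,
        flagged_bins=flagged,
        degenerate=degenerate,
    )


def _tail_prob(
    model: FisherZEffectModel, sd: np.ndarray, q: float, tails: int
) -> np.ndarray:
    """P(p <= q) per record under the model (one tail of z)."""
    z_q = float(_z_of_p(np.array([q]), tails)[0])
    scale = np.sqrt(model.tau**2 + sd**2)
    return special.ndtr((model.delta - z_q * sd) / scale)


@dataclass(frozen=True)
class ExcessMeasures:
    delta_all: float
    delta_small: float
    effect_drop: float
    D: float
    p_obs_below_cut: float
    p_exp_below_cut: float
    cut: float
    sig_bound: float
    fit_small: FitResult
    fit_all: FitResult


def excess_measures(
    pool: PValuePool,
    cut: float = DEFAULT_CUT,
    sig_bound: float = ALPHA,
    n_bins: int = DEFAULT_N_BINS,
) -> ExcessMeasures:
    """Effect-size drop and D odds ratio for a significant pool.

    Fits the model separately to p <= ``cut`` and to p <= ``sig_bound``.
    ``p_obs_below_cut`` is the observed share of the significant pool below
    the cut; ``p_exp_below_cut`` averages each record's conditional
    probability P(p <= cut | p <= sig_bound) under the cut-based fit.  D is
    oriented so that D > 1 indicates excess mass in (cut, sig_bound]
    relative to the model expectation:

        D = [(1 - p_obs) / p_obs] * [p_exp / (1 - p_exp)].
    """
    if not 0 < cut < sig_bound:
        raise ValueError("need 0 < cut < sig_bound")
    sig = pool.restrict(0.0, sig_bound)
    n_below = int((sig.p <= cut).sum())
    if n_below == 0:
        raise ValueError("cut too small for pool: no observed p-values below cut")
    fit_small = fit_effect_model(pool, (0.0, cut), n_bins)
    fit_all = fit_effect_model(pool, (0.0, sig_bound), n_bins)

    p_obs = n_below / len(sig)
    num = _tail_prob(fit_small.model, sig.sd_z, cut, pool.tails)
    den = _tail_prob(fit_small.model, sig.sd_z, sig_bound, pool.tails)
    p_exp = float(np.mean(num / den))
    D = ((1.0 - p_obs) / p_obs) * (p_exp / (1.0 - p_exp))
    return ExcessMeasures(
        delta_all=fit_all.model.delta,
        delta_small=fit_small.model.delta,
        effect_drop=fit_small.model.delta - fit_all.model.delta,
        D=float(D),
        p_obs_below_cut=float(p_obs),
        p_exp_below_cut=p_exp,
        cut=cut,
        sig_bound=sig_bound,
        fit_small=fit_small,
        fit_all=fit_all,
    )


def true_D_from_labels(
    outcomes: StudyOutcomes,
    cut: float = DEFAULT_CUT,
    sig_bound: float = ALPHA,
) -> float:
    """Label-based excess factor for the interval (cut, sig_bound].

    With simulation ground truth, the factor by which optional stopping
    inflated the interval is N / (N - N_peeked), where N counts final
    p-values in the interval and N_peeked those obtained via peeking.
    """
    p = outcomes.p_final
    in_interval = (p > cut) & (p <= sig_bound)
    n_interval = int(in_interval.sum())
    n_peeked = int((in_interval & outcomes.significant_via_peek).sum())
    if n_interval - n_peeked <= 0:
        raise ValueError("no non-peeked p-values in the interval")
    return n_interval / (n_interval - n_peeked)


def expected_significant_share(
    model: FisherZEffectModel,
    sd_z: np.ndarray,
    alpha: float = ALPHA,
    tails: int = 2,
) -> float:
    """Average probability of a significant result under the model.

    For two-tailed records both tails count: P(|z| > z_{alpha/2} * sd).
    """
    sd = np.asarray(sd_z, dtype=float)
    scale = np.sqrt(model.tau**2 + sd**2)
    if tails == 1:
        z_a = float(special.ndtri(1.0 - alpha))
        share = special.ndtr((model.delta - z_a * sd) / scale)
    else:
        z_a = float(special.ndtri(1.0 - alpha / 2.0))
        upper = special.ndtr((model.delta - z_a * sd) / scale)
        lower = special.ndtr((-z_a * sd - model.delta) / scale)
        share = upper + lower
    return float(np.mean(share))
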