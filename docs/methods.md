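# Methods

This note documents the statistical models and procedures implemented in
`pvforensics`, the choices made where the design was genuinely open, and
the limits of what the synthetic experiments can show.

## Why p-value distributions

In the absence of questionable research practices (QRPs), the density of
p-values from a mixture of true and null effects is monotone
non-increasing: uniform under the null, right-skewed under a true effect.
Two kinds of distortion below the .05 threshold are of forensic interest:

* a **bump** — a local excess just below .05 that breaks monotonicity,
  produced by practices that push marginal results over the line
  (optional stopping, incorrect rounding, covariate hunting);
* **monotonic excess** — inflation below .05 that leaves the distribution
  monotone, which a local bump test cannot see.

The package implements one detector for each: the Caliper test (bump) and
an effect-size-distribution model with two excess measures (monotonic
excess), plus the infrastructure to audit reported results and to simulate
the main generating mechanism (data peeking).

## Reported-result auditing (`apa`)

APA-style results (`t(85) = 2.86, p = .005`) carry enough information to
recalculate the p-value from the statistic and degrees of freedom.
Recalculation conventions: two-tailed for t, r (via the exact
`t = r·sqrt(df)/sqrt(1-r²)` equivalence) and Z; upper tail for F and
chi-square. Whether reported one-tailed tests occur in a corpus cannot be
determined from the result string alone; the two-tailed convention is
applied uniformly, which matches standard recalculation practice.

A result is **consistent** when the recalculated p agrees with the
reported one up to reporting precision: half a unit in the last reported
decimal for `p = v` (policy `half_decimal`), or the widened window
[.045, .055] for p-values reported as exactly .05 (policy `wide_05`,
giving two-decimal rounding the benefit of the doubt). A **gross
inconsistency** is a flip of significance at .05 between the reported
claim and the recalculated value. Grossness overrides the window, so
`gross ⇒ not consistent` holds by construction; under `wide_05` a
reported `= .05` counts as gross only when the recalculated value leaves
[.045, .055]. A consequence worth noting: honest rounding to k decimals
can move a p-value across .05 only inside the wide window, so under
`wide_05` honest reporting never produces a gross flag — which is what
makes gross counts a clean detector of deliberate down-rounding.

Impossible results (`F(0, 55)`, `|r| > 1`, non-positive df) are removed
before any analysis.

## Caliper test (`caliper`)

For two adjacent intervals below the threshold, monotonicity implies that
the upper interval holds at most half of the combined count, so the test
is an exact one-tailed binomial test of H0: Pr ≤ .5 on x successes out of
N, with `P(X ≥ x | N, 1/2)`. The exact test is used at every N (the
worked example 40/60 gives p = .0284).

Interval conventions: internally all bins are half-open `[lo, hi)`, with
p exactly equal to the threshold excluded. For *recalculated* p-values
the intervals are adjacent: `[.05-2w, .05-w)` and `[.05-w, .05)`. For
*reported* p-values the lower interval is anchored one two-decimal
reporting step below the threshold and includes the gridpoint —
`(.04-w, .04]` versus `[.05-w, .05)` — because reported values cluster on
the two-decimal grid. The shared-endpoint bracket choice affects only
measure-zero events for continuous p-values.

The time trend is unweighted OLS of (Pr − .5) on calendar year centred at
the start of data collection, requiring at least three yearly points;
years with N = 0 are dropped. Intercept = bump at the centre year; slope =
change per year; two-tailed p-values.

## Optional-stopping simulator (`peeking`)

Each study draws a true effect d ~ Normal(delta, tau) on Cohen's d scale,
then samples two groups of standard-normal observations with mean offset
d, n_k = 24 per group by default. A pooled-variance Student t-test is
applied; if not significant at alpha = .05, each peeking round adds
round(n_k/3) = 8 observations *per group* (the symmetric reading of "one
third of the original sample size") and re-tests the accumulated data, up
to 3 rounds (n_k doubles by the final look). The final p-value is the
first significant one, else the last look's. A *condition* generates
studies until a quota (1,000,000 in the original design; 200k-500k here)
has final p < .1.

**Sidedness.** The simulator's default test is one-sided in the
hypothesized direction (`alternative="greater"`). This choice is pinned
down empirically: the published per-condition compositions for the
homogeneous (tau = 0) peeking conditions — significant share per kept
study of .7598/.8113/.9365/.9950 and sub-.00125 share of
.0097/.0216/.0956/.3505 across d = 0/.2/.5/.8 — are reproduced to
Monte-Carlo error by the one-sided design and are off by up to .08 under
the two-sided one. Under the null both choices give uniform p-values. A
two-sided option is provided and is used by the synthetic corpus (APA
corpora report two-tailed tests).

**Known discrepancy.** The published compositions of the *heterogeneous*
(tau_d = .15) peeking conditions are not reproducible from the described
procedure under any variant we constructed (sidedness, per-round effect
redraws, additions without effect, alternative keep rules, n read as
total). They are in fact structurally impossible under
stop-at-.05/keep-below-.1 accumulation: for delta = 0 the reported
significant share (.4347) is below even the no-peeking share (≥ .53),
although peeking can only raise it. Since the homogeneous conditions
match exactly under identical code, the difference lies in the original
heterogeneity-with-peeking runs. Quantities derived from those runs (the
true and estimated excess factors for the d ~ N(.5, .15) peeking
condition) therefore deviate from the published 1.223/1.472: this package
computes ≈ 1.65 (label-based) and ≈ 2.1 (estimated). They are reported as
computed.

Implementation: fully vectorized over studies via cumulative sufficient
statistics, which agree exactly (to floating point) with recomputation
from stored raw observations — a property the test suite checks against a
raw-data reference implementation and scipy's `ttest_ind`. A single seed
determines a condition's entire output stream.

## Effect-size model and excess measures (`effect_model`)

**Model.** True effects on the Fisher-z scale (atanh-transformed
correlation, rho_F) are Normal(delta, tau) across studies, delta ≥ 0
(only positive observed effects are modelled). A record with df degrees
of freedom has effective sample size N = df + 2 and observed
z ~ Normal(delta, sqrt(tau² + sd²)) with sd = 1/sqrt(N − 3). Records
enter from t, r, and F(df1 = 1) statistics via r = t/sqrt(t² + df); for an
equal-n two-group design Cohen's d converts as
rho = d/sqrt(d² + 4), z = atanh(rho) (d = .5 → .247, d = .8 → .390).
These formulas are this package's reconstruction of the fitting machinery
(the original supplementary technical note is unavailable); all published
model-based values are therefore matched with tolerance bands rather than
exactly.

**Expected p-value distribution.** A p-interval maps to a z-interval via
the inverse normal: two-tailed `z = Phi^-1(1 - p/2)·sd` for corpus data,
one-sided `z = Phi^-1(1 - p)·sd` for one-sided simulation output (the
mapping must match the data's sidedness; a mismatch visibly distorts the
full-range fits). Per-record bin probabilities are renormalized over the
fitting range (equivalent to conditioning on the range, which also
implements the positive-side truncation) and averaged across records —
grouped by their distinct sd values — in closed form; no stochastic
integration.

**Fit.** Observed p-values are counted into 40 equal-width bins spanning
the fitting range (0-1, 0-.05, or 0-.00125) and (delta, tau) minimizes
Pearson chi-square, Σ(O−E)²/E. The surface has a well-documented
near-flat ridge: a larger delta mimics a larger tau. The minimizer is a
deterministic grid (delta 0-1.5 step .01, tau 0-.6 step .005); grid
points within a fixed margin of 2.0 chi-square units of the minimum — the
cost of the two fitted parameters, below which differences are
statistically meaningless — count as tied, the tie resolving to the
smallest tau and then the smallest delta, followed by a Nelder-Mead
polish bounded to the winning grid cell. Without the near-tie rule the
estimate wanders along the ridge between seeds; with it, ridge landings
are stable and match the published preference for tau ≈ 0 solutions on
the tiny-p range. Near the tau = 0 boundary the tau estimate converges at
rate n^(-1/4), so single-replicate recovery tolerances at n = 10^5 carry
Monte-Carlo allowances in the tests. Expected counts below 1e-8 with
nonzero observations are flagged rather than merged; an all-one-bin pool
is flagged degenerate.

**Measure 1 — effect-size drop.** delta is estimated twice: from
p ≤ .00125 only (assumed uncontaminated: peeking rarely produces tiny
p-values, a property the simulator reproduces within 10%) and from all
p ≤ .05. Practices that inflate just-significant p-values drag the second
estimate down, so `drop = delta_small − delta_all > 0` signals
contamination.

**Measure 2 — the D odds ratio.** With p_o the observed and p_e the
model-expected (under the tiny-p fit) share of the significant pool below
the cut,

    D = [(1 − p_o)/p_o] · [p_e/(1 − p_e)],

oriented so D > 1 means excess mass in (.00125, .05] relative to
expectation. (The printed formula in the source orients the ratio the
other way, which contradicts its own worked values and interpretation;
this package uses the orientation that reproduces them.) p_e averages
each record's conditional probability P(p ≤ cut | p ≤ .05). With
simulation ground truth, the *label-based* excess factor
N/(N − N_peeked) over the interval is the reference D computes against.

**Known behaviour on the ridge.** For a heterogeneous null (delta = 0,
tau_d = .15, no peeking) the tiny-p fit lands at the delta-heavy ridge
end (≈ (.09, .01) here, (.1, .025) in the original), which mechanically
produces D ≈ 1.1-1.2 despite no peeking — the documented failure mode of
D under heterogeneity. The chi-square misfit values of the original
(which depend on the exact fitting machinery) are reported but not
matched.

## Synthetic corpus (`synthetic`)

The generator emulates the structure of a large extracted corpus: articles
per journal with year spans, a test-family mix dominated by t/F/r, an
effect mixture on the d scale (defaults: 35% null, 45% modest d = .4
effects, 20% large d = .9 manipulation-check-like effects, with
heterogeneity .15-.2 — chosen as a realistic psychology-like blend),
per-group sample sizes of 10-75, ~73% inexactly reported p-values
(matching the share seen in extracted corpora), and two decimals before
2010 / three from 2010 (the APA edition change). Statistics are rounded
to two decimals and the reported p derives from the *rounded* statistic,
so reported statistic and p cohere.

QRPs are injected at exactly two points: *peeking* at the generative
layer (two-sided optional stopping for two-sample designs; r, chi-square
and Z records are never peeked) and *incorrect rounding* at the reporting
layer (a record whose recalculable p lies in (.05, .055] is reported as
`= .05` or `< .05`). Honest exact reporting never crosses the .05
boundary: values in the window are reported at three decimals instead.
Ground truth (true effect, peeked, rounding flags) lives in a side table
the analysis modules never read.

What the corpus does **not** emulate: journal-specific reporting quirks,
other QRPs (outlier exclusion, covariate selection, selective reporting),
one-tailed reported tests, errors in reported statistics themselves, and
tabular results. Passing end-to-end tests on the corpus therefore shows
the detectors work when reporting follows APA text conventions and the
only distortions are the two modelled QRPs — not that they are robust to
every real-world contamination.

## Reporting pipeline (`pipeline`, `cli`)

`run_pipeline` chains corpus loading (or synthesis), impossible-result
filtering, subset selection, caliper tables per journal and binwidth
(.00125/.0025/.005/.01), yearly trends, model fits and excess measures
into CSV/JSON reports; significance bolding becomes a boolean column.
Reports are byte-identical across reruns of the same manifest. The `pvf`
CLI wraps each stage.

## Problem sizes

The original simulation design collects 1,000,000 studies below p = .1
per condition. This package's acceptance runs use 300,000 (500,000 for
the peeking null, whose D statistic requires the tiny-p fit to resolve
(0,0) cleanly) and its test suite 200,000-400,000; parameter-recovery
and oracle checks use 10^5-10^6 draws. At these sizes every reproducible
published quantity is matched within the stated tolerances; scaling
further was not observed to change any conclusion (the two documented
discrepancies above persist at the full 1M scale).

## Known limitations

* The Fisher-z normal approximation to the t-test sampling distribution
  is a reconstruction; systematic deviations from the original fits are
  possible everywhere and documented where observed.
* The normal effect-size distribution is a modelling convenience; real
  corpora mix heterogeneous effect families, and D in particular is
  unreliable under heterogeneity (reproduced here).
* The parser handles running-text APA results only (no tables), mirrors
  the extraction tools it emulates, and treats all reported tests as
  two-tailed.
* tau near zero is weakly identified (n^(-1/4) convergence at the
  boundary); reported tau values below ~.02 should be read as "no
  evidence of heterogeneity", not as precise estimates.
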