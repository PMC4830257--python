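# pvforensics

Forensic statistics for collections of reported p-values.

Large corpora of published test results carry fingerprints of how the
research behind them was conducted. Because an APA-style result —
`t(85) = 2.86, p = .005` — reports both the statistic and the p-value,
every record can be audited: the p-value is recalculated from the
statistic and degrees of freedom, and disagreements that flip
significance at .05 (*gross inconsistencies*) expose misreporting such as
rounding p = .052 down to "p = .05". Beyond individual records, the
*shape* of the distribution of significant p-values is informative: under
honest reporting it must decrease monotonically, so a bump just below .05
— or a monotonic excess there — points to questionable research practices
(QRPs) such as optional stopping ("data peeking").

`pvforensics` is aimed at meta-researchers auditing published literatures
and at methodologists studying QRP detectors. It provides:

* **`pvforensics.apa`** — an APA result parser (t, F, r, χ², Z),
  p-value recalculation, consistency/gross-inconsistency classification
  with rounding-aware windows, impossible-result filtering, and the
  standard analysis subsets;
* **`pvforensics.caliper`** — the Caliper bump test: for counts x of N in
  two adjacent intervals below .05, the exact one-tailed binomial test of
  H₀: Pr ≤ ½ against a bump (Pr = x/N > ½), plus its linear time trend;
* **`pvforensics.peeking`** — a vectorized optional-stopping simulator:
  two-sample t-tests with n_k = 24 per group, up to three rounds of
  additional sampling (each +⅓ of the original n) after a nonsignificant
  look, stopping at p ≤ .05;
* **`pvforensics.effect_model`** — estimation of the effect-size
  distribution underlying truncated significant p-values. True Fisher-z
  effects are modelled as Normal(δ, τ); a record with effective sample
  size N = df + 2 contributes an observed z with SD 1/√(N−3). (δ, τ) are
  fitted by minimizing the Pearson χ² over 40 p-value bins. Two excess
  measures follow: the *effect-size drop* (δ̂ from p ≤ .00125 minus δ̂
  from p ≤ .05) and the odds ratio
  **D = [(1−p_o)/p_o] · [p_e/(1−p_e)]**, where p_o and p_e are the
  observed and model-expected shares of significant p-values below
  .00125; D > 1 signals excess just-significant results;
* **`pvforensics.synthetic`** — a synthetic-literature generator with
  ground-truth labels and injectable QRPs (peeking, incorrect rounding)
  for end-to-end validation without any external data;
* **`pvforensics.pipeline` / the `pvf` CLI** — orchestrated runs
  producing caliper tables, trend fits and measure reports.

## Worked example

```python
from pvforensics import parse_apa_result, consistency_check, caliper_test

text = ("Group means differed, t(85) = 2.86, p = .005; "
        "the interaction was significant, F(1, 46) = 4.05, p = .05.")
for res in parse_apa_result(text):
    v = consistency_check(res, "wide_05")
    print(f"{res.test_family.value}: reported p = {res.reported_p}, "
          f"recalculated p = {v.recalculated_p:.4f}, "
          f"consistent = {v.consistent}, gross = {v.gross_inconsistency}")

res = caliper_test([0.043] * 40 + [0.048] * 60, binwidth=0.005)
print(f"caliper: x = {res.x}, N = {res.N}, Pr = {res.Pr:.2f}, "
      f"binomial p = {res.p_binomial:.4f}")
```

```
t: reported p = 0.005, recalculated p = 0.0053, consistent = True, gross = False
F: reported p = 0.05, recalculated p = 0.0500, consistent = True, gross = False
caliper: x = 60, N = 100, Pr = 0.60, binomial p = 0.0284
```

Both reported results check out (the t-test's .0053 rounds to the
reported .005), and a 60:40 split across two adjacent intervals below .05
is significant evidence of a bump (p = .0284).

Simulating the QRP itself and detecting it:

```python
from pvforensics.peeking import PeekingDesign, simulate_condition
from pvforensics.effect_model import (pool_from_outcomes, excess_measures,
                                      true_D_from_labels)

design = PeekingDesign(delta=0.0, tau=0.0, seed=11)   # null effects
cond = simulate_condition(design, 100_000, peeking=True)
kept = cond.kept
print(f"kept {len(kept)} of {cond.n_attempted} studies; "
      f"{(kept.p_final <= .05).mean():.1%} significant, "
      f"{kept.significant_via_peek.mean():.1%} via peeking")
meas = excess_measures(pool_from_outcomes(kept))
print(f"D = {meas.D:.2f}  (true excess factor from ground-truth labels: "
      f"{true_D_from_labels(kept):.2f})")
```

```
kept 100000 of 767033 studies; 75.9% significant, 37.7% via peeking
D = 2.03  (true excess factor from ground-truth labels: 2.01)
```

With pure null effects, optional stopping makes 76% of the collected
studies significant; the D measure estimates a two-fold excess of
just-significant p-values, matching the labelled ground truth.

## Command line

```
pvf parse article.txt --out results.csv
pvf recalc results.csv --out results_recalc.csv
pvf consistency results.csv --window wide_05
pvf caliper results.csv --binwidth 0.00125 --mode recalculated
pvf trend results.csv --center 1985
pvf simulate --delta 0.5 --tau 0.15 --peeking --n-keep 100000 --seed 42 --out outcomes.csv
pvf fit results.csv --range 0:.05 --bins 40
pvf measures results.csv --cut .00125
pvf synth --out corpus.csv --truth truth.csv --seed 1
pvf run --manifest run.json
```

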