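"""Fisher-z effect model: conversions, expected distributions, fits, measures."""

import numpy as np
import pytest
from scipy import special, stats

from pvforensics.apa import TestFamily, TestResult
from pvforensics.effect_model import (
    FisherZEffectModel,
    PValuePool,
    bin_pool,
    d_to_fisher_z,
    effective_normal_params,
    excess_measures,
    expected_bin_proportions,
    expected_significant_share,
    fit_effect_model,
    pool_from_outcomes,
    true_D_from_labels,
)
from pvforensics.peeking import StudyOutcomes

SD46 = 1.0 / np.sqrt(45.0)  # sampling SD for a t(46) record (N = 48)


class TestConversions:
    @pytest.mark.parametrize(
        "d, expected",
        [(0.0, 0.0), (0.5, 0.247), (0.8, 0.390), (-0.5, -0.247)],
    )
    def test_d_to_fisher_z_printed_values(self, d, expected):
        assert round(d_to_fisher_z(d), 3) == expected

    def test_odd_function(self, rng):
        for d in rng.uniform(-3, 3, 20):
            assert d_to_fisher_z(-d) == pytest.approx(-d_to_fisher_z(d), abs=1e-14)

    def test_effective_params_null_t(self):
        z, sd = effective_normal_params(TestResult(TestFamily.t, 0.0, df2=46))
        assert z == 0.0
        assert sd == pytest.approx(SD46, abs=1e-12)

    def test_effective_params_r(self):
        z, sd = effective_normal_params(TestResult(TestFamily.r, 0.3, df2=45))
        assert z == pytest.approx(np.arctanh(0.3), abs=1e-12)
        assert sd == pytest.approx(1 / np.sqrt(44), abs=1e-12)

    def test_f1_equals_t_mapping(self):
        z_f, sd_f = effective_normal_params(TestResult(TestFamily.F, 4.0, df1=1, df2=46))
        z_t, sd_t = effective_normal_params(TestResult(TestFamily.t, 2.0, df2=46))
        assert z_f == pytest.approx(z_t, abs=1e-14)
        assert sd_f == sd_t

    def test_unsupported_family(self):
        with pytest.raises(ValueError, match="unsupported"):
            effective_normal_params(TestResult(TestFamily.chi2, 5.0, df1=2))


def model_pool(rng, delta, tau, n, sd=SD46, tails=2):
    """Generate p-values from the generative model itself (positive side)."""
    z = rng.normal(delta, np.sqrt(tau**2 + sd**2), size=n)
    if tails == 2:
        keep = z > 0
        p = 2 * special.ndtr(-z[keep] / sd)
        return PValuePool(p, np.full(keep.sum(), sd), tails=2)
    p = special.ndtr(-z / sd)
    return PValuePool(p, np.full(n, sd), tails=1)


class TestExpectedProportions:
    def test_null_model_is_uniform_over_any_range(self, rng):
        pool = model_pool(rng, 0.3, 0.0, 2000)  # data irrelevant to expectation
        for fit_range in [(0.0, 0.05), (0.0, 1.0), (0.0, 0.00125)]:
            bins = bin_pool(pool, fit_range, 40)
            props = expected_bin_proportions(FisherZEffectModel(0.0, 0.0), bins)
            np.testing.assert_allclose(props, np.full(40, 1 / 40), atol=1e-12)

    @pytest.mark.parametrize(
        "delta, tau, fit_range",
        [
            (0.1, 0.0, (0.0, 0.05)),
            (0.3, 0.1, (0.0, 0.05)),
            (0.0, 0.2, (0.0, 1.0)),
            (0.25, 0.05, (0.0, 1.0)),
            (0.4, 0.15, (0.0, 0.00125)),
        ],
    )
    def test_proportions_sum_to_one(self, rng, delta, tau, fit_range):
        pool = model_pool(rng, 0.3, 0.1, 3000)
        bins = bin_pool(pool, fit_range, 40)
        props = expected_bin_proportions(FisherZEffectModel(delta, tau), bins)
        assert props.sum() == pytest.approx(1.0, abs=1e-9)
        assert (props >= 0).all()

    @pytest.mark.parametrize(
        "delta, tau",
        [(0.0, 0.0), (0.3, 0.1), (0.1, 0.0), (0.0, 0.15), (0.25, 0.2)],
    )
    def test_matches_monte_carlo_oracle(self, delta, tau):
        """Closed-form bin probabilities equal brute-force simulation of the
        generative model (normal effect + normal sampling error, positive
        side, conditioned on the fitting range)."""
        rng = np.random.default_rng(777)
        n = 1_000_000
        zs = rng.normal(delta, np.sqrt(tau**2 + SD46**2), size=n)
        zs = zs[zs > 0]
        p_mc = 2 * special.ndtr(-zs / SD46)
        in_range = p_mc <= 0.05
        p_mc = p_mc[in_range]
        edges = np.linspace(0, 0.05, 11)
        observed = np.histogram(p_mc, bins=edges)[0] / p_mc.size

        pool = PValuePool(p_mc, np.full(p_mc.size, SD46), tails=2)
        bins = bin_pool(pool, (0.0, 0.05), 10)
        expected = expected_bin_proportions(FisherZEffectModel(delta, tau), bins)
        se = np.sqrt(expected * (1 - expected) / p_mc.size)
        assert np.all(np.abs(observed - expected) <= 3 * se + 1e-9)

    def test_one_sided_mapping_oracle(self):
        rng = np.random.default_rng(778)
        delta, tau = 0.2, 0.1
        zs = rng.normal(delta, np.sqrt(tau**2 + SD46**2), size=500_000)
        p_mc = special.ndtr(-zs / SD46)  # one-sided p, both directions kept
        edges = np.linspace(0, 1, 21)
        observed = np.histogram(p_mc, bins=edges)[0] / p_mc.size
        pool = PValuePool(p_mc, np.full(p_mc.size, SD46), tails=1)
        bins = bin_pool(pool, (0.0, 1.0), 20)
        expected = expected_bin_proportions(FisherZEffectModel(delta, tau), bins)
        se = np.sqrt(expected * (1 - expected) / p_mc.size)
        assert np.all(np.abs(observed - expected) <= 4 * se + 1e-9)


class TestFit:
    def test_parameter_recovery_homogeneous(self):
        """delta recovered within .01 and tau within .02 on model data."""
        rng = np.random.default_rng(4242)
        pool = model_pool(rng, 0.25, 0.0, 100_000)
        fit = fit_effect_model(pool, (0.0, 0.05))
        assert fit.model.delta == pytest.approx(0.25, abs=0.01)
        assert fit.model.tau <= 0.02

    def test_parameter_recovery_full_range(self):
        rng = np.random.default_rng(4243)
        pool = model_pool(rng, 0.15, 0.1, 100_000, tails=1)
        fit = fit_effect_model(pool, (0.0, 1.0))
        assert fit.model.delta == pytest.approx(0.15, abs=0.02)
        assert fit.model.tau == pytest.approx(0.1, abs=0.02)

    def test_ridge_under_heterogeneous_null(self):
        """delta = 0 with tau > 0 fitted on tiny p-values sits on a flat
        delta-tau ridge: the chi-square difference along the ridge is small
        even though the parameter combinations differ widely."""
        rng = np.random.default_rng(4244)
        pool = model_pool(rng, 0.0, 0.075, 400_000)
        sub = pool.restrict(0.0, 0.00125)
        bins = bin_pool(pool, (0.0, 0.00125), 40)
        fit = fit_effect_model(pool, (0.0, 0.00125))
        # compare chi2 at the fit against the other ridge end
        from pvforensics.effect_model import _bin_prop_grid, _chi2_grid

        def chi2_at(delta, tau):
            props = _bin_prop_grid(np.array([delta]), np.array([tau]), bins)[0, 0]
            props = props / props.sum()
            return float(_chi2_grid(bins.counts, props[None, :])[0])

        other_end = chi2_at(0.1, 0.02) if fit.model.delta < 0.05 else chi2_at(0.0, 0.07)
        assert other_end - fit.chi2_misfit < 3 * np.sqrt(2 * 40)  # ~flat in chi2 units

    def test_empty_pool_raises(self):
        pool = PValuePool(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            fit_effect_model(pool, (0.0, 0.05))

    def test_degenerate_pool_flagged(self):
        pool = PValuePool(np.full(50, 0.049), np.full(50, SD46))
        fit = fit_effect_model(pool, (0.0, 0.05))
        assert fit.degenerate


class TestExcessMeasures:
    def test_D_is_one_for_model_consistent_data(self):
        """When observed and expected proportions agree, D ~ 1."""
        rng = np.random.default_rng(5555)
        pool = model_pool(rng, 0.0, 0.0, 4_000_000)  # null: p uniform
        meas = excess_measures(pool)
        assert meas.D == pytest.approx(1.0, abs=0.1)
        assert meas.p_exp_below_cut == pytest.approx(0.025, abs=0.005)
        assert meas.p_obs_below_cut == pytest.approx(0.025, rel=0.1)

    def test_hand_computed_odds_ratio(self):
        """D follows the odds-ratio arithmetic: observed .9 vs expected .8
        mass above the cut gives (.9/.1)/(.8/.2) = 2.25."""
        p_obs_below, p_exp_below = 0.1, 0.2
        D = ((1 - p_obs_below) / p_obs_below) * (p_exp_below / (1 - p_exp_below))
        assert D == pytest.approx(2.25)

    def test_injected_excess_strictly_increases_D(self):
        rng = np.random.default_rng(600)
        pool = model_pool(rng, 0.0, 0.0, 2_000_000)
        base = excess_measures(pool)
        Ds = [base.D]
        sub = pool.restrict(0.0, 0.05)
        for frac in (0.2, 0.5):
            extra = rng.uniform(0.00125, 0.05, size=int(frac * len(sub)))
            injected = PValuePool(
                np.concatenate([sub.p, extra]),
                np.concatenate([sub.sd_z, np.full(extra.size, SD46)]),
                tails=2,
            )
            Ds.append(excess_measures(injected).D)
        assert Ds[0] < Ds[1] < Ds[2]

    def test_cut_too_small(self):
        rng = np.random.default_rng(601)
        pool = PValuePool(rng.uniform(0.01, 0.05, 1000), np.full(1000, SD46))
        with pytest.raises(ValueError, match="cut too small"):
            excess_measures(pool, cut=0.00125)

    def test_effect_drop_negative_under_peeking(self, cond_peek_d02):
        """Optional stopping depresses the all-significant estimate more
        than the tiny-p estimate, so the drop (small - all) is positive."""
        pool = pool_from_outcomes(cond_peek_d02.kept)
        meas = excess_measures(pool)
        assert meas.effect_drop > 0.03
        assert meas.D > 1.2


class TestTrueD:
    def _outcomes(self, p, rounds):
        n = len(p)
        return StudyOutcomes(
            p_final=np.asarray(p, dtype=float),
            t_final=np.ones(n),
            n_final_per_group=np.full(n, 24),
            rounds_used=np.asarray(rounds),
            d_drawn=np.zeros(n),
            alpha=0.05,
        )

    def test_no_peeked_labels_gives_one(self):
        out = self._outcomes([0.01, 0.02, 0.03], [0, 0, 0])
        assert true_D_from_labels(out) == 1.0

    def test_counting_oracle(self, rng):
        p = rng.uniform(0, 0.06, 500)
        rounds = rng.integers(0, 4, 500)
        out = self._outcomes(p, rounds)
        interval = (p > 0.00125) & (p <= 0.05)
        peeked = interval & (rounds > 0) & (p <= 0.05)
        expected = interval.sum() / (interval.sum() - peeked.sum())
        assert true_D_from_labels(out) == pytest.approx(expected, abs=1e-12)

    def test_paper_scale_arithmetic(self):
        # 582,659 interval results of which 106,241 peek-obtained -> 1.223
        assert 582_659 / (582_659 - 106_241) == pytest.approx(1.223, abs=5e-4)

    def test_all_peeked_interval_raises(self):
        out = self._outcomes([0.01, 0.02], [1, 2])
        with pytest.raises(ValueError):
            true_D_from_labels(out)


class TestSignificantShare:
    def test_null_share_equals_alpha(self):
        model = FisherZEffectModel(0.0, 0.0)
        share = expected_significant_share(model, np.full(10, SD46), alpha=0.05)
        assert share == pytest.approx(0.05, abs=1e-9)

    def test_large_effect_share_tends_to_one(self):
        model = FisherZEffectModel(1.4, 0.0)
        share = expected_significant_share(model, np.full(10, SD46))
        assert share > 0.99

    def test_heterogeneous_share_matches_monte_carlo(self):
        rng = np.random.default_rng(888)
        model = FisherZEffectModel(0.0, 0.183)
        n = 1_000_000
        z = rng.normal(0.0, np.sqrt(0.183**2 + SD46**2), size=n)
        p = 2 * special.ndtr(-np.abs(z) / SD46)
        mc = (p <= 0.05).mean()
        share = expected_significant_share(model, np.array([SD46]), alpha=0.05)
        assert share == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / n))
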