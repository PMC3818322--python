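"""Derived feeding statistics: summaries, intervals, sweeps, standardisation."""

import math

import numpy as np
import pytest

from oikofeed import (
    Environment,
    ModelParameters,
    Scenario,
    accumulation_rate,
    food_sweep,
    gut_passage_time,
    half_saturation_wrt_food,
    pellet_onset_concentration,
    simulate,
    standardize,
    summarize,
)
from oikofeed.analysis import steady_defecation_interval
from oikofeed.rates import filtration_rate

P = ModelParameters()


class TestSummarize:
    def test_constant_food_mean_filtration_is_instantaneous_rate(self, standard_run):
        s = summarize(standard_run)
        assert s.mean_F == pytest.approx(filtration_rate(P, 1.0, 15.0, 100.0), rel=1e-6)

    def test_efficiencies_are_proper_fractions(self, standard_run):
        s = summarize(standard_run)
        assert 0 < s.ingestion_efficiency < 1
        assert 0 < s.assimilation_efficiency < 1
        assert s.mean_F > s.mean_I > s.mean_A > 0

    def test_gpt_is_steady_interval_times_pellet_number(self, standard_run):
        s = summarize(standard_run)
        assert s.gut_passage_time_min == pytest.approx(
            s.defecation_interval_steady_min * P.nbfp, rel=1e-12)
        # the settled cadence is faster than the raw mean interval, which
        # still carries the post-renewal refill lags
        assert s.defecation_interval_steady_min < s.defecation_interval_min

    def test_undefined_interval_reported_as_nan_not_zero(self):
        traj = simulate(Scenario(
            environment=Environment.constant_food(15.0, 10.0, 1.0),
            n_house_cycles=4))
        s = summarize(traj)
        assert traj.n_pellets < 2
        assert math.isnan(s.defecation_interval_min)
        assert math.isnan(s.gut_passage_time_min)

    def test_final_cycle_window(self, standard_run):
        s = summarize(standard_run, final_cycle_only=True)
        assert s.window_days == pytest.approx(2.91 / 24.0, rel=1e-9)
        # the final cycle has no start-up transient, so it assimilates more
        assert s.mean_A > summarize(standard_run).mean_A


class TestAccumulationRate:
    def test_house_content_over_lifespan(self, standard_run):
        rate = accumulation_rate(standard_run)
        assert rate == pytest.approx(0.17 / (2.91 / 24.0), rel=0.05)

    def test_zero_food_zero_rate(self):
        traj = simulate(Scenario(
            environment=Environment.constant_food(15.0, 0.0, 1.0),
            n_house_cycles=2))
        assert accumulation_rate(traj) == 0.0

    def test_requires_a_completed_cycle(self):
        traj = simulate(Scenario(
            environment=Environment.constant_food(15.0, 100.0, 1.0),
            duration_days=0.05, renewals_enabled=False))
        with pytest.raises(ValueError):
            accumulation_rate(traj)


class TestSteadyDefecationInterval:
    def test_settled_cadence_ignores_renewal_spanning_intervals(self):
        renewals = np.array([10.0])
        # cadence settles to 1.0 before the renewal; the 9->11 interval spans it
        pellets = np.array([2.0, 3.5, 4.7, 5.8, 6.9, 8.0, 9.0, 11.0, 12.5, 13.6])
        di = steady_defecation_interval(pellets, renewals)
        assert di == pytest.approx((1.0 + 1.1) / 2)

    def test_falls_back_to_plain_mean(self):
        pellets = np.array([1.0, 3.0])
        di = steady_defecation_interval(pellets, np.array([2.0]))
        assert di == pytest.approx(2.0)


class TestStandardize:
    def test_hand_computed_example(self):
        out = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_moments_and_idempotence(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, 100)
        z = standardize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(standardize(z), z, atol=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            standardize([1.0])

    def test_sample_sd_convention_close_to_population(self):
        x = np.arange(50.0)
        pop = standardize(x)
        samp = standardize(x, ddof=1)
        assert np.abs(pop / samp - 1).max() < 0.02


class TestPelletOnset:
    def test_grid_below_onset_reports_none(self):
        assert pellet_onset_concentration(P, 15.0, 1.0, [5.0, 10.0, 15.0]) is None

    def test_onset_independent_of_body_weight(self):
        grid = np.arange(20.0, 40.0, 2.0)
        onset_small = pellet_onset_concentration(P, 15.0, 0.5, grid)
        onset_large = pellet_onset_concentration(P, 15.0, 4.0, grid)
        assert onset_small == onset_large

    def test_grid_must_be_ascending(self):
        with pytest.raises(ValueError):
            pellet_onset_concentration(P, 15.0, 1.0, [30.0, 20.0])


class TestHalfSaturation:
    def test_recovers_known_constant_from_exact_michaelis_curve(self):
        # the plateau convention (value at the grid top) needs the sweep to
        # extend far beyond K for the identity to hold
        fc = np.linspace(1.0, 20000.0, 4000)
        curve = 5.0 * fc / (40.0 + fc)
        k = half_saturation_wrt_food(fc, curve)
        assert k == pytest.approx(40.0, rel=0.02)

    def test_non_saturating_curve_rejected(self):
        fc = np.linspace(1.0, 100.0, 50)
        with pytest.raises(ValueError):
            half_saturation_wrt_food(fc, fc)  # linear, never saturates


@pytest.fixture(scope="module")
def sweep():
    return food_sweep(P, 15.0, 1.0, [10.0, 40.0, 100.0, 300.0], n_cycles=2)


class TestFoodSweep:
    def test_mean_rates_nondecreasing_in_food(self, sweep):
        for col in ("mean_F", "mean_I", "mean_A"):
            assert np.all(np.diff(sweep[col]) >= -1e-9)

    def test_efficiencies_decrease_above_onset(self, sweep):
        eff = sweep["ingestion_efficiency"].to_numpy()
        assert np.all(np.diff(eff) <= 1e-9)

    def test_gpt_identity_function(self):
        assert gut_passage_time(10.0, 3.368) == pytest.approx(33.68)
        assert gut_passage_time(10.0, 1.0) == 10.0
        assert math.isnan(gut_passage_time(math.nan, 3.368))
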