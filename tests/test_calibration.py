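"""Least-squares estimation machinery on synthetic observations.

The heavy global-search recovery and the replicate coverage study live in the
acceptance suite; here the cost function, the generator and the local fitting
paths are exercised on small designs.
"""

import numpy as np
import pytest

from oikofeed.calibration import (
    DEFAULT_BOUNDS,
    Observation,
    confidence_intervals,
    cost,
    default_design,
    fit_least_squares,
    fit_local,
    generate_synthetic_observations,
    observations_from_csv,
    observations_to_csv,
    predict,
)
from tests.conftest import THETA_TRUE

#: Small design (4 distinct conditions) keeping each cost evaluation cheap.
SMALL_DESIGN = [
    (15.0, fc, 1.0, kind)
    for fc in (20.0, 60.0, 150.0, 400.0)
    for kind in ("ingestion_rate", "assimilation_rate")
]


@pytest.fixture(scope="module")
def clean_obs():
    return generate_synthetic_observations(THETA_TRUE, design=SMALL_DESIGN,
                                           noise_sd=0.0, seed=0)


class TestCost:
    def test_zero_at_generating_parameters(self, clean_obs):
        assert cost(THETA_TRUE, clean_obs) == pytest.approx(0.0, abs=1e-20)

    def test_nonnegative_and_order_invariant(self, clean_obs):
        theta = THETA_TRUE * 1.1
        forward = cost(theta, clean_obs)
        backward = cost(theta, clean_obs[::-1])
        assert forward >= 0
        assert forward == pytest.approx(backward, rel=1e-12)

    @pytest.mark.parametrize("component", [0, 1, 2, 3])
    def test_single_component_perturbation_raises_cost(self, clean_obs, component):
        theta = THETA_TRUE.copy()
        theta[component] *= 1.2
        assert cost(theta, clean_obs) > cost(THETA_TRUE, clean_obs)

    def test_infeasible_ordering_penalised(self, clean_obs):
        swapped = np.array([0.4818, 0.0029, 1.2232, 0.0282])  # a > i, ka > ki
        assert cost(swapped, clean_obs) > 1e5

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            cost(THETA_TRUE, [])

    def test_weights_change_the_balance(self, clean_obs):
        theta = THETA_TRUE * 1.05
        w = np.linspace(0.1, 2.0, len(clean_obs))
        assert cost(theta, clean_obs, weights=w) != pytest.approx(
            cost(theta, clean_obs), rel=1e-6)


class TestGenerator:
    def test_noise_free_equals_forward_model(self, clean_obs):
        values = np.array([o.value for o in clean_obs])
        np.testing.assert_allclose(values, predict(THETA_TRUE, clean_obs), rtol=1e-12)

    def test_seed_reproducibility(self):
        a = generate_synthetic_observations(THETA_TRUE, SMALL_DESIGN, 0.05, seed=3)
        b = generate_synthetic_observations(THETA_TRUE, SMALL_DESIGN, 0.05, seed=3)
        c = generate_synthetic_observations(THETA_TRUE, SMALL_DESIGN, 0.05, seed=4)
        assert [o.value for o in a] == [o.value for o in b]
        assert [o.value for o in a] != [o.value for o in c]

    def test_empirical_noise_matches_requested_sd(self):
        sd = 0.05
        reps = np.array([
            [o.value for o in generate_synthetic_observations(
                THETA_TRUE, SMALL_DESIGN[:2], sd, seed=s)]
            for s in range(150)
        ])
        assert reps.std(axis=0) == pytest.approx(sd, rel=0.25)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_observations(THETA_TRUE, SMALL_DESIGN, -0.1)

    def test_default_design_has_six_series(self):
        design = default_design()
        series = {(t, bo, kind) for t, _, bo, kind in design}
        assert len(series) == 6
        temps = {t for t, *_ in design}
        assert temps == {15.0, 20.0}


class TestObservationIO:
    def test_csv_round_trip(self, clean_obs, tmp_path):
        path = tmp_path / "obs.csv"
        observations_to_csv(clean_obs, path)
        back = observations_from_csv(path)
        assert back == clean_obs

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        observations_to_csv([], path)
        with pytest.raises(ValueError):
            observations_from_csv(path)

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            Observation(15.0, 100.0, 1.0, "respiration_rate", 1.0)


class TestLocalFits:
    def test_least_squares_refit_recovers_from_noisy_start(self, clean_obs):
        start = THETA_TRUE * np.array([1.3, 0.7, 1.2, 0.8])
        res = fit_least_squares(clean_obs, start)
        assert np.abs(res.theta / THETA_TRUE - 1).max() < 0.01
        assert res.cost < 1e-10
        assert not res.on_boundary

    def test_hessian_is_positive_definite_and_cis_contain_estimate(self):
        obs = generate_synthetic_observations(THETA_TRUE, SMALL_DESIGN,
                                              noise_sd=0.01, seed=9)
        res = fit_least_squares(obs, THETA_TRUE * 1.05)
        assert np.all(np.linalg.eigvalsh(res.hessian) > 0)
        ci, _ = confidence_intervals(res, seed=0)
        assert np.all(ci[:, 0] <= res.theta) and np.all(res.theta <= ci[:, 1])
        # estimated ordering constraints hold
        i_, ki_, a_, ka_ = res.theta
        assert a_ < i_ and ka_ < ki_

    def test_noise_free_intervals_collapse_onto_estimate(self, clean_obs):
        res = fit_least_squares(clean_obs, THETA_TRUE * 1.02)
        ci, _ = confidence_intervals(res, seed=0)
        np.testing.assert_allclose(ci[:, 0], res.theta, rtol=1e-4)
        np.testing.assert_allclose(ci[:, 1], res.theta, rtol=1e-4)

    def test_bounds_excluding_truth_flagged_on_boundary(self, clean_obs):
        bounds = ((1e-3, 1.0), DEFAULT_BOUNDS[1], DEFAULT_BOUNDS[2], DEFAULT_BOUNDS[3])
        res = fit_local(clean_obs, np.array([0.9, 0.0282, 0.45, 0.0029]),
                        bounds=bounds, polish=False)
        assert res.on_boundary
        assert res.theta[0] == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("seed", [21, 24, 26])
    def test_identifiable_functionals_under_relative_noise(self, seed):
        """With 5 % relative noise the individually weak parameters (a, ka)
        trade off along a ridge, but the observables they control stay
        determined: the ingestion maximum i and the effective assimilation
        plateau a·cap/(ka + cap) (cap = nbfp·fpp per unit allometric weight)
        recover to ~15 % with noise-matched weights."""
        obs = generate_synthetic_observations(THETA_TRUE, default_design(),
                                              noise_sd=0.05, relative=True,
                                              seed=seed)
        weights = [1.0 / max(o.value, 1e-3) ** 2 for o in obs]
        res = fit_least_squares(obs, THETA_TRUE * np.array([1.2, 0.8, 1.2, 0.8]),
                                weights=weights)
        cap = 3.368 * 0.0175

        def plateau(theta):
            return theta[2] * cap / (theta[3] + cap)

        assert abs(res.theta[0] / THETA_TRUE[0] - 1) < 0.15
        assert abs(plateau(res.theta) / plateau(THETA_TRUE) - 1) < 0.15
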