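"""Event-driven integration: conservation, events, scaling, drain oracle."""

import math

import numpy as np
import pytest

from oikofeed import (
    Environment,
    FoodSchedule,
    ModelParameters,
    OrganismState,
    Scenario,
    apply_egestion,
    apply_house_renewal,
    simulate,
)
from oikofeed.rates import faecal_pellet_weight, gut_capacity, temperature_scale
from oikofeed.simulate import IntegrationError

P = ModelParameters()


def michaelis_drain_time(x0: float, x1: float, k: float, vmax: float) -> float:
    """Closed-form implicit solution for a single Michaelis-drained pool:
    time (days) to fall from x0 to x1 at dX/dt = -vmax X/(k+X)."""
    return ((x0 - x1) + k * math.log(x0 / x1)) / vmax


@pytest.mark.parametrize("fc, T, bo, cycles", [
    (100.0, 15.0, 1.0, 4),
    (30.0, 15.0, 1.0, 4),
    (800.0, 15.0, 1.0, 2),
    (200.0, 20.0, 0.62, 4),
    (150.0, 10.0, 3.97, 2),
])
def test_carbon_conservation(fc, T, bo, cycles):
    """Filtered carbon equals house + detritus + gut + faeces + assimilated
    at every sample, to 1e-6 relative."""
    traj = simulate(Scenario(environment=Environment.constant_food(T, fc, bo),
                             n_house_cycles=cycles))
    assert traj.mass_balance_error() < 1e-6


def test_no_food_no_dynamics():
    traj = simulate(Scenario(environment=Environment.constant_food(15.0, 0.0, 1.0),
                             n_house_cycles=2))
    for arr in (traj.F, traj.I, traj.A, traj.hou, traj.gut, traj.det, traj.fec):
        assert np.all(arr == 0.0)
    assert traj.n_pellets == 0


def test_standard_run_paper_anchors(standard_run):
    """The constant-food reference run fills each house to ~0.17 µgC and
    produces its first pellet after ~90 min."""
    assert standard_run.renewal_amounts == pytest.approx([0.17] * 4, rel=0.05)
    first_pellet_min = standard_run.egestion_times[0] * 1440
    assert first_pellet_min == pytest.approx(90.0, rel=0.1)
    # houses repeat identically under constant forcing
    assert np.ptp(standard_run.renewal_amounts) < 1e-9
    assert standard_run.final_state.det == pytest.approx(
        4 * standard_run.renewal_amounts[0], rel=1e-9)


def test_trajectory_structural_invariants(standard_run):
    traj = standard_run
    assert np.all(np.diff(traj.times) > 0)
    for arr in (traj.det, traj.fec, traj.cum_filtered, traj.cum_ingested,
                traj.cum_assimilated):
        assert np.all(np.diff(arr) >= -1e-12)
    cap = gut_capacity(P, 1.0)
    assert np.max(traj.gut) <= cap * (1 + 1e-9)
    assert np.all(traj.event_carbon[traj.event_kinds == "egestion"] > 0)


def test_apply_house_renewal_moves_carbon_to_detritus():
    state = OrganismState(hou=0.17, gut=0.04, det=1.0, house_age=0.1)
    out = apply_house_renewal(state)
    assert out.det == pytest.approx(1.17)
    assert out.hou == 0.0
    assert out.gut == 0.04
    assert out.house_age == 0.0
    # an empty house only resets the age
    again = apply_house_renewal(out)
    assert again.det == out.det


def test_apply_egestion_removes_one_pellet():
    cap = gut_capacity(P, 1.0)
    fpw = faecal_pellet_weight(P, 1.0)
    state = OrganismState(gut=cap)
    out = apply_egestion(state, P, 1.0)
    assert out.gut == pytest.approx(cap - fpw)
    assert out.gut == pytest.approx(P.fpp * (P.nbfp - 1), rel=1e-9)
    assert out.fec == pytest.approx(fpw)
    assert out.pellet_count == state.pellet_count + 1
    with pytest.raises(IntegrationError):
        apply_egestion(OrganismState(gut=cap / 2), P, 1.0)


@pytest.mark.parametrize("compartment", ["gut", "house"])
def test_single_pool_drain_matches_closed_form(compartment):
    """With the input shut off, a lone pool must empty on the implicit
    Michaelis schedule to within 0.1 %."""
    tf = temperature_scale(P.t10, 15.0)
    if compartment == "gut":
        x0 = 0.05
        k, vmax = P.ka, P.a * tf
        state = OrganismState(gut=x0)
        pick = "gut"
    else:
        x0 = 0.1
        k, vmax = P.ki, P.i * tf
        state = OrganismState(hou=x0)
        pick = "hou"
    traj = simulate(Scenario(
        environment=Environment.constant_food(15.0, 0.0, 1.0),
        initial_state=state, duration_days=0.5, renewals_enabled=False,
    ))
    content = getattr(traj, pick)
    x1 = 0.01 * x0
    below = np.nonzero(content < x1)[0][0]
    frac = (content[below - 1] - x1) / (content[below - 1] - content[below])
    t_sim = traj.times[below - 1] + frac * (traj.times[below] - traj.times[below - 1])
    assert t_sim == pytest.approx(michaelis_drain_time(x0, x1, k, vmax), rel=1e-3)


def test_weight_independence_of_efficiencies():
    """Organisms of 0.5, 1 and 4 µgC at identical forcing show identical
    I/F and A/I, and state trajectories that scale exactly as BO**b."""
    runs = {}
    for bo in (0.5, 1.0, 4.0):
        runs[bo] = simulate(Scenario(
            environment=Environment.constant_food(15.0, 100.0, bo),
            n_house_cycles=4))
    ref = runs[1.0]
    ing_eff_ref = ref.final_state.cum_ingested / ref.final_state.cum_filtered
    ass_eff_ref = ref.final_state.cum_assimilated / ref.final_state.cum_ingested
    for bo, traj in runs.items():
        w = bo ** P.b
        fs = traj.final_state
        assert fs.cum_ingested / fs.cum_filtered == pytest.approx(ing_eff_ref, rel=1e-9)
        assert fs.cum_assimilated / fs.cum_ingested == pytest.approx(ass_eff_ref, rel=1e-9)
        # identical sampling grid, exactly scaled states
        np.testing.assert_allclose(traj.hou, ref.hou * w, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(traj.gut, ref.gut * w, rtol=1e-9, atol=1e-12)
        assert traj.n_pellets == ref.n_pellets


def test_interruption_zeroes_filtration_but_not_ingestion():
    t_int = 0.03
    traj = simulate(Scenario(
        environment=Environment.constant_food(15.0, 100.0, 1.0),
        duration_days=0.12, interruption_time_d=t_int))
    after = traj.times > t_int
    assert np.all(traj.F[after] == 0.0)
    # house content keeps feeding the gut for a while
    just_after = after & (traj.times < t_int + 0.01)
    assert np.all(traj.I[just_after] > 0.0)


def test_renewals_can_be_disabled():
    traj = simulate(Scenario(
        environment=Environment.constant_food(15.0, 100.0, 1.0),
        duration_days=0.3, renewals_enabled=False))
    assert traj.renewal_times.size == 0
    assert traj.final_state.det == 0.0


def test_scenario_validation():
    env = Environment.constant_food(15.0, 100.0, 1.0)
    with pytest.raises(ValueError):
        Scenario(environment=env)  # no duration
    with pytest.raises(ValueError):
        Scenario(environment=env, n_house_cycles=4, duration_days=1.0)
    with pytest.raises(ValueError):
        Scenario(environment=env, n_house_cycles=0)
    with pytest.raises(ValueError):
        simulate(Scenario(environment=env, duration_days=0.1,
                          interruption_time_d=0.5))


def test_food_schedule_lookup():
    sched = FoodSchedule([0.0, 0.1, 0.2], [100.0, 50.0, 0.0])
    assert sched.value_at(0.05) == 100.0
    assert sched.value_at(0.1) == 50.0
    assert sched.value_at(0.35) == 0.0
    with pytest.raises(ValueError):
        FoodSchedule([0.1], [5.0])
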