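"""Summary statistics derived from simulated trajectories.

Covers the quantities the model is interrogated for: time-averaged process
rates and the two transfer efficiencies, the house carbon accumulation rate,
the defecation interval (DI) and gut passage time (GPT = DI · nbfp), the
food-concentration threshold below which no pellet is ever produced, and the
apparent half-saturation of a mean rate with respect to the *external* food
concentration (as opposed to the internal substrate the rate laws use).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import Environment, ModelParameters, OrganismState
from .simulate import Scenario, Trajectory, simulate

__all__ = [
    "ProcessSummary",
    "summarize",
    "steady_defecation_interval",
    "accumulation_rate",
    "gut_passage_time",
    "standardize",
    "pellet_onset_concentration",
    "half_saturation_wrt_food",
    "food_sweep",
]

MIN_PER_DAY = 1440.0


@dataclass(frozen=True)
class ProcessSummary:
    """Time-averaged process values over a run (or its final house cycle).

    Rates in µgC d⁻¹; DI and GPT in minutes (NaN when fewer than two
    egestion events occurred — undefined, not zero); pellet rate in h⁻¹.
    """

    mean_F: float
    mean_I: float
    mean_A: float
    ingestion_efficiency: float
    assimilation_efficiency: float
    pellet_rate_per_h: float
    defecation_interval_min: float
    defecation_interval_steady_min: float
    gut_passage_time_min: float
    accumulation_rate: float
    window_days: float


def _window_mean(times: np.ndarray, cum: np.ndarray, ta: float, tb: float) -> float:
    ca, cb = np.interp([ta, tb], times, cum)
    return float((cb - ca) / (tb - ta))


def summarize(trajectory: Trajectory, final_cycle_only: bool = False) -> ProcessSummary:
    """Compute the time-averaged process summary of a trajectory.

    With ``final_cycle_only`` the averaging window is the last complete house
    cycle instead of the whole run; DI/GPT always use the whole run's event
    log (pellet-to-pellet intervals only, which excludes the start-up
    transient from empty initial conditions).
    """
    times = trajectory.times
    t0, t1 = float(times[0]), float(times[-1])
    if final_cycle_only:
        ren = trajectory.renewal_times
        lifespan = trajectory.scenario.lifespan_days
        if ren.size == 0 or (ren[-1] - t0) < lifespan * (1 - 1e-9):
            raise ValueError("trajectory does not contain a complete house cycle")
        t1 = float(ren[-1])
        t0 = t1 - lifespan
    window = t1 - t0

    mean_f = _window_mean(times, trajectory.cum_filtered, t0, t1)
    mean_i = _window_mean(times, trajectory.cum_ingested, t0, t1)
    mean_a = _window_mean(times, trajectory.cum_assimilated, t0, t1)
    ing_eff = mean_i / mean_f if mean_f > 0 else math.nan
    ass_eff = mean_a / mean_i if mean_i > 0 else math.nan

    eg = trajectory.egestion_times
    duration = trajectory.duration
    pellet_rate = eg.size / (duration * 24.0) if duration > 0 else math.nan
    if eg.size >= 2:
        di_min = float(np.mean(np.diff(eg))) * MIN_PER_DAY
        di_steady = steady_defecation_interval(eg, trajectory.renewal_times) * MIN_PER_DAY
    else:
        di_min = math.nan
        di_steady = math.nan
    nbfp = trajectory.scenario.params.nbfp
    gpt_min = gut_passage_time(di_steady, nbfp)
    accum = (accumulation_rate(trajectory)
             if trajectory.renewal_times.size else math.nan)

    return ProcessSummary(
        mean_F=mean_f,
        mean_I=mean_i,
        mean_A=mean_a,
        ingestion_efficiency=ing_eff,
        assimilation_efficiency=ass_eff,
        pellet_rate_per_h=pellet_rate,
        defecation_interval_min=di_min,
        defecation_interval_steady_min=di_steady,
        gut_passage_time_min=gpt_min,
        accumulation_rate=accum,
        window_days=window,
    )


def steady_defecation_interval(egestion_times: np.ndarray,
                               renewal_times: np.ndarray) -> float:
    """Settled pellet cadence (days): mean, over house cycles, of the last
    inter-pellet interval of each cycle.

    Within a house cycle the inter-pellet interval shrinks monotonically
    toward a steady cadence as ingestion recovers from the post-renewal empty
    house; intervals spanning a renewal carry that start-up artefact and are
    excluded, and the last interval completed in each cycle is taken as the
    settled value.  The pellet-production rate this cadence implies is the
    rate at which the curve of pellets-per-hour saturates.  Falls back to the
    plain mean interval when no cycle completes two pellets.
    """
    d = np.diff(egestion_times)
    starts, ends = egestion_times[:-1], egestion_times[1:]
    spans = np.array([
        bool(np.any((renewal_times > a) & (renewal_times < b)))
        for a, b in zip(starts, ends)
    ])
    if np.all(spans):
        return float(np.mean(d))
    boundaries = np.concatenate([renewal_times, [np.inf]])
    cycle_of_end = np.searchsorted(boundaries, ends[~spans], side="right")
    keep_d = d[~spans]
    last_per_cycle = [keep_d[cycle_of_end == c][-1] for c in np.unique(cycle_of_end)]
    return float(np.mean(last_per_cycle))


def accumulation_rate(trajectory: Trajectory) -> float:
    """House carbon accumulation rate (µgC d⁻¹): mean house content at
    discard divided by the house lifespan, averaged over completed cycles.

    Zero when no house was ever filled; requires at least one renewal.
    """
    amounts = trajectory.renewal_amounts
    if amounts.size == 0:
        raise ValueError("trajectory contains no completed house cycle")
    return float(np.mean(amounts) / trajectory.scenario.lifespan_days)


def gut_passage_time(di_min: float, nbfp: float) -> float:
    """Gut passage time (min): defecation interval × mean pellets in gut.

    An undefined (NaN) defecation interval propagates.
    """
    return di_min * nbfp


def standardize(values: Sequence[float], ddof: int = 0) -> np.ndarray:
    """Centre and scale a series to mean 0, standard deviation 1.

    Population SD by default (``ddof=0``).  A constant series has no spread
    and raises ``ValueError``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = arr.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a series with zero spread")
    return (arr - arr.mean()) / sd


def _four_cycle_scenario(p: ModelParameters, temperature_C: float, body_weight: float,
                         fc: float, n_cycles: int = 4, renewal_config=None,
                         record_stride: int = 10) -> Scenario:
    return Scenario(
        environment=Environment.constant_food(temperature_C, fc, body_weight),
        params=p,
        initial_state=OrganismState(),
        n_house_cycles=n_cycles,
        renewal_config=renewal_config,
        record_stride=record_stride,
    )


def pellet_onset_concentration(
    p: ModelParameters, temperature_C: float, body_weight: float,
    fc_grid: Sequence[float], n_cycles: int = 4, renewal_config=None,
) -> Optional[float]:
    """Smallest food concentration in an ascending grid at which at least one
    faecal pellet is egested over ``n_cycles`` house cycles from a zero
    initial state; ``None`` if no grid point produces a pellet."""
    fc_grid = np.asarray(fc_grid, dtype=float)
    if np.any(np.diff(fc_grid) <= 0):
        raise ValueError("fc_grid must be sorted ascending")
    for fc in fc_grid:
        traj = simulate(_four_cycle_scenario(p, temperature_C, body_weight, float(fc),
                                             n_cycles, renewal_config, record_stride=100))
        if traj.n_pellets >= 1:
            return float(fc)
    return None


def half_saturation_wrt_food(fc: Sequence[float], mean_rate: Sequence[float],
                             rtol: float = 1e-3) -> float:
    """Food concentration at which a mean-rate curve reaches half its plateau.

    The plateau is defined as the value at the top of the sweep grid; the
    curve must actually saturate there (be its own maximum within ``rtol``)
    and the half level must be bracketed, otherwise a ``ValueError`` signals
    an insufficient sweep range.  The crossing is located by monotone linear
    interpolation.
    """
    fc = np.asarray(fc, dtype=float)
    rate = np.asarray(mean_rate, dtype=float)
    if fc.size != rate.size or fc.size < 3:
        raise ValueError("need matching fc/rate arrays with >= 3 points")
    if np.any(np.diff(fc) <= 0):
        raise ValueError("fc must be sorted ascending")
    plateau = rate[-1]
    if plateau <= 0 or plateau < rate.max() * (1 - rtol):
        raise ValueError("curve does not saturate within the sweep range")
    if (rate[-1] - rate[-2]) > rtol * abs(plateau):
        raise ValueError("curve is still rising at the top of the sweep range")
    half = plateau / 2.0
    idx = np.nonzero(rate >= half)[0]
    if idx.size == 0 or idx[0] == 0:
        raise ValueError("half-plateau level is not bracketed by the sweep")
    j = idx[0]
    return float(np.interp(half, rate[j - 1:j + 1], fc[j - 1:j + 1]))


def food_sweep(
    p: ModelParameters, temperature_C: float, body_weight: float,
    fc_grid: Sequence[float], n_cycles: int = 4, renewal_config=None,
) -> pd.DataFrame:
    """Run a four-cycle simulation at each food concentration and tabulate
    the process summary (one row per concentration)."""
    rows = []
    for fc in np.asarray(fc_grid, dtype=float):
        traj = simulate(_four_cycle_scenario(p, temperature_C, body_weight, float(fc),
                                             n_cycles, renewal_config))
        s = summarize(traj)
        rows.append({
            "FC": fc,
            "mean_F": s.mean_F,
            "mean_I": s.mean_I,
            "mean_A": s.mean_A,
            "ingestion_efficiency": s.ingestion_efficiency,
            "assimilation_efficiency": s.assimilation_efficiency,
            "pellet_rate_per_h": s.pellet_rate_per_h,
            "DI_min": s.defecation_interval_min,
            "DI_steady_min": s.defecation_interval_steady_min,
            "GPT_min": s.gut_passage_time_min,
            "accumulation_rate": s.accumulation_rate,
        })
    return pd.DataFrame(rows)
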