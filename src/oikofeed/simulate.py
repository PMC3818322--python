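"""Event-driven simulation of the coupled house/gut dynamics.

A scenario fixes the forcing (temperature, piecewise-constant food, body
weight), the parameter set and a duration, expressed either in days or in
house cycles.  House renewals fire deterministically at every multiple of the
temperature-dependent house lifespan; egestion fires whenever the gut content
reaches its capacity.  The integrator is a fixed-step explicit 4th-order
scheme (step ≤ 1e-4 d ≈ 8.6 s) with egestion crossings located by bisection
within the step: the dynamics are smooth between events, so no stiff solver
is needed, but accurate event placement matters for the defecation-interval
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import DT_MAX, EV_EGESTION, EV_RENEWAL, REC_COLUMNS, run_kernel
from .parameters import Environment, FoodSchedule, ModelParameters, OrganismState
from .rates import (
    allometric_scale,
    faecal_pellet_weight,
    gut_capacity,
    temperature_scale,
)
from .renewal import HOURS_PER_DAY, house_lifespan

__all__ = [
    "Scenario",
    "Trajectory",
    "IntegrationError",
    "simulate",
    "apply_house_renewal",
    "apply_egestion",
]

#: Tolerance (µgC, relative to capacity) accepted when an egestion helper is
#: invoked below capacity.
EVENT_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when event detection or buffer bookkeeping fails."""


@dataclass
class Scenario:
    """A single simulation protocol.

    Exactly one of ``n_house_cycles`` / ``duration_days`` must be given.
    ``interruption_time_d`` zeroes the food from that instant on (alimentary
    interruption), on top of whatever schedule the environment carries.
    ``renewals_enabled=False`` suppresses scheduled house renewals, for
    single-cycle starvation protocols.
    """

    environment: Environment
    params: ModelParameters = field(default_factory=ModelParameters)
    initial_state: OrganismState = field(default_factory=OrganismState)
    n_house_cycles: Optional[int] = None
    duration_days: Optional[float] = None
    interruption_time_d: Optional[float] = None
    record_stride: int = 1
    renewal_config: object = None
    renewals_enabled: bool = True
    dt_max: float = DT_MAX

    def __post_init__(self) -> None:
        if (self.n_house_cycles is None) == (self.duration_days is None):
            raise ValueError("specify exactly one of n_house_cycles or duration_days")
        if self.n_house_cycles is not None and self.n_house_cycles <= 0:
            raise ValueError("n_house_cycles must be positive")
        if self.duration_days is not None and self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.dt_max <= 0 or self.dt_max > 1e-3:
            raise ValueError("dt_max must be in (0, 1e-3] days")

    @property
    def lifespan_days(self) -> float:
        return house_lifespan(self.environment.temperature_C, self.renewal_config) / HOURS_PER_DAY

    @property
    def total_days(self) -> float:
        if self.duration_days is not None:
            return float(self.duration_days)
        return self.n_house_cycles * self.lifespan_days


@dataclass
class Trajectory:
    """Sampled states, instantaneous rates and the discrete-event log."""

    times: np.ndarray          # days
    F: np.ndarray              # µgC d⁻¹
    I: np.ndarray
    A: np.ndarray
    hou: np.ndarray            # µgC
    gut: np.ndarray
    det: np.ndarray
    fec: np.ndarray
    cum_filtered: np.ndarray
    cum_ingested: np.ndarray
    cum_assimilated: np.ndarray
    event_times: np.ndarray
    event_kinds: np.ndarray    # "house_renewal" | "egestion"
    event_carbon: np.ndarray
    scenario: Scenario
    final_state: OrganismState

    @property
    def renewal_times(self) -> np.ndarray:
        return self.event_times[self.event_kinds == "house_renewal"]

    @property
    def renewal_amounts(self) -> np.ndarray:
        return self.event_carbon[self.event_kinds == "house_renewal"]

    @property
    def egestion_times(self) -> np.ndarray:
        return self.event_times[self.event_kinds == "egestion"]

    @property
    def n_pellets(self) -> int:
        return int(np.count_nonzero(self.event_kinds == "egestion"))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def mass_balance_error(self) -> float:
        """Maximum relative carbon-balance defect over all samples.

        Filtered carbon since the start of the run must equal the growth of
        house + detritus + gut + faeces + assimilated carbon over the same
        span (the initial state may carry mass).
        """
        lhs = self.cum_filtered - self.cum_filtered[0]
        total = self.hou + self.det + self.gut + self.fec + self.cum_assimilated
        rhs = total - total[0]
        scale = np.maximum(np.maximum(np.abs(lhs), total[0]), 1.0)
        return float(np.max(np.abs(lhs - rhs) / scale))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_d": self.times,
            "F": self.F,
            "I": self.I,
            "A": self.A,
            "HOU": self.hou,
            "GUT": self.gut,
            "DET": self.det,
            "FEC": self.fec,
        })

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_d": self.event_times,
            "kind": self.event_kinds,
            "carbon_ugC": self.event_carbon,
        })


def apply_house_renewal(state: OrganismState) -> OrganismState:
    """Discard the current house: its content moves to the detritus pool,
    the new house starts empty, the gut is untouched."""
    out = state.copy()
    out.det += out.hou
    out.hou = 0.0
    out.house_age = 0.0
    return out


def apply_egestion(state: OrganismState, p: ModelParameters, body_weight: float) -> OrganismState:
    """Egest one faecal pellet from a full gut.

    Requires the gut to be at capacity (within event tolerance); capacity
    minus one pellet weight is strictly positive for any valid parameters, so
    a single subtraction always suffices.
    """
    cap = gut_capacity(p, body_weight)
    fpw = faecal_pellet_weight(p, body_weight)
    if state.gut < cap * (1.0 - EVENT_TOL) - EVENT_TOL:
        raise IntegrationError(
            f"egestion invoked with gut={state.gut} below capacity {cap}"
        )
    out = state.copy()
    out.gut -= fpw
    out.fec += fpw
    out.pellet_count += 1
    return out


def _effective_schedule(scenario: Scenario) -> FoodSchedule:
    sched = scenario.environment.food
    t_int = scenario.interruption_time_d
    if t_int is None:
        return sched
    if not (0.0 < t_int <= scenario.total_days):
        raise ValueError("interruption_time_d must fall inside the run")
    keep = sched.times < t_int
    return FoodSchedule(
        np.append(sched.times[keep], t_int),
        np.append(sched.values[keep], 0.0),
    )


def simulate(scenario: Scenario) -> Trajectory:
    """Run one scenario and return its trajectory.

    Raises :class:`IntegrationError` on event-buffer overflow rather than
    silently truncating.
    """
    env = scenario.environment
    p = scenario.params
    t_end = scenario.total_days
    lifespan = scenario.lifespan_days

    w = allometric_scale(env.body_weight, p.b)
    tf = temperature_scale(p.t10, env.temperature_C)
    imax = p.i * w * tf
    ki = p.ki * w
    amax = p.a * w * tf
    ka = p.ka * w
    cap = gut_capacity(p, env.body_weight)
    fpw = faecal_pellet_weight(p, env.body_weight)

    sched = _effective_schedule(scenario)

    # segment boundaries: run edges, schedule breaks, scheduled renewals
    boundaries = {0.0, t_end}
    boundaries.update(float(t) for t in sched.times if 0.0 < t < t_end)
    renewal_set: set[float] = set()
    if scenario.renewals_enabled:
        k = 1
        while k * lifespan <= t_end * (1 + 1e-12):
            renewal_set.add(min(k * lifespan, t_end))
            k += 1
    boundaries.update(rt for rt in renewal_set if rt < t_end)
    seg_t = np.array(sorted(boundaries))
    nseg = seg_t.size - 1
    renew_flag = np.zeros(seg_t.size, dtype=np.int64)
    for j, bt in enumerate(seg_t):
        if any(abs(bt - rt) <= 1e-12 for rt in renewal_set):
            renew_flag[j] = 1

    fmax = p.f * w * tf
    seg_fc = np.array([
        fmax * sched.value_at(0.5 * (seg_t[j] + seg_t[j + 1])) /
        (p.kf + sched.value_at(0.5 * (seg_t[j] + seg_t[j + 1])))
        for j in range(nseg)
    ])

    n_steps = int(np.ceil(t_end / scenario.dt_max)) + 2 * nseg + 4
    n_ev_max = int(t_end * imax / fpw * 1.5) + len(renewal_set) + 64
    n_rec_max = n_steps // scenario.record_stride + nseg * 4 + n_ev_max + 16
    rec = np.empty((n_rec_max, len(REC_COLUMNS)))
    ev_t = np.empty(n_ev_max)
    ev_kind = np.empty(n_ev_max, dtype=np.int64)
    ev_amt = np.empty(n_ev_max)

    s0 = scenario.initial_state
    status, n_rec, n_ev, hou, gut, det, fec, cumf, cumi, cuma, npel = run_kernel(
        seg_t, seg_fc, renew_flag, scenario.dt_max,
        imax, ki, amax, ka, cap, fpw,
        s0.hou, s0.gut, s0.det, s0.fec,
        s0.cum_filtered, s0.cum_ingested, s0.cum_assimilated,
        scenario.record_stride, rec, ev_t, ev_kind, ev_amt,
    )
    if status != 0:
        raise IntegrationError(f"integration buffers exhausted (status={status})")

    rec = rec[:n_rec]
    kinds = np.where(ev_kind[:n_ev] == EV_RENEWAL, "house_renewal", "egestion")
    last_renewal = 0.0
    ren = ev_t[:n_ev][ev_kind[:n_ev] == EV_RENEWAL]
    if ren.size:
        last_renewal = float(ren[-1])
    final = OrganismState(
        time=t_end, hou=hou, gut=gut, det=det, fec=fec,
        house_age=t_end - last_renewal,
        cum_filtered=cumf, cum_ingested=cumi, cum_assimilated=cuma,
        pellet_count=s0.pellet_count + int(npel),
    )
    return Trajectory(
        times=rec[:, 0].copy(), F=rec[:, 1].copy(), I=rec[:, 2].copy(),
        A=rec[:, 3].copy(), hou=rec[:, 4].copy(), gut=rec[:, 5].copy(),
        det=rec[:, 6].copy(), fec=rec[:, 7].copy(),
        cum_filtered=rec[:, 8].copy(), cum_ingested=rec[:, 9].copy(),
        cum_assimilated=rec[:, 10].copy(),
        event_times=ev_t[:n_ev].copy(), event_kinds=kinds,
        event_carbon=ev_amt[:n_ev].copy(),
        scenario=scenario, final_state=final,
    )
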