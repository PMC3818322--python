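"""Parameter, forcing and state containers for the appendicularian feeding model.

The model tracks carbon through four pools around an individual *Oikopleura
dioica*: the food concentration of the surrounding water, the contents of the
self-built filtering house, the gut, and two cumulative sinks (discarded
houses and faecal pellets).  All masses are micrograms of carbon (µgC), all
times are days, all rates µgC d⁻¹; hours and minutes only appear at reporting
interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "DEFAULT_PARAMETERS",
    "HIGH_FPP_PARAMETERS",
    "FoodSchedule",
    "Environment",
    "OrganismState",
    "InvalidOrganismError",
    "InvalidForcingError",
    "InvalidStateError",
]


class InvalidOrganismError(ValueError):
    """Raised for a nonpositive body weight."""


class InvalidForcingError(ValueError):
    """Raised for invalid environmental forcing (e.g. negative food)."""


class InvalidStateError(ValueError):
    """Raised for an inconsistent organism state (e.g. negative gut content)."""


@dataclass(frozen=True)
class ModelParameters:
    """The ten constants of the feeding model.

    Parameters
    ----------
    f : float
        Maximum food intake for filtration at 0 °C (µgC µgC⁻ᵇ d⁻¹).
    kf : float
        Half-saturation constant for filtration w.r.t. the external food
        concentration (µgC l⁻¹).
    b : float
        Exponent of the allometric body-weight scaling (dimensionless).
    t10 : float
        Tenth root of the Q10 temperature coefficient (dimensionless); every
        rate is multiplied by ``t10**T`` at temperature ``T`` °C.
    i : float
        Maximum food intake for ingestion at 0 °C (µgC µgC⁻ᵇ d⁻¹).
    ki : float
        Half-saturation constant for ingestion w.r.t. the house content,
        expressed per unit of allometric weight (µgC µgC⁻ᵇ).
    a : float
        Maximum food intake for assimilation at 0 °C (µgC µgC⁻ᵇ d⁻¹).
    ka : float
        Half-saturation constant for assimilation w.r.t. the gut content
        (µgC µgC⁻ᵇ).
    fpp : float
        Faecal-pellet size proportion: one pellet weighs ``fpp * BO**b`` µgC.
    nbfp : float
        Mean number of faecal pellets resident in the gut; the gut capacity
        is ``nbfp * fpp * BO**b``.
    """

    f: float = 3.7
    kf: float = 150.0
    b: float = 0.9
    t10: float = 1.06
    i: float = 1.2232
    ki: float = 0.0282
    a: float = 0.4818
    ka: float = 0.0029
    fpp: float = 0.0175
    nbfp: float = 3.368

    def __post_init__(self) -> None:
        for fld in fields(self):
            value = getattr(self, fld.name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {fld.name!r} must be finite and > 0, got {value}")
        if not self.a < self.i:
            raise ValueError(f"assimilation maximum a={self.a} must be below ingestion maximum i={self.i}")
        if not self.ka < self.ki:
            raise ValueError(f"assimilation half-saturation ka={self.ka} must be below ki={self.ki}")
        if not self.nbfp > 1:
            raise ValueError(f"nbfp must exceed 1 (gut holds more than one pellet), got {self.nbfp}")
        if not self.t10 > 1:
            raise ValueError(f"t10 must exceed 1 (rates increase with temperature), got {self.t10}")

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {fld.name: float(getattr(self, fld.name)) for fld in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        known = {fld.name for fld in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


#: Canonical calibrated parameter set.
DEFAULT_PARAMETERS = ModelParameters()

#: Alternative preset with the pellet proportion re-estimated from in-situ gut
#: volumes (fpp = 0.03 instead of 0.0175); gives a gut capacity near 0.10 µgC
#: for a 1 µgC organism.
HIGH_FPP_PARAMETERS = ModelParameters(fpp=0.03)


class FoodSchedule:
    """Piecewise-constant external food concentration (µgC l⁻¹) over time (d).

    ``times`` are the left edges of the constant segments; ``times[0]`` must be
    0.  ``value_at(t)`` returns the concentration of the segment containing
    ``t``.
    """

    def __init__(self, times, values):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or times.size == 0:
            raise ValueError("times and values must be equal-length 1-d arrays")
        if times[0] != 0.0:
            raise ValueError("the food schedule must start at time 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("schedule breakpoints must be strictly increasing")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise InvalidForcingError("food concentrations must be finite and >= 0")
        self.times = times
        self.values = values

    @classmethod
    def constant(cls, fc: float) -> "FoodSchedule":
        return cls([0.0], [fc])

    @classmethod
    def step_to_zero(cls, fc0: float, interruption_time: float) -> "FoodSchedule":
        """Constant ``fc0`` until ``interruption_time`` (d), zero afterwards."""
        if interruption_time <= 0:
            return cls.constant(0.0)
        return cls([0.0, float(interruption_time)], [fc0, 0.0])

    def value_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.values[max(idx, 0)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FoodSchedule)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        pairs = ", ".join(f"{t:g}d->{v:g}" for t, v in zip(self.times, self.values))
        return f"FoodSchedule({pairs})"


@dataclass(frozen=True)
class Environment:
    """Forcing variables: temperature (°C), food schedule, body weight (µgC).

    The body weight is a forcing constant within a run; the model has no
    growth feedback.
    """

    temperature_C: float
    food: FoodSchedule
    body_weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature_C):
            raise InvalidForcingError("temperature must be finite")
        if not (np.isfinite(self.body_weight) and self.body_weight > 0):
            raise InvalidOrganismError(f"body weight must be > 0, got {self.body_weight}")

    @classmethod
    def constant_food(cls, temperature_C: float, fc: float, body_weight: float) -> "Environment":
        return cls(temperature_C, FoodSchedule.constant(fc), body_weight)


@dataclass
class OrganismState:
    """Instantaneous state of the individual.

    ``hou`` and ``gut`` are the two state variables (house and gut carbon);
    ``det`` and ``fec`` are the cumulative diagnostic sinks (discarded-house
    and faecal carbon); ``cum_filtered``/``cum_ingested``/``cum_assimilated``
    are running time-integrals of the three fluxes used for mass balance and
    time-averaged rates.
    """

    time: float = 0.0
    hou: float = 0.0
    gut: float = 0.0
    det: float = 0.0
    fec: float = 0.0
    house_age: float = 0.0
    cum_filtered: float = 0.0
    cum_ingested: float = 0.0
    cum_assimilated: float = 0.0
    pellet_count: int = 0

    def __post_init__(self) -> None:
        for name in ("hou", "gut", "det", "fec", "cum_filtered", "cum_ingested", "cum_assimilated"):
            if getattr(self, name) < 0:
                raise InvalidStateError(f"{name} must be >= 0, got {getattr(self, name)}")

    def copy(self) -> "OrganismState":
        return OrganismState(**{f.name: getattr(self, f.name) for f in fields(self)})
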