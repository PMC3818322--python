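"""House-renewal (house lifespan) configuration.

The organism periodically abandons its filtering house and deploys a fresh,
empty one.  The renewal interval shortens with temperature; the underlying
empirical regression (measured at salinity 30) is not reproduced here, so
the lifespan is a pluggable configuration.  The shipped default is a
nearest-anchor lookup table pinned to the well-established value of 2.91 h
at 15 °C, extended to 10 °C and 20 °C with a Q10 ≈ 2 decline — an anchored
approximation adequate for the 10–20 °C range the model is exercised over.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

__all__ = ["RenewalConfigurationError", "HouseRenewalTable", "DEFAULT_RENEWAL", "house_lifespan"]

HOURS_PER_DAY = 24.0


class RenewalConfigurationError(ValueError):
    """Raised when a lifespan is requested outside the configured range."""


class HouseRenewalTable:
    """Flat-per-temperature house lifespan: nearest configured anchor wins.

    Parameters
    ----------
    anchors : mapping of temperature (°C) to lifespan (hours)
        Must be strictly positive lifespans, nonincreasing with temperature.
    margin_C : float
        Half-width of the validity band around the extreme anchors; a
        temperature outside ``[min-margin, max+margin]`` raises
        :class:`RenewalConfigurationError`.
    """

    def __init__(self, anchors: Mapping[float, float], margin_C: float = 2.5):
        items = sorted((float(t), float(h)) for t, h in anchors.items())
        if not items:
            raise ValueError("at least one anchor is required")
        temps = np.array([t for t, _ in items])
        hours = np.array([h for _, h in items])
        if np.any(hours <= 0):
            raise ValueError("lifespans must be > 0")
        if np.any(np.diff(hours) > 0):
            raise ValueError("lifespan must be nonincreasing with temperature")
        self.temps = temps
        self.hours = hours
        self.margin_C = float(margin_C)

    def lifespan_hours(self, temperature_C: float) -> float:
        lo = self.temps[0] - self.margin_C
        hi = self.temps[-1] + self.margin_C
        if not (lo <= temperature_C <= hi):
            raise RenewalConfigurationError(
                f"temperature {temperature_C} °C outside configured renewal range [{lo}, {hi}] °C"
            )
        idx = int(np.argmin(np.abs(self.temps - temperature_C)))
        return float(self.hours[idx])

    def lifespan_days(self, temperature_C: float) -> float:
        return self.lifespan_hours(temperature_C) / HOURS_PER_DAY

    def to_dict(self) -> dict:
        return {
            "anchors": {float(t): float(h) for t, h in zip(self.temps, self.hours)},
            "margin_C": self.margin_C,
        }

    @classmethod
    def from_config(cls, obj) -> "HouseRenewalTable":
        if isinstance(obj, HouseRenewalTable):
            return obj
        if isinstance(obj, Mapping) and "anchors" in obj:
            return cls({float(t): float(h) for t, h in obj["anchors"].items()},
                       margin_C=float(obj.get("margin_C", 2.5)))
        if isinstance(obj, Mapping):
            return cls({float(t): float(h) for t, h in obj.items()})
        raise TypeError(f"cannot build a renewal table from {type(obj).__name__}")


#: Default lifespan table: 2.91 h at 15 °C (anchor), Q10≈2 extension.
DEFAULT_RENEWAL = HouseRenewalTable({10.0: 4.12, 15.0: 2.91, 20.0: 2.06})


def house_lifespan(
    temperature_C: float,
    renewal_config: HouseRenewalTable | Callable[[float], float] | None = None,
) -> float:
    """House replacement interval in **hours** at ``temperature_C``.

    ``renewal_config`` may be a :class:`HouseRenewalTable`, a callable
    ``T -> hours``, or ``None`` for the shipped default.
    """
    if renewal_config is None:
        renewal_config = DEFAULT_RENEWAL
    if callable(renewal_config) and not isinstance(renewal_config, HouseRenewalTable):
        value = float(renewal_config(temperature_C))
        if value <= 0:
            raise RenewalConfigurationError(f"configured lifespan must be > 0, got {value}")
        return value
    return HouseRenewalTable.from_config(renewal_config).lifespan_hours(temperature_C)
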