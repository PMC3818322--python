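"""Instantaneous process rates of the feeding model.

Each of the three fluxes — filtration (water → house), ingestion
(house → gut) and assimilation (gut → tissue) — is a Michaelis–Menten
function of its substrate, scaled allometrically by the body weight
(``BO**b``) and exponentially by temperature (``t10**T``):

    F = f · BO^b · t10^T · FC / (kf + FC)
    I = i · BO^b · t10^T · HOU / (ki·BO^b + HOU)
    A = a · BO^b · t10^T · GUT / (ka·BO^b + GUT)

The ingestion and assimilation half-saturations scale with ``BO**b`` so that
the ingestion efficiency (I/F) and assimilation efficiency (A/I) are strictly
independent of body weight.  The two discrete-event quantities — the weight
of one faecal pellet and the gut capacity that triggers egestion — share the
same allometric scaling.
"""

from __future__ import annotations

from .parameters import (
    InvalidForcingError,
    InvalidOrganismError,
    InvalidStateError,
    ModelParameters,
)

__all__ = [
    "temperature_scale",
    "allometric_scale",
    "filtration_rate",
    "ingestion_rate",
    "assimilation_rate",
    "faecal_pellet_weight",
    "gut_capacity",
]


def temperature_scale(t10: float, temperature_C: float) -> float:
    """Multiplicative temperature factor ``t10**T`` (Q10 = t10**10).

    Negative temperatures are allowed and simply yield a factor below 1.
    """
    if t10 <= 0:
        raise ValueError(f"t10 must be > 0, got {t10}")
    return t10 ** temperature_C


def allometric_scale(body_weight: float, b: float) -> float:
    """Allometric body-weight factor ``BO**b``."""
    if body_weight <= 0:
        raise InvalidOrganismError(f"body weight must be > 0, got {body_weight}")
    return body_weight ** b


def filtration_rate(p: ModelParameters, body_weight: float, temperature_C: float, fc: float) -> float:
    """Filtration flux from the water into the house (µgC d⁻¹).

    Saturates in the external food concentration ``fc`` (µgC l⁻¹) with
    half-saturation ``kf``.
    """
    if fc < 0:
        raise InvalidForcingError(f"food concentration must be >= 0, got {fc}")
    scale = allometric_scale(body_weight, p.b) * temperature_scale(p.t10, temperature_C)
    return p.f * scale * fc / (p.kf + fc)


def ingestion_rate(p: ModelParameters, body_weight: float, temperature_C: float, hou: float) -> float:
    """Ingestion flux from the house content into the gut (µgC d⁻¹).

    Saturates in the house carbon content ``hou`` with weight-scaled
    half-saturation ``ki·BO**b``.
    """
    if hou < 0:
        raise InvalidStateError(f"house content must be >= 0, got {hou}")
    w = allometric_scale(body_weight, p.b)
    return p.i * w * temperature_scale(p.t10, temperature_C) * hou / (p.ki * w + hou)


def assimilation_rate(p: ModelParameters, body_weight: float, temperature_C: float, gut: float) -> float:
    """Assimilation flux from the gut content into the organism (µgC d⁻¹).

    Saturates in the gut carbon content ``gut`` with weight-scaled
    half-saturation ``ka·BO**b``.
    """
    if gut < 0:
        raise InvalidStateError(f"gut content must be >= 0, got {gut}")
    w = allometric_scale(body_weight, p.b)
    return p.a * w * temperature_scale(p.t10, temperature_C) * gut / (p.ka * w + gut)


def faecal_pellet_weight(p: ModelParameters, body_weight: float) -> float:
    """Carbon weight of one faecal pellet, ``fpp·BO**b`` (µgC)."""
    return p.fpp * allometric_scale(body_weight, p.b)


def gut_capacity(p: ModelParameters, body_weight: float) -> float:
    """Maximum gut content before a pellet is egested, ``nbfp·fpp·BO**b`` (µgC)."""
    return p.nbfp * faecal_pellet_weight(p, body_weight)
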