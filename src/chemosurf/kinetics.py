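"""Fertilization kinetics and the ballistic strong-flow limit.

Experiments report the fraction of fertilized eggs P_fert, not the
per-sperm encounter probability.  With sperm and egg densities rho_sperm
and rho_egg, the number of sperm encountering a given egg is Poisson with
mean P_sperm:egg * rho_sperm / rho_egg, and each encounter fertilizes with
probability p_f (the fertilizability), so

    P_fert = 1 - exp( - p_f * P_sperm:egg * rho_sperm / rho_egg ).

A maximum of P_sperm:egg(alpha) therefore maps to a maximum of
P_fert(alpha) at the same alpha; sperm density only scales the amplitude.

Without chemotaxis a swimmer of speed v_h sweeps egg volume at rate
q = pi r_egg^2 v_h rho_egg, giving P_sperm:egg(t) = 1 - exp(-q t).  In very
strong flow this encounter rate collapses: only sperm within a boundary
layer delta ~ 0.1 r_egg of the egg can reach it, and they must traverse
delta within the half-rotation time 2 pi / alpha of the egg, which fails
above the characteristic shear rate alpha ~ 2 pi v_h / delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticsParams",
    "fertilization_probability",
    "ballistic_encounter",
    "strong_flow_drop_scale",
    "background_concentration_estimate",
]


@dataclass
class KineticsParams:
    """Fertilizability and gamete densities."""

    p_f: float
    rho_sperm: float
    rho_egg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_f <= 1.0:
            raise ValueError("p_f must be a probability")
        if self.rho_sperm < 0 or self.rho_egg < 0:
            raise ValueError("densities must be >= 0")


def fertilization_probability(P_enc: float | np.ndarray, kp: KineticsParams):
    """P_fert = 1 - exp(-p_f P_enc rho_sperm / rho_egg)."""
    P_enc = np.asarray(P_enc, dtype=float)
    if np.any((P_enc < 0) | (P_enc > 1)):
        raise ValueError("P_enc must be in [0, 1]")
    if kp.rho_egg == 0:
        raise ValueError("rho_egg must be > 0")
    out = 1.0 - np.exp(-kp.p_f * P_enc * kp.rho_sperm / kp.rho_egg)
    return float(out) if out.ndim == 0 else out


def ballistic_encounter(
    t: float | np.ndarray, v_h: float, r_egg: float, rho_egg: float
):
    """Encounter probability of a ballistic swimmer in still water,
    1 - exp(-q t) with swept-volume rate q = pi r_egg^2 v_h rho_egg."""
    q = np.pi * r_egg**2 * v_h * rho_egg
    out = 1.0 - np.exp(-q * np.asarray(t, dtype=float))
    return float(out) if out.ndim == 0 else out


def strong_flow_drop_scale(v_h: float, r_egg: float, delta_frac: float = 0.1) -> float:
    """Characteristic shear rate 2 pi v_h / (delta_frac * r_egg) above which
    the ballistic encounter rate collapses."""
    if v_h <= 0 or r_egg <= 0 or delta_frac <= 0:
        raise ValueError("inputs must be > 0")
    return 2.0 * np.pi * v_h / (delta_frac * r_egg)


def background_concentration_estimate(
    Qdot: float, rho_egg: float, t_prep: float
) -> float:
    """Well-mixed accumulated background c_bg = Qdot * t_prep * rho_egg
    (degradation neglected; an order-of-magnitude estimate)."""
    if Qdot < 0 or rho_egg < 0 or t_prep < 0:
        raise ValueError("inputs must be >= 0")
    return Qdot * t_prep * rho_egg
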