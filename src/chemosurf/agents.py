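"""Equations of motion for individual sperm cells.

The helical swimming path is coarse-grained to its axis ``h``: the cell swims
with speed ``v_h`` along ``h`` while being advected by the external flow, and
a chemotactic signalling response rotates ``h`` towards the local
concentration gradient at a rate proportional to the adaptively normalised
gradient |grad c| / (c + c_b),

    h_dot = v_phi / (c + c_b) * (I - h h^T) . grad c ,

equivalent to ``Psi_dot = -v_phi |grad c| sin(Psi) / (c + c_b)`` for the angle
Psi between gradient and axis.  Co-rotation by the flow adds the Jeffery term
for an effective prolate aspect ratio ``g``.

The integrator is an explicit midpoint (RK2) step with renormalisation of
``h``; the helix itself can be decorated back onto the axis trajectory with
`helical_overlay` for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .flow import ShearFlow, SphereDisturbance, jeffery_rate, velocity_gradient, total_velocity

__all__ = ["ChemotaxisParams", "SpermState", "alignment_rate", "step", "helical_overlay"]


@dataclass
class ChemotaxisParams:
    """Chemotaxis and swimming parameters of a sperm cell.

    v_h : helix-axis swimming speed, m/s.
    v_phi : effective chemotactic response parameter (alignment rate scale), m/s.
    c_b : sensory adaptation threshold, mol/m^3.
    r0 : helix radius, m (visualisation only; the axis model samples the
        concentration at the centreline).
    g : effective hydrodynamic aspect ratio for Jeffery co-rotation.
    """

    v_h: float
    v_phi: float
    c_b: float
    r0: float = 7e-6
    g: float = 5.0
    chemotaxis_on: bool = True
    corotation_on: bool = True

    def __post_init__(self) -> None:
        if self.v_h <= 0:
            raise ValueError("v_h must be > 0")
        if self.v_phi < 0 or self.c_b <= 0 or self.r0 < 0:
            raise ValueError("require v_phi >= 0, c_b > 0, r0 >= 0")
        if self.g < 1:
            raise ValueError("aspect ratio g must be >= 1")


@dataclass
class SpermState:
    """State of one sperm cell: position, helix axis, clock, status."""

    r: np.ndarray
    h: np.ndarray
    t: float = 0.0
    status: str = "swimming"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = np.linalg.norm(self.h)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("|h| must be 1 +- 1e-9")


def alignment_rate(
    h: np.ndarray, c: np.ndarray, grad_c: np.ndarray, params: ChemotaxisParams
) -> np.ndarray:
    """Chemotactic rotation rate of the helix axis (perpendicular to h)."""
    h = np.asarray(h, dtype=float)
    grad_c = np.asarray(grad_c, dtype=float)
    c = np.asarray(c, dtype=float)
    pref = params.v_phi / (c + params.c_b)
    h_dot_g = np.einsum("...i,...i->...", h, grad_c)
    return pref[..., None] * (grad_c - h_dot_g[..., None] * h)


def _clamped(r: np.ndarray, r_egg: float) -> np.ndarray:
    """Positions with radius clamped to the egg surface (for field/velocity
    evaluation during a step that dips inside the egg)."""
    rn = np.linalg.norm(r, axis=-1, keepdims=True)
    scale = np.maximum(rn, r_egg) / np.where(rn > 0, rn, 1.0)
    return r * scale


def derivatives(
    r: np.ndarray,
    h: np.ndarray,
    flow: ShearFlow,
    sphere: SphereDisturbance | None,
    field,
    params: ChemotaxisParams,
    t: float = 0.0,
):
    """(r_dot, h_dot) for an array of agents; vectorised over leading axes."""
    r_eval = _clamped(r, sphere.r_egg) if sphere is not None and sphere.enabled else r
    v = total_velocity(r_eval, flow, sphere, t)
    rdot = params.v_h * h + v
    hdot = np.zeros_like(h)
    if params.chemotaxis_on and field is not None:
        c, grad = field.evaluate(r_eval)
        hdot = hdot + alignment_rate(h, c, grad, params)
    if params.corotation_on:
        grad_v = velocity_gradient(r_eval, flow, sphere, t)
        hdot = hdot + jeffery_rate(h, grad_v, params.g)
    return rdot, hdot


def step_arrays(
    r: np.ndarray,
    h: np.ndarray,
    dt: np.ndarray | float,
    flow: ShearFlow,
    sphere: SphereDisturbance | None,
    field,
    params: ChemotaxisParams,
    t: float = 0.0,
):
    """One explicit-midpoint step for arrays of agents; returns (r_new, h_new).

    ``dt`` may be scalar or per-agent.  ``h`` is renormalised after the step.
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("dt must be > 0")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(h))):
        raise ValueError("non-finite agent state")
    dt_ = dt[..., None] if dt.ndim else dt
    k1r, k1h = derivatives(r, h, flow, sphere, field, params, t)
    hm = h + 0.5 * dt_ * k1h
    hm /= np.linalg.norm(hm, axis=-1, keepdims=True)
    rm = r + 0.5 * dt_ * k1r
    k2r, k2h = derivatives(rm, hm, flow, sphere, field, params, t)
    r_new = r + dt_ * k2r
    h_new = h + dt_ * k2h
    h_new /= np.linalg.norm(h_new, axis=-1, keepdims=True)
    return r_new, h_new


def step(
    state: SpermState,
    dt: float,
    flow: ShearFlow,
    sphere: SphereDisturbance | None = None,
    field=None,
    params: ChemotaxisParams | None = None,
    r_max: float | None = None,
) -> SpermState:
    """Advance a single sperm cell by one time step.

    Capture (crossing of the egg surface, detected with sub-step linear
    interpolation of the trajectory segment) sets status 'captured';
    crossing ``r_max`` sets status 'exited'.
    """
    if params is None:
        raise ValueError("params required")
    if state.status != "swimming":
        return state
    r_new, h_new = step_arrays(
        state.r[None], state.h[None], dt, flow, sphere, field, params, state.t
    )
    r_new, h_new = r_new[0], h_new[0]
    status = "swimming"
    t_new = state.t + dt
    if sphere is not None and sphere.enabled:
        frac = segment_capture_fraction(
            state.r[None], r_new[None], sphere.r_egg
        )[0]
        if frac >= 0:
            status = "captured"
            t_new = state.t + frac * dt
            r_new = state.r + frac * (r_new - state.r)
    if status == "swimming" and r_max is not None and np.linalg.norm(r_new) >= r_max:
        status = "exited"
    return SpermState(r=r_new, h=h_new, t=t_new, status=status)


def segment_capture_fraction(
    r0: np.ndarray, r1: np.ndarray, r_egg: float
) -> np.ndarray:
    """Earliest fraction s in [0, 1] at which the segment r0 -> r1 crosses
    |r| = r_egg, or -1 if it does not (linear sub-step interpolation, which
    prevents tunnelling through the egg at finite dt)."""
    d = r1 - r0
    a = np.einsum("...i,...i->...", d, d)
    b = 2.0 * np.einsum("...i,...i->...", r0, d)
    c = np.einsum("...i,...i->...", r0, r0) - r_egg**2
    out = np.full(np.shape(a), -1.0)
    inside = c <= 0  # started on/inside the egg
    out[inside] = 0.0
    disc = b**2 - 4 * a * c
    ok = (~inside) & (disc >= 0) & (a > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    s1 = (-b - sq) / np.where(a > 0, 2 * a, 1.0)
    hit = ok & (s1 >= 0.0) & (s1 <= 1.0)
    out[hit] = s1[hit]
    return out


def helical_overlay(
    positions: np.ndarray,
    h: np.ndarray,
    params: ChemotaxisParams,
    times: np.ndarray,
    omega: float = 2.0 * np.pi,
) -> np.ndarray:
    """Decorate a coarse-grained centreline with an explicit circular helix.

    positions, h : (n, 3) arrays sampled along the axis trajectory.
    times : (n,) sample times; the helix phase is omega * t.
    Returns positions offset by the helix radius r0 in the plane normal to h.
    With r0 = 0 this is the centreline itself; the time average over one
    period recovers the centreline.
    """
    positions = np.asarray(positions, dtype=float)
    h = np.asarray(h, dtype=float)
    times = np.asarray(times, dtype=float)
    if params.r0 == 0:
        return positions.copy()
    ref = np.where(np.abs(h[..., 2:3]) < 0.9, [0.0, 0.0, 1.0], [1.0, 0.0, 0.0])
    e1 = np.cross(h, ref)
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(h, e1)
    phase = (omega * times)[..., None]
    return positions + params.r0 * (np.cos(phase) * e1 + np.sin(phase) * e2)
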