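"""Velocity fields, co-rotation dynamics, and turbulence scale conversions.

The ambient flow is a simple shear ``v(r) = alpha * (r . e_y) e_x`` expressed in
an orthonormal triad (flow direction ``e_x``, gradient direction ``e_y``,
vorticity direction ``e_z``).  In steady mode the triad is fixed; in unsteady
mode it performs isotropic rotational Brownian motion with diffusivity
``D_rot``, which mimics how gametes below the Kolmogorov scale perceive
turbulence as shear of slowly wandering orientation.

A freely rotating rigid sphere (the egg) may be superimposed: the classical
Stokes solution for a torque-free sphere in linear ambient flow.  The sphere
co-rotates at half the ambient vorticity, so the rotational part of the flow is
undisturbed and only the straining part carries a disturbance, which decays as
``1/r**2`` (stresslet) plus ``1/r**4`` terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShearFlow",
    "SphereDisturbance",
    "TurbulenceScales",
    "shear_velocity",
    "total_velocity",
    "velocity_gradient",
    "jeffery_rate",
    "kolmogorov_scales",
    "alpha_from_epsilon",
    "burger_exposure_time",
]

_FRAME_TOL = 1e-12


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (3, 3):
        raise ValueError("axis_frame must be a 3x3 matrix with rows e_x, e_y, e_z")
    if not np.allclose(frame @ frame.T, np.eye(3), atol=1e-9):
        raise ValueError("axis_frame must be orthonormal")
    # Re-orthonormalize to machine precision so downstream invariants hold to 1e-12.
    u, _, vt = np.linalg.svd(frame)
    frame = u @ vt
    if np.linalg.det(frame) < 0:
        raise ValueError("axis_frame must be right-handed")
    assert np.abs(frame @ frame.T - np.eye(3)).max() < _FRAME_TOL
    return frame


@dataclass
class ShearFlow:
    """Simple shear flow with shear rate ``alpha`` (1/s).

    Parameters
    ----------
    alpha : float
        Shear rate, 1/s.  Must be non-negative.
    axis_frame : (3, 3) array
        Rows are (e_x, e_y, e_z) = (flow, gradient, vorticity) directions.
    unsteady : bool
        If True the frame performs rotational Brownian motion with
        diffusivity ``D_rot`` (rad^2/s), discretised with step ``frame_dt``.
    seed : int
        Seed for the frame trajectory (unsteady mode only).
    """

    alpha: float
    axis_frame: np.ndarray = field(default_factory=lambda: np.eye(3))
    unsteady: bool = False
    D_rot: float = 0.0
    seed: int = 0
    frame_dt: float = 0.1

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")
        if self.D_rot < 0:
            raise ValueError("D_rot must be >= 0")
        self.axis_frame = _check_frame(self.axis_frame)
        self._frames = [self.axis_frame.copy()]
        self._frame_rng = np.random.default_rng(self.seed)

    # -- frame trajectory -------------------------------------------------
    def frame_at(self, t: float) -> np.ndarray:
        """Orthonormal triad at time ``t`` (rows e_x, e_y, e_z)."""
        if not self.unsteady or self.D_rot == 0.0:
            return self.axis_frame
        if t < 0:
            raise ValueError("t must be >= 0")
        idx = int(round(t / self.frame_dt))
        while len(self._frames) <= idx:
            # Rotation increment with <dphi^2> = 2 * D_rot * dt per axis.
            dphi = self._frame_rng.normal(
                scale=np.sqrt(2.0 * self.D_rot * self.frame_dt), size=3
            )
            prev = self._frames[-1]
            self._frames.append(_rotate_frame(prev, dphi))
        return self._frames[idx]

    def gradient_tensor(self, t: float = 0.0) -> np.ndarray:
        """Velocity-gradient tensor A with A_ij = dv_i/dr_j = alpha e_x e_y^T."""
        fr = self.frame_at(t)
        return self.alpha * np.outer(fr[0], fr[1])


def _rotate_frame(frame: np.ndarray, dphi: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(dphi)
    if angle == 0.0:
        return frame
    axis = dphi / angle
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    new = frame @ R.T
    u, _, vt = np.linalg.svd(new)
    return u @ vt


@dataclass
class SphereDisturbance:
    """Rigid freely-rotating sphere of radius ``r_egg`` at the origin."""

    r_egg: float
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.r_egg <= 0:
            raise ValueError("r_egg must be > 0")


@dataclass
class TurbulenceScales:
    """Kinematic viscosity nu (m^2/s), dissipation rate epsilon (m^2/s^3),
    and the dimensionless proportionality factor ``a`` in alpha = a*sqrt(eps/nu)."""

    nu: float
    epsilon: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.epsilon <= 0 or self.a <= 0:
            raise ValueError("nu, epsilon, a must all be > 0")


# ---------------------------------------------------------------------------
# velocity fields
# ---------------------------------------------------------------------------

def shear_velocity(r: np.ndarray, flow: ShearFlow, t: float = 0.0) -> np.ndarray:
    """Ambient shear velocity ``alpha * (r . e_y) e_x`` at position(s) ``r``."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("position must be finite")
    fr = flow.frame_at(t)
    return flow.alpha * (r @ fr[1])[..., None] * fr[0]


def _strain_rotation(flow: ShearFlow, t: float) -> tuple[np.ndarray, np.ndarray]:
    A = flow.gradient_tensor(t)
    E = 0.5 * (A + A.T)
    W = 0.5 * (A - A.T)
    return E, W


def total_velocity(
    r: np.ndarray,
    flow: ShearFlow,
    sphere: SphereDisturbance | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Velocity of shear flow around a freely-rotating sphere at the origin.

    Uses the classical Stokes solution for a torque- and force-free rigid
    sphere in linear ambient flow: the rotational part W.r is undisturbed
    (the sphere spins at half the ambient vorticity), while the straining
    part acquires the stresslet + degenerate-quadrupole disturbance

        u_dist = -(a^5/r^5) E.r - (5/2) (a^3/r^5 - a^5/r^7) (r.E.r) r

    which satisfies no-slip on ``|r| = r_egg`` and vanishes at infinity.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("position must be finite")
    v = shear_velocity(r, flow, t)
    if sphere is None or not sphere.enabled:
        return v
    a = sphere.r_egg
    rn = np.linalg.norm(r, axis=-1)
    if np.any(rn < a * (1 - 1e-12)):
        raise ValueError("position inside the egg (|r| < r_egg)")
    E, _ = _strain_rotation(flow, t)
    Er = r @ E.T
    rEr = np.einsum("...i,...i->...", r, Er)
    r2 = rn**2
    a3 = (a / rn) ** 3
    a5 = (a / rn) ** 5
    u_dist = (
        -a5[..., None] * Er
        - 2.5 * ((a3 - a5) / r2)[..., None] * rEr[..., None] * r
    )
    return v + u_dist


def velocity_gradient(
    r: np.ndarray,
    flow: ShearFlow,
    sphere: SphereDisturbance | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Velocity-gradient tensor(s) A_ij = dv_i/dr_j at position(s) ``r``.

    Both the ambient shear and the sphere-disturbance contribution are
    analytic (the disturbance is differentiated in closed form).  Points
    inside the egg are clamped to its surface first.
    """
    r = np.asarray(r, dtype=float)
    A = flow.gradient_tensor(t)
    out = np.broadcast_to(A, r.shape[:-1] + (3, 3)).copy()
    if sphere is None or not sphere.enabled:
        return out
    single = r.ndim == 1
    pts = np.atleast_2d(r)
    rn = np.linalg.norm(pts, axis=-1, keepdims=True)
    a = sphere.r_egg
    pts = np.where(rn < a, pts * (a / np.maximum(rn, 1e-300)), pts)
    rn = np.maximum(rn, a)
    E, _ = _strain_rotation(flow, t)
    Er = pts @ E.T
    rEr = np.einsum("...i,...i->...", pts, Er)[..., None]
    r5 = rn**-5
    r7 = rn**-7
    r9 = rn**-9
    a3, a5 = a**3, a**5
    eye = np.eye(3)
    # grad of  u_dist = -(a^5/r^5) E.r - (5/2)(a^3/r^5 - a^5/r^7)(r.E.r) r :
    # g_ik = 5 a5 r^-7 (E.r)_i r_k - a5 r^-5 E_ik
    #        + (12.5 a3 r^-7 - 17.5 a5 r^-9) (r.E.r) r_i r_k
    #        - 2.5 (a3 r^-5 - a5 r^-7) (delta_ik (r.E.r) + 2 r_i (E.r)_k)
    g = 5.0 * a5 * r7[..., None] * Er[..., :, None] * pts[..., None, :]
    g -= (a5 * r5)[..., None] * E
    g += ((12.5 * a3 * r7 - 17.5 * a5 * r9) * rEr)[..., None] * (
        pts[..., :, None] * pts[..., None, :]
    )
    c3 = 2.5 * (a3 * r5 - a5 * r7)
    g -= (c3 * rEr)[..., None] * eye
    g -= (2.0 * c3)[..., None] * pts[..., :, None] * Er[..., None, :]
    if single:
        return A + g[0]
    out += g
    return out


# ---------------------------------------------------------------------------
# orientation dynamics
# ---------------------------------------------------------------------------

def jeffery_rate(h: np.ndarray, grad_v: np.ndarray, g: float = 5.0) -> np.ndarray:
    """Rotation rate of a prolate spheroid's axis in linear flow.

        h_dot = W.h + G (E.h - (h.E.h) h),   G = (g^2 - 1)/(g^2 + 1)

    with E/W the symmetric/antisymmetric parts of ``grad_v`` and ``g`` the
    effective aspect ratio.  The result is orthogonal to ``h``.
    """
    if g < 1:
        raise ValueError("aspect ratio g must be >= 1")
    h = np.asarray(h, dtype=float)
    norm = np.linalg.norm(h, axis=-1)
    if np.any(np.abs(norm - 1.0) > 1e-9):
        raise ValueError("orientation h must be a unit vector (|h| = 1 +- 1e-9)")
    grad_v = np.asarray(grad_v, dtype=float)
    E = 0.5 * (grad_v + np.swapaxes(grad_v, -1, -2))
    W = 0.5 * (grad_v - np.swapaxes(grad_v, -1, -2))
    G = (g**2 - 1.0) / (g**2 + 1.0)
    Wh = np.einsum("...ij,...j->...i", W, h)
    Eh = np.einsum("...ij,...j->...i", E, h)
    hEh = np.einsum("...i,...i->...", h, Eh)
    return Wh + G * (Eh - hEh[..., None] * h)


# ---------------------------------------------------------------------------
# turbulence scale conversions
# ---------------------------------------------------------------------------

def kolmogorov_scales(ts: TurbulenceScales) -> tuple[float, float]:
    """Kolmogorov length eta = (nu^3/eps)^(1/4) and time tau = sqrt(nu/eps)."""
    eta = (ts.nu**3 / ts.epsilon) ** 0.25
    tau = np.sqrt(ts.nu / ts.epsilon)
    return float(eta), float(tau)


def alpha_from_epsilon(ts: TurbulenceScales) -> float:
    """Characteristic shear rate alpha = a * sqrt(epsilon / nu)."""
    return float(ts.a * np.sqrt(ts.epsilon / ts.nu))


def burger_exposure_time(alpha: float) -> float:
    """Effective sperm-egg exposure time ~ decay time of a Burgers vortex, 25/alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return 25.0 / alpha
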