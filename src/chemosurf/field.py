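"""Chemoattractant concentration fields in linear shear flow.

A point source at the origin releases chemoattractant at constant rate
``Qdot`` into a simple shear flow.  Because the flow is linear, the
advection-diffusion propagator of each released parcel stays exactly
Gaussian; its centroid obeys ``m_dot = A m`` (hence stays at the origin) and
its covariance obeys ``C_dot = A C + C A^T + 2 D I``.  For steady simple
shear the covariance has the classical shear-dispersion closed form

    C_yy = C_zz = 2 D tau,   C_xy = D alpha tau^2,
    C_xx = 2 D tau (1 + alpha^2 tau^2 / 3).

The continuous-release field is the time integral of these Gaussians,

    c(r, t) = c_bg + Qdot * Integral_0^t  N(r; 0, C(tau)) d tau,

evaluated either by adaptive quadrature (reference) or by a fixed
Gauss-Legendre rule on logarithmically growing panels (fast, vectorised,
used for tabulation).  Gradients are obtained by differentiating the
Gaussian under the integral, never by finite differences.

The flow stretches this field into a slender filament: exponential decay
along the centreline and a Gaussian (elliptical) cross-section,

    c = c0 * exp(-k |x|) * exp(-((y - y0)^2 / a_y^2 + z^2) / (2 sigma^2)),

whose parameters are recovered from a computed field by least squares
(`fit_filament`).  Level sets c >= c_b of this form are ellipses whose area
and circumference enter the encounter-probability theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dfield

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate
from scipy.interpolate import RegularGridInterpolator

from .flow import ShearFlow

__all__ = [
    "SourceParams",
    "FilamentParams",
    "LevelSetGeometry",
    "point_release_moments",
    "concentration",
    "concentration_gradient",
    "tabulate_field",
    "TabulatedField",
    "fit_filament",
    "level_set_geometry",
    "total_chemotactic_volume",
]


@dataclass
class SourceParams:
    """Continuous chemoattractant source (the egg) at the origin.

    Qdot : release rate, mol/s.
    D : diffusivity of the chemoattractant, m^2/s.
    t_release : release duration, s (the static reference field is the field
        at this time).
    c_bg : uniform background concentration, mol/m^3.
    r_egg : egg radius, m; the field is clamped at this radius.
    """

    Qdot: float
    D: float
    t_release: float
    c_bg: float = 0.0
    r_egg: float = 50e-6

    def __post_init__(self) -> None:
        if self.Qdot < 0:
            raise ValueError("Qdot must be >= 0")
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.t_release <= 0:
            raise ValueError("t_release must be > 0")
        if self.c_bg < 0:
            raise ValueError("c_bg must be >= 0")


# ---------------------------------------------------------------------------
# propagator moments
# ---------------------------------------------------------------------------

def _steady_cov_components(alpha: float, D: float, tau: np.ndarray):
    """Covariance components in the shear frame for steady simple shear."""
    tau = np.asarray(tau, dtype=float)
    Cyy = 2.0 * D * tau
    Czz = 2.0 * D * tau
    Cxy = D * alpha * tau**2
    Cxx = 2.0 * D * tau * (1.0 + alpha**2 * tau**2 / 3.0)
    return Cxx, Cxy, Cyy, Czz


def point_release_moments(
    tau: float, flow: ShearFlow, D: float
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and covariance of a point release of age ``tau`` (lab frame).

    Steady shear uses the closed form above; unsteady shear integrates the
    deformation gradient along the (seeded) frame history, with the release
    at time 0 and observation at time ``tau``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    m = np.zeros(3)
    if tau == 0:
        return m, np.zeros((3, 3))
    if not flow.unsteady or flow.D_rot == 0.0:
        Cxx, Cxy, Cyy, Czz = _steady_cov_components(flow.alpha, D, tau)
        C_frame = np.array([[Cxx, Cxy, 0.0], [Cxy, Cyy, 0.0], [0.0, 0.0, Czz]])
        F = flow.axis_frame
        return m, F.T @ C_frame @ F
    C = _unsteady_covariances(flow, D, tau, np.array([tau]))[0]
    return m, C


def _unsteady_covariances(
    flow: ShearFlow, D: float, t_obs: float, ages: np.ndarray
) -> np.ndarray:
    """Covariances for parcels of the given ages observed at ``t_obs``.

    Integrates the deformation gradient F (F_dot = A(t) F) with RK4 on a fine
    grid, then C(age) = 2 D F(t) [K(t) - K(t-age)] F(t)^T with
    K(s) = Integral_0^s F^-1 F^-T ds'.
    """
    n = max(200, int(np.ceil(t_obs / (0.25 * flow.frame_dt))) + 1)
    ts = np.linspace(0.0, t_obs, n)
    dt = ts[1] - ts[0]
    F = np.eye(3)
    Fs = np.empty((n, 3, 3))
    Fs[0] = F
    for i in range(n - 1):
        t0 = ts[i]
        k1 = flow.gradient_tensor(t0) @ F
        k2 = flow.gradient_tensor(t0 + dt / 2) @ (F + dt / 2 * k1)
        k3 = flow.gradient_tensor(t0 + dt / 2) @ (F + dt / 2 * k2)
        k4 = flow.gradient_tensor(t0 + dt) @ (F + dt * k3)
        F = F + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        Fs[i + 1] = F
    Finv = np.linalg.inv(Fs)
    integrand = Finv @ np.swapaxes(Finv, -1, -2)
    K = integrate.cumulative_trapezoid(integrand, ts, axis=0, initial=0.0)
    Ft = Fs[-1]
    out = np.empty((len(ages), 3, 3))
    for j, age in enumerate(ages):
        K_lo = np.array(
            [np.interp(t_obs - age, ts, K[:, a, b]) for a in range(3) for b in range(3)]
        ).reshape(3, 3)
        out[j] = 2.0 * D * Ft @ (K[-1] - K_lo) @ Ft.T
    return out


# ---------------------------------------------------------------------------
# fixed-node quadrature (vectorised evaluator)
# ---------------------------------------------------------------------------

def _quadrature_nodes(
    t: float, tau_lo: float, n_per_panel: int = 8, growth: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on log-growing panels covering [tau_lo, t]."""
    xg, wg = leggauss(n_per_panel)
    edges = [tau_lo]
    while edges[-1] < t:
        edges.append(min(edges[-1] * growth, t))
    taus, ws = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        taus.append(mid + half * xg)
        ws.append(half * wg)
    return np.concatenate(taus), np.concatenate(ws)


class _FixedQuadEvaluator:
    """Vectorised c and grad c via fixed quadrature, steady shear only."""

    def __init__(self, src: SourceParams, flow: ShearFlow, t: float):
        if flow.unsteady and flow.D_rot > 0:
            raise NotImplementedError("fixed-node evaluator requires steady shear")
        self.src, self.flow, self.t = src, flow, t
        tau_lo = src.r_egg**2 / (150.0 * src.D)
        taus, w = _quadrature_nodes(t, tau_lo)
        Cxx, Cxy, Cyy, Czz = _steady_cov_components(flow.alpha, src.D, taus)
        det2 = Cxx * Cyy - Cxy**2
        det = det2 * Czz
        self._taus, self._w = taus, w
        self._ixx = Cyy / det2
        self._ixy = -Cxy / det2
        self._iyy = Cxx / det2
        self._izz = 1.0 / Czz
        self._norm = 1.0 / ((2.0 * np.pi) ** 1.5 * np.sqrt(det))

    def __call__(self, points: np.ndarray, chunk: int = 65536):
        """Return (c, grad) at lab-frame points of shape (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        pts = _clamp_to_egg(pts, self.src.r_egg)
        F = self.flow.axis_frame
        xi = pts @ F.T  # frame coords
        n = len(xi)
        c = np.empty(n)
        grad_f = np.empty((n, 3))
        for lo in range(0, n, chunk):
            sl = slice(lo, min(lo + chunk, n))
            x, y, z = xi[sl, 0:1], xi[sl, 1:2], xi[sl, 2:3]
            gx = self._ixx * x + self._ixy * y
            gy = self._ixy * x + self._iyy * y
            gz = self._izz * z
            q = gx * x + gy * y + gz * z
            N = self._norm * np.exp(-0.5 * q)
            wN = self._w * N
            c[sl] = wN.sum(axis=1)
            grad_f[sl, 0] = -(wN * gx).sum(axis=1)
            grad_f[sl, 1] = -(wN * gy).sum(axis=1)
            grad_f[sl, 2] = -(wN * gz).sum(axis=1)
        c = self.src.Qdot * c + self.src.c_bg
        grad = self.src.Qdot * (grad_f @ F)
        if np.asarray(points).ndim == 1:
            return float(c[0]), grad[0]
        return c, grad


def _clamp_to_egg(pts: np.ndarray, r_egg: float) -> np.ndarray:
    rn = np.linalg.norm(pts, axis=-1)
    inside = rn < r_egg
    if np.any(inside):
        pts = pts.copy()
        safe = np.where(rn[inside] > 0, rn[inside], r_egg)
        pts[inside] *= (r_egg / safe)[:, None]
        pts[rn == 0] = np.array([r_egg, 0.0, 0.0])
    return pts


# ---------------------------------------------------------------------------
# reference (adaptive) evaluation
# ---------------------------------------------------------------------------

def _gaussian_integrand(tau, xi, flow, D):
    Cxx, Cxy, Cyy, Czz = _steady_cov_components(flow.alpha, D, tau)
    det2 = Cxx * Cyy - Cxy**2
    det = det2 * Czz
    x, y, z = xi
    q = (Cyy * x**2 - 2 * Cxy * x * y + Cxx * y**2) / det2 + z**2 / Czz
    return np.exp(-0.5 * q) / ((2 * np.pi) ** 1.5 * np.sqrt(det))


def concentration(
    r: np.ndarray,
    t: float,
    src: SourceParams,
    flow: ShearFlow,
    method: str = "adaptive",
) -> float | np.ndarray:
    """Concentration c(r, t) for continuous release since time 0.

    ``method='adaptive'`` (default) uses scipy adaptive quadrature with
    relative tolerance 1e-8 per point; ``method='fixed'`` uses the fast
    vectorised fixed-node rule.  Points inside the egg are clamped to the
    egg surface with a warning.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    pts = np.atleast_2d(np.asarray(r, dtype=float))
    if np.any(np.linalg.norm(pts, axis=-1) < src.r_egg):
        warnings.warn("position inside egg: concentration clamped at r_egg surface")
    if method == "fixed":
        c, _ = _FixedQuadEvaluator(src, flow, t)(r)
        return c
    if flow.unsteady and flow.D_rot > 0:
        return _concentration_unsteady(r, t, src, flow)
    pts = _clamp_to_egg(pts, src.r_egg)
    F = flow.axis_frame
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        xi = F @ p
        val, err = integrate.quad(
            _gaussian_integrand,
            0.0,
            t,
            args=(xi, flow, src.D),
            epsabs=0.0,
            epsrel=1e-8,
            limit=400,
        )
        if err > 1e-4 * max(abs(val), 1e-300):
            raise RuntimeError(
                f"quadrature did not converge at r={p}: value {val}, err {err}"
            )
        out[i] = src.Qdot * val + src.c_bg
    return float(out[0]) if np.asarray(r).ndim == 1 else out


def _concentration_unsteady(r, t, src, flow):
    pts = _clamp_to_egg(np.atleast_2d(np.asarray(r, dtype=float)), src.r_egg)
    taus, w = _quadrature_nodes(t, src.r_egg**2 / (150.0 * src.D), n_per_panel=6)
    Cs = _unsteady_covariances(flow, src.D, t, taus)
    Cinv = np.linalg.inv(Cs)
    dets = np.linalg.det(Cs)
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        q = np.einsum("i,nij,j->n", p, Cinv, p)
        N = np.exp(-0.5 * q) / ((2 * np.pi) ** 1.5 * np.sqrt(dets))
        out[i] = src.Qdot * np.sum(w * N) + src.c_bg
    return float(out[0]) if np.asarray(r).ndim == 1 else out


def concentration_gradient(
    r: np.ndarray,
    t: float,
    src: SourceParams,
    flow: ShearFlow,
    method: str = "adaptive",
) -> np.ndarray:
    """Gradient of the concentration field, by differentiating the Gaussian
    under the time integral (analytic in the integrand, not finite
    differences)."""
    if method == "fixed":
        _, g = _FixedQuadEvaluator(src, flow, t)(r)
        return g
    pts = _clamp_to_egg(np.atleast_2d(np.asarray(r, dtype=float)), src.r_egg)
    F = flow.axis_frame
    out = np.empty((len(pts), 3))
    for i, p in enumerate(pts):
        xi = F @ p
        for comp in range(3):
            def integrand(tau, comp=comp):
                Cxx, Cxy, Cyy, Czz = _steady_cov_components(flow.alpha, src.D, tau)
                det2 = Cxx * Cyy - Cxy**2
                gvec = np.array(
                    [
                        (Cyy * xi[0] - Cxy * xi[1]) / det2,
                        (-Cxy * xi[0] + Cxx * xi[1]) / det2,
                        xi[2] / Czz,
                    ]
                )
                return -_gaussian_integrand(tau, xi, flow, src.D) * gvec[comp]
            val, _ = integrate.quad(
                integrand, 0.0, t, epsabs=0.0, epsrel=1e-8, limit=400
            )
            out[i, comp] = src.Qdot * val
    out = out @ F  # frame -> lab
    return out[0] if np.asarray(r).ndim == 1 else out


# ---------------------------------------------------------------------------
# tabulated field
# ---------------------------------------------------------------------------

def _stretched_axis(half_extent: float, n: int, beta: float = 3.0) -> np.ndarray:
    """Symmetric axis clustered near 0: x = L sinh(beta u)/sinh(beta)."""
    if n % 2 == 0:
        n += 1
    u = np.linspace(-1.0, 1.0, n)
    ax = half_extent * np.sinh(beta * u) / np.sinh(beta)
    ax[n // 2] = 0.0
    return ax


class TabulatedField:
    """Trilinear interpolant of (c, grad c) on a rectilinear stretched grid.

    Inside ``r_near`` of the origin (where the field is steep) and outside
    the grid (where c = c_bg) evaluation falls back to direct quadrature /
    the constant background, so the interpolant is only trusted in its
    smooth bulk.  ``validate`` measures the worst relative interpolation
    error against adaptive quadrature at random points.
    """

    def __init__(self, src, flow, t, xs, ys, zs, c, grad, r_near=1.5e-3):
        self.src, self.flow, self.t = src, flow, t
        self.xs, self.ys, self.zs = xs, ys, zs
        self.c_values = c
        self.grad_values = grad
        self.r_near = r_near
        vals = np.concatenate([c[..., None], grad], axis=-1)
        self._interp = RegularGridInterpolator(
            (xs, ys, zs), vals, method="linear", bounds_error=False, fill_value=None
        )
        self._direct = _FixedQuadEvaluator(src, flow, t)

    def evaluate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (c, grad) at points of shape (..., 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        flat = pts.reshape(-1, 3)
        c = np.full(len(flat), self.src.c_bg)
        grad = np.zeros((len(flat), 3))
        rn = np.linalg.norm(flat, axis=-1)
        near = rn < self.r_near
        outside = (
            (np.abs(flat[:, 0]) > self.xs[-1])
            | (np.abs(flat[:, 1]) > self.ys[-1])
            | (np.abs(flat[:, 2]) > self.zs[-1])
        )
        bulk = ~near & ~outside
        if np.any(bulk):
            vals = self._interp(flat[bulk])
            c[bulk] = vals[:, 0]
            grad[bulk] = vals[:, 1:]
        if np.any(near):
            c[near], grad[near] = self._direct(flat[near])
        shape = pts.shape[:-1]
        if np.asarray(points).ndim == 1:
            return float(c[0]), grad[0]
        return c.reshape(shape), grad.reshape(shape + (3,))

    def validate(
        self, n_points: int = 1000, rtol: float = 0.01, seed: int = 0
    ) -> float:
        """Worst relative error of interpolated c vs direct quadrature at
        random points where c is non-negligible.  Raises if above ``rtol``."""
        rng = np.random.default_rng(seed)
        c_ref_scale = float(
            self._direct(np.array([2 * self.src.r_egg, 0.0, 0.0]))[0]
        ) - self.src.c_bg
        floor = 1e-3 * c_ref_scale
        pts = np.column_stack(
            [
                rng.uniform(self.xs[0], self.xs[-1], 8 * n_points),
                rng.uniform(self.ys[0], self.ys[-1], 8 * n_points),
                rng.uniform(self.zs[0], self.zs[-1], 8 * n_points),
            ]
        )
        c_dir, _ = self._direct(pts)
        keep = (c_dir - self.src.c_bg) > floor
        keep &= np.linalg.norm(pts, axis=-1) > self.src.r_egg
        pts, c_dir = pts[keep][:n_points], c_dir[keep][:n_points]
        if len(pts) == 0:
            raise RuntimeError("no validation points above the concentration floor")
        c_int, _ = self.evaluate(pts)
        rel = np.abs(c_int - c_dir) / np.abs(c_dir)
        worst = float(rel.max())
        if worst > rtol:
            iw = int(np.argmax(rel))
            raise RuntimeError(
                f"tabulated field fails validation: worst rel error {worst:.3g} "
                f"at r={pts[iw]} (tolerance {rtol})"
            )
        return worst


def tabulate_field(
    src: SourceParams,
    flow: ShearFlow,
    t: float,
    nx: int = 241,
    nyz: int = 145,
    x_max: float | None = None,
    yz_max: float | None = None,
    r_near: float = 1.5e-3,
    validate: bool = False,
) -> TabulatedField:
    """Tabulate c and grad c on a stretched rectilinear grid.

    The default extents follow the dispersion scales: axially
    ``6 sqrt(C_xx(t))`` plus a diffusive margin, transversally
    ``8 sqrt(2 D t)``.  Exploits the point symmetry
    c(x, y, z) = c(-x, -y, z) = c(x, y, -z) to evaluate only one quarter of
    the grid.
    """
    Cxx, _, Cyy, _ = _steady_cov_components(flow.alpha, src.D, np.array([t]))
    sx, sy = float(np.sqrt(Cxx[0])), float(np.sqrt(Cyy[0]))
    Lx = x_max if x_max is not None else 6.0 * sx + 4.0 * sy
    Lyz = yz_max if yz_max is not None else 8.0 * sy
    xs = _stretched_axis(Lx, nx)
    ys = _stretched_axis(Lyz, nyz)
    zs = _stretched_axis(Lyz, nyz)
    ev = _FixedQuadEvaluator(src, flow, t)
    nx_, ny_, nz_ = len(xs), len(ys), len(zs)
    mid_x, mid_z = nx_ // 2, nz_ // 2
    xs_half, zs_half = xs[mid_x:], zs[mid_z:]
    X, Y, Z = np.meshgrid(xs_half, ys, zs_half, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    c_q, g_q = ev(pts)
    cq = c_q.reshape(len(xs_half), ny_, len(zs_half))
    gq = g_q.reshape(len(xs_half), ny_, len(zs_half), 3)
    c = np.empty((nx_, ny_, nz_))
    grad = np.empty((nx_, ny_, nz_, 3))
    # quarter -> half (mirror z; c even, grad_z odd)
    c[mid_x:, :, mid_z:] = cq
    grad[mid_x:, :, mid_z:] = gq
    c[mid_x:, :, : mid_z] = cq[:, :, 1:][:, :, ::-1]
    grad[mid_x:, :, : mid_z] = gq[:, :, 1:][:, :, ::-1]
    grad[mid_x:, :, : mid_z, 2] *= -1.0
    # half -> full (mirror x & y together; c even, grad_x/grad_y odd)
    c[: mid_x] = c[mid_x + 1 :, ::-1][::-1]
    grad[: mid_x] = grad[mid_x + 1 :, ::-1][::-1]
    grad[: mid_x, :, :, 0] *= -1.0
    grad[: mid_x, :, :, 1] *= -1.0
    tf = TabulatedField(src, flow, t, xs, ys, zs, c, grad, r_near=r_near)
    if validate:
        tf.validate()
    return tf


# ---------------------------------------------------------------------------
# filament parameterisation
# ---------------------------------------------------------------------------

@dataclass
class FilamentParams:
    """Fitted parameters of the filament form of the concentration field.

    ``sigma`` and ``y0`` vary with |x|; they are stored at the fitted nodes
    and linearly interpolated (clamped outside).
    """

    c0: float
    k: float
    a_y: float
    x_nodes: np.ndarray
    sigma_nodes: np.ndarray
    y0_nodes: np.ndarray
    axial_residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.c0 > 0 and self.k > 0):
            raise ValueError("c0 and k must be > 0")
        if np.any(self.sigma_nodes <= 0):
            raise ValueError("sigma must be > 0")
        self.a_y = max(float(self.a_y), 1.0)

    @property
    def sigma(self) -> float:
        """Representative cross-sectional decay length (median over nodes)."""
        return float(np.median(self.sigma_nodes))

    def sigma_at(self, x) -> np.ndarray:
        return np.interp(np.abs(x), self.x_nodes, self.sigma_nodes)

    def y0_at(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sign(x) * np.interp(np.abs(x), self.x_nodes, self.y0_nodes)

    def profile(self, r: np.ndarray) -> np.ndarray:
        """Evaluate the filament form itself at lab points (..., 3)."""
        r = np.asarray(r, dtype=float)
        x, y, z = r[..., 0], r[..., 1], r[..., 2]
        s = self.sigma_at(x)
        y0 = self.y0_at(x)
        return (
            self.c0
            * np.exp(-self.k * np.abs(x))
            * np.exp(-(((y - y0) ** 2) / self.a_y**2 + z**2) / (2.0 * s**2))
        )


@dataclass
class LevelSetGeometry:
    """Cross-sectional area A and circumference S of {c >= threshold} at x."""

    x: float
    A: float
    S: float


def _cross_section_fit(conc_fn, x, y_center, span, n=(41, 21)):
    """Fit ln c over a (y, z) patch to a quadratic; returns
    (c_ridge, y0, sigma, a_y) or None when the signal is too weak."""
    ys = y_center + np.linspace(-span, span, n[0])
    zs = np.linspace(0.0, span, n[1])
    Y, Z = np.meshgrid(ys, zs, indexing="ij")
    pts = np.column_stack([np.full(Y.size, x), Y.ravel(), Z.ravel()])
    c = conc_fn(pts)
    if np.max(c) <= 0:
        return None
    keep = c > np.max(c) * np.exp(-4.0)
    if keep.sum() < 12:
        return None
    dy = Y.ravel()[keep] - y_center
    zz = Z.ravel()[keep]
    lc = np.log(c[keep])
    Adm = np.column_stack([np.ones_like(dy), dy, dy**2, zz**2])
    wts = np.sqrt(c[keep] / np.max(c))
    coef, *_ = np.linalg.lstsq(Adm * wts[:, None], lc * wts, rcond=None)
    b0, b1, b2, bz = coef
    if b2 >= 0 or bz >= 0:
        return None
    sigma = float(np.sqrt(-1.0 / (2.0 * bz)))
    a_y = float(np.sqrt(bz / b2))
    y0 = float(y_center - b1 / (2.0 * b2))
    c_ridge = float(np.exp(b0 - b1**2 / (4.0 * b2)))
    return c_ridge, y0, sigma, a_y


def fit_filament(
    field,
    flow: ShearFlow,
    t: float,
    x_range: tuple[float, float] | None = None,
    n_x: int = 20,
) -> FilamentParams:
    """Recover filament parameters (c0, k, sigma(x), a_y, y0(x)) from a field.

    ``field`` is a TabulatedField, or a SourceParams (evaluated directly).
    For each sampled x > 0 the cross-section maximum locates y0(x); a
    weighted least-squares fit of ln c over the (y, z) cross-section gives
    sigma and a_y; an exponential fit along the ridge gives c0 and k.
    """
    if flow.alpha <= 0:
        raise ValueError("filament fit requires alpha > 0 (no filament in still water)")
    if isinstance(field, SourceParams):
        src = field
        ev = _FixedQuadEvaluator(src, flow, t)
        conc_fn = lambda pts: ev(pts)[0] - src.c_bg
    else:
        src = field.src
        conc_fn = lambda pts: field.evaluate(pts)[0] - src.c_bg
    sy = float(np.sqrt(2.0 * src.D * t))
    if x_range is None:
        Cxx, *_ = _steady_cov_components(flow.alpha, src.D, np.array([t]))
        x_hi = 2.5 * float(np.sqrt(Cxx[0]))
        x_range = (max(5.0 * src.r_egg, 0.02 * x_hi), x_hi)
    xs = np.geomspace(x_range[0], x_range[1], n_x)
    rows = []
    for x in xs:
        # coarse ridge scan in y at z = 0
        y_scan = np.linspace(0.0, 4.0 * sy, 81)
        pts = np.column_stack([np.full_like(y_scan, x), y_scan, np.zeros_like(y_scan)])
        c_scan = conc_fn(pts)
        if np.max(c_scan) <= 0:
            continue
        yc = float(y_scan[np.argmax(c_scan)])
        span = sy
        fit = None
        for _ in range(3):  # shrink the patch to the fitted width
            new = _cross_section_fit(conc_fn, x, yc, 2.5 * span)
            if new is None:
                break
            fit = new
            yc, span = fit[1], fit[2]
        if fit is not None:
            rows.append((x, *fit))
    if len(rows) < 4:
        raise RuntimeError("no filament: concentration below numerical floor over fit range")
    xs_f = np.array([r[0] for r in rows])
    c_ridge = np.array([r[1] for r in rows])
    y0s = np.abs([r[2] for r in rows])
    sigmas = np.array([r[3] for r in rows])
    a_ys = np.array([r[4] for r in rows])
    slope, intercept = np.polyfit(xs_f, np.log(c_ridge), 1)
    resid = np.log(c_ridge) - (intercept + slope * xs_f)
    k = float(-slope)
    if k <= 0:
        raise RuntimeError("no filament: ridge concentration does not decay axially")
    return FilamentParams(
        c0=float(np.exp(intercept)),
        k=k,
        a_y=float(np.median(a_ys)),
        x_nodes=xs_f,
        sigma_nodes=sigmas,
        y0_nodes=y0s,
        axial_residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def level_set_geometry(x: float, fp: FilamentParams, c_thresh: float) -> LevelSetGeometry:
    """Area and circumference of the elliptical level set c >= c_thresh at x.

    With L = ln(c0 e^{-k|x|} / c_thresh): empty for L <= 0, else an ellipse
    with semi-axes a_y sigma sqrt(2L) and sigma sqrt(2L), area
    A = 2 pi a_y sigma^2 L, circumference by Ramanujan's approximation.
    """
    if c_thresh <= 0:
        raise ValueError("c_thresh must be > 0")
    L = np.log(fp.c0 * np.exp(-fp.k * abs(x)) / c_thresh)
    if L <= 0:
        return LevelSetGeometry(x=x, A=0.0, S=0.0)
    s = float(fp.sigma_at(x))
    a = fp.a_y * s * np.sqrt(2.0 * L)
    b = s * np.sqrt(2.0 * L)
    A = np.pi * a * b
    S = np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))
    return LevelSetGeometry(x=x, A=float(A), S=float(S))


def total_chemotactic_volume(
    fp: FilamentParams,
    c_thresh: float,
    x_range: tuple[float, float] | None = None,
    n: int = 2001,
) -> float:
    """V_tot = Integral A(x) dx over the filament (both lobes)."""
    if x_range is None:
        L0 = np.log(fp.c0 / c_thresh)
        if L0 <= 0:
            return 0.0
        x_range = (-L0 / fp.k, L0 / fp.k)
    xs = np.linspace(x_range[0], x_range[1], n)
    As = np.array([level_set_geometry(x, fp, c_thresh).A for x in xs])
    return float(np.trapezoid(As, xs))
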