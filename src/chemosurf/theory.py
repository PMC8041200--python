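"""Analytical theory of filament surfing and the encounter-probability formula.

Inside a slender concentration filament the transverse chemotactic dynamics
reduces to a one-dimensional oscillator for the normalised centreline
distance Y (time in units of the transverse oscillation period):

    Y'' = ( -(1 - Y'^2) Y  -/+  gamma (1 - Y'^2) Y' ) * c/(c + c_b)

The first term is the restoring force of the steep cross-sectional gradient;
the second is damping fed by the weak axial gradient — damping when the cell
moves toward the egg, anti-damping when it moves away.  To leading order
this is a damped harmonic oscillator with damping ratio gamma/2, so the
logarithmic decrement per cycle is ~ pi * gamma.

Linearising the helix-axis alignment law in the filament of the fitted form
gives the transverse frequency omega = sqrt(v_h v_phi)/sigma and the axial
damping rate v_phi k, hence

    gamma = K * k * sigma * sqrt(v_phi / v_h)

with a single dimensionless calibration constant K (default 1, measurable
against full agent simulations with `calibrate_gamma`).  gamma decreases for
longer (smaller k) and thinner (smaller sigma) filaments and increases with
the chemotactic response v_phi.

The encounter probability decomposes into an outer search (blind ballistic
swimming, flux j_out onto the filament surface) and an inner search
(surfing, success probability p_in(x) and conditional duration t_in(x)):

    P = Integral dx  p_in(x) [ A(x) rho_egg + S(x) j_out t_out(x) ] ,

with t_out = max(0, t_max - t_in) where p_in > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import j0

from .agents import ChemotaxisParams, segment_capture_fraction, step_arrays
from .ensemble import DomainConfig
from .field import (
    FilamentParams,
    SourceParams,
    _FixedQuadEvaluator,
    fit_filament,
    level_set_geometry,
    total_chemotactic_volume,
)
from .flow import ShearFlow, SphereDisturbance

__all__ = [
    "SurfState",
    "TheoryInputs",
    "surf_rhs",
    "integrate_surf",
    "gamma_from_filament",
    "calibrate_gamma",
    "inner_search",
    "encounter_probability_theory",
    "theory_curve",
    "fit_j_out",
    "j_out_ballistic",
    "near_field_estimate",
]


@dataclass
class SurfState:
    """State of the surfing oscillator: normalised transverse coordinate Y,
    its rate, axial position and travel direction."""

    Y: float
    Ydot: float
    x: float = 0.0
    direction: str = "toward-egg"


def surf_rhs(state: SurfState, gamma: float, dimmer: float = 1.0) -> float:
    """Acceleration Y'' of the surfing oscillator.

    ``dimmer`` = c/(c + c_b) in [0, 1] switches the response off where the
    concentration drops to the sensing threshold.  The damping term has sign
    - for 'toward-egg' (damped) and + for 'away-from-egg' (amplified).
    """
    if not 0.0 <= dimmer <= 1.0:
        raise ValueError("dimmer must be in [0, 1]")
    sgn = -1.0 if state.direction == "toward-egg" else 1.0
    pref = 1.0 - state.Ydot**2
    return (-pref * state.Y + sgn * gamma * pref * state.Ydot) * dimmer


def integrate_surf(
    Y0: float,
    Ydot0: float,
    gamma: float,
    t_span: float,
    direction: str = "toward-egg",
    dimmer: float = 1.0,
    n_eval: int = 2000,
):
    """Integrate the surfing oscillator; returns (t, Y, Ydot)."""

    def rhs(t, y):
        return [y[1], surf_rhs(SurfState(y[0], y[1], direction=direction), gamma, dimmer)]

    sol = solve_ivp(
        rhs,
        (0.0, t_span),
        [Y0, Ydot0],
        t_eval=np.linspace(0.0, t_span, n_eval),
        rtol=1e-10,
        atol=1e-12,
    )
    return sol.t, sol.y[0], sol.y[1]


def log_decrement(t: np.ndarray, Y: np.ndarray, max_extrema: int = 10) -> float:
    """Mean logarithmic decrement per cycle of a decaying oscillation.

    Uses half-cycle amplitudes |Y_i - Y_{i+1}|/2 between successive extrema,
    which is robust to a slowly varying oscillation centre; restricted to
    the first ``max_extrema`` extrema above the noise floor."""
    s = np.sign(np.diff(Y))
    turning = np.flatnonzero(np.diff(s) != 0) + 1
    ex = Y[turning]
    amps = np.abs(np.diff(ex)) / 2.0
    amps = amps[:max_extrema]
    amps = amps[amps > 0.02 * amps.max()] if len(amps) else amps
    if len(amps) < 3:
        raise ValueError("too few oscillation extrema to measure a decrement")
    return float(2.0 * np.mean(np.log(amps[:-1] / amps[1:])))


def gamma_from_filament(
    fp: FilamentParams, params: ChemotaxisParams, K: float = 1.0
) -> float:
    """Dimensionless surfing parameter gamma = K k sigma sqrt(v_phi/v_h)."""
    if fp.k <= 0 or fp.sigma <= 0:
        raise ValueError("degenerate filament")
    return float(K * fp.k * fp.sigma * np.sqrt(params.v_phi / params.v_h))


def _entry_states(fp, params, x_entry, c_b, rng, n):
    """Entry positions on the c = c_b level-set ellipse at x_entry with
    influx-weighted inward directions."""
    L = np.log(fp.c0 * np.exp(-fp.k * abs(x_entry)) / c_b)
    if L <= 0:
        return None
    s = float(fp.sigma_at(x_entry))
    w_y, w_z = fp.a_y * s * np.sqrt(2 * L), s * np.sqrt(2 * L)
    th = rng.uniform(0, 2 * np.pi, n)
    y0 = float(fp.y0_at(x_entry))
    r = np.column_stack(
        [np.full(n, x_entry), y0 + w_y * np.cos(th), w_z * np.sin(th)]
    )
    inward = np.zeros((n, 3))
    rho = np.hypot(r[:, 1] - y0, r[:, 2])
    inward[:, 1] = -(r[:, 1] - y0) / rho
    inward[:, 2] = -r[:, 2] / rho
    # influx-weighted direction ~ cos(angle to inward normal): reflect outward draws
    h = rng.normal(size=(n, 3))
    h /= np.linalg.norm(h, axis=1, keepdims=True)
    dot = np.einsum("ij,ij->i", h, inward)
    flip = dot < 0
    h[flip] -= 2 * dot[flip, None] * inward[flip]
    return r, h


def inner_search(
    x_entry: float,
    fp: FilamentParams,
    params: ChemotaxisParams,
    t_max: float,
    mode: str = "criterion",
    field=None,
    flow: ShearFlow | None = None,
    sphere: SphereDisturbance | None = None,
    r_egg: float = 50e-6,
    n: int = 200,
    dt: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Probability p_in of reaching the egg after entering the filament at
    x_entry, and the conditional mean surfing time t_in.

    'montecarlo' integrates the full agent dynamics from entry states on the
    c = c_b level set (needs field/flow).  'criterion' is a closed-form
    screen with the two failure modes: the filament is too thin for the
    first chemotactic turn (turning radius v_h/Omega_edge exceeds the
    half-width, i.e. L < v_h/v_phi), or the surf from |x| at the effective
    speed v_h <cos theta> exceeds t_max.
    """
    c_b = params.c_b
    L = np.log(fp.c0 * np.exp(-fp.k * abs(x_entry)) / c_b)
    if L <= 0:
        return 0.0, float("nan")
    if mode == "criterion":
        if L < params.v_h / max(params.v_phi, 1e-300):
            return 0.0, float("nan")
        s = float(fp.sigma_at(x_entry))
        w = s * np.sqrt(2 * L)
        omega = np.sqrt(params.v_h * params.v_phi) / s
        theta_max = min(np.pi / 2, w * omega / params.v_h)
        v_surf = params.v_h * max(float(j0(theta_max)), 0.1)
        t_in = abs(x_entry) / v_surf
        return (1.0, t_in) if t_in <= t_max else (0.0, float("nan"))
    if mode != "montecarlo":
        raise ValueError("mode must be 'criterion' or 'montecarlo'")
    if field is None or flow is None:
        raise ValueError("montecarlo mode needs field and flow")
    if rng is None:
        rng = np.random.default_rng(0)
    ent = _entry_states(fp, params, x_entry, c_b, rng, n)
    if ent is None:
        return 0.0, float("nan")
    r, h = ent
    if sphere is None:
        sphere = SphereDisturbance(r_egg=r_egg, enabled=True)
    t = np.zeros(n)
    cap = np.zeros(n, bool)
    tcap = np.full(n, np.nan)
    active = np.ones(n, bool)
    s = float(fp.sigma_at(x_entry))
    lost_scale = 10.0 * s * np.sqrt(2 * max(L, 1.0))
    while active.any():
        idx = np.flatnonzero(active)
        dti = np.minimum(dt, t_max - t[idx])
        r1, h1 = step_arrays(r[idx], h[idx], dti, flow, sphere, field, params)
        fr = segment_capture_fraction(r[idx], r1, sphere.r_egg)
        hit = fr >= 0
        new = idx[hit]
        cap[new] = True
        tcap[new] = t[new] + fr[hit] * dti[hit]
        active[new] = False
        r[idx] = r1
        h[idx] = h1
        t[idx] += dti
        active[idx[t[idx] >= t_max * (1 - 1e-12)]] = False
        gone = np.abs(r[:, 1] - fp.y0_at(r[:, 0])) > lost_scale
        gone |= np.abs(r[:, 2]) > lost_scale
        active[active & gone] = False
    p = float(cap.mean())
    return p, (float(np.nanmean(tcap)) if cap.any() else float("nan"))


def calibrate_gamma(
    field,
    fp: FilamentParams,
    params: ChemotaxisParams,
    flow: ShearFlow,
    x_start: float,
    t_span: float = 150.0,
    dt: float = 0.25,
) -> tuple[float, float]:
    """Measure the damping of surfing oscillations in a full agent simulation
    and return (gamma_measured, K) with K = gamma_measured / gamma(K=1).

    A single agent is launched on the level-set edge moving transversally
    inward; the log-decrement of its centreline distance divided by pi is
    the measured gamma.
    """
    c_b = params.c_b
    L = np.log(fp.c0 * np.exp(-fp.k * abs(x_start)) / c_b)
    s = float(fp.sigma_at(x_start))
    w = s * np.sqrt(2 * max(L, 0.1))
    r = np.array([[x_start, float(fp.y0_at(x_start)) + w, 0.0]])
    h = np.array([[0.0, -1.0, 0.0]])
    n_steps = int(t_span / dt)
    ys, ts = [], []
    for i in range(n_steps):
        r, h = step_arrays(r, h, dt, flow, None, field, params)
        if r[0, 0] < 0.1 * x_start:  # stop before the near-egg region
            break
        ys.append(r[0, 1] - float(fp.y0_at(r[0, 0])))
        ts.append((i + 1) * dt)
    gamma_meas = log_decrement(np.asarray(ts), np.asarray(ys)) / np.pi
    g0 = gamma_from_filament(fp, params, K=1.0)
    return float(gamma_meas), float(gamma_meas / g0)


@dataclass
class TheoryInputs:
    """Inputs of the encounter-probability integral."""

    fp: FilamentParams
    cfg: DomainConfig
    params: ChemotaxisParams
    j_out: float
    gamma: float = 0.0
    n_grid: int = 400
    x_min_factor: float = 2.0  # exclude |x| < 2 r_egg (far-field validity)

    def __post_init__(self) -> None:
        if self.j_out < 0 or self.gamma < 0:
            raise ValueError("j_out and gamma must be >= 0")


def encounter_probability_theory(
    inputs: TheoryInputs,
    t_max: float | None = None,
    p_in_fn=None,
) -> float:
    """Evaluate P = Int dx p_in [A rho_egg + S j_out t_out], clipped to [0,1].

    ``p_in_fn(x) -> (p_in, t_in)`` defaults to the criterion-mode screen.
    """
    cfg, fp, pars = inputs.cfg, inputs.fp, inputs.params
    if t_max is None:
        t_max = cfg.t_max
    if p_in_fn is None:
        p_in_fn = lambda x: inner_search(x, fp, pars, t_max, mode="criterion")
    xs = np.linspace(inputs.x_min_factor * cfg.r_egg, cfg.r_max, inputs.n_grid // 2)
    vals = np.zeros_like(xs)
    for i, x in enumerate(xs):
        p_in, t_in = p_in_fn(x)
        if p_in <= 0:
            continue
        g = level_set_geometry(x, fp, pars.c_b)
        t_out = max(0.0, t_max - t_in)
        vals[i] = p_in * (g.A * cfg.rho_egg + g.S * inputs.j_out * t_out)
    P = 2.0 * float(np.trapezoid(vals, xs))  # both lobes (integrand even in x)
    return min(max(P, 0.0), 1.0)


def j_out_ballistic(rho_egg: float, v_h: float) -> float:
    """Flux of ballistic swimmers with isotropic directions onto a surface,
    j_out = rho_egg v_h / 4."""
    if rho_egg < 0 or v_h < 0:
        raise ValueError("inputs must be >= 0")
    return rho_egg * v_h / 4.0


def theory_curve(
    alphas,
    src: SourceParams,
    cfg: DomainConfig,
    params: ChemotaxisParams,
    j_out: float | str = "ballistic",
    gamma_K: float = 1.0,
) -> pd.DataFrame:
    """Theory prediction P(alpha) over a sweep; the filament is fitted from
    the exact field at each alpha.  Columns: alpha, gamma, P_theory, V_tot."""
    jb = j_out_ballistic(cfg.rho_egg, params.v_h)
    j = jb if j_out == "ballistic" else float(j_out)
    rows = []
    for alpha in alphas:
        if alpha <= 0:
            rows.append(dict(alpha=alpha, gamma=np.nan, P_theory=np.nan, V_tot=np.nan))
            continue
        flow = ShearFlow(alpha=float(alpha))
        fp = fit_filament(src, flow, src.t_release)
        gamma = gamma_from_filament(fp, params, K=gamma_K)
        ti = TheoryInputs(fp=fp, cfg=cfg, params=params, j_out=j, gamma=gamma)
        P = encounter_probability_theory(ti)
        rows.append(
            dict(
                alpha=alpha,
                gamma=gamma,
                P_theory=P,
                V_tot=total_chemotactic_volume(fp, params.c_b),
            )
        )
    return pd.DataFrame(rows)


def fit_j_out(theory_tab: pd.DataFrame, sim_tab: pd.DataFrame, j_ref: float) -> float:
    """Single-parameter rescaling of j_out to match a simulated curve.

    The outer-search term of the theory is linear in j_out; with the
    resident term negligible (low egg density) P_theory is ~ proportional
    to j_out, so a weighted least-squares scale suffices.
    """
    m = pd.merge(theory_tab, sim_tab, on="alpha", how="inner").dropna(
        subset=["P_theory"]
    )
    m = m[m["P_theory"] > 0]
    if len(m) == 0:
        raise ValueError("no overlapping sweep points")
    w = 1.0 / np.maximum(m["sd"].to_numpy(), 1e-12) ** 2
    x, y = m["P_theory"].to_numpy(), m["P"].to_numpy()
    scale = float(np.sum(w * x * y) / np.sum(w * x * x))
    return j_ref * scale


def near_field_estimate(
    src: SourceParams,
    params: ChemotaxisParams,
    cfg: DomainConfig,
    alphas,
    j_out: float | None = None,
) -> pd.DataFrame:
    """Encounter estimate for a high-background plume (near-field regime).

    The chemotactically useful region around the egg is approximately a
    sphere of radius R_c(alpha) (direction-averaged).  With a background
    c_bg far above the sensing threshold, the adaptive response dims to
    v_phi |grad c| / c_bg, so gradient climbing works where the chemotactic
    turning is at least as fast as swimming past the egg; with
    |grad c| ~ excess/r this gives the threshold
    excess(R_c) = (v_h/v_phi) (c_bg + c_b).  Sperm inside follow the
    gradient straight in: t_in = (R_c - r_egg)/v_h, and
    the two-stage structure reduces to a resident volume term plus the flux
    through the sphere.  As alpha grows, R_c shrinks (near-egg concentration
    ~ 1/alpha), so the curve decreases toward the non-chemotactic ballistic
    baseline.  Columns: alpha, R_c, P_enc.
    """
    if j_out is None:
        j_out = j_out_ballistic(cfg.rho_egg, params.v_h)
    q = np.pi * cfg.r_egg**2 * params.v_h * cfg.rho_egg
    P_ball = 1.0 - np.exp(-q * cfg.t_max)
    dirs = np.concatenate([np.eye(3), -np.eye(3)])
    rows = []
    for alpha in alphas:
        flow = ShearFlow(alpha=float(alpha))
        ev = _FixedQuadEvaluator(src, flow, src.t_release)

        thresh = (params.v_h / max(params.v_phi, 1e-300)) * (src.c_bg + params.c_b)

        def excess(r):
            pts = r * dirs
            c, _ = ev(pts)
            return float(np.mean(c)) - src.c_bg - max(params.c_b, thresh)

        if excess(cfg.r_egg * 1.0000001) <= 0:
            rows.append(dict(alpha=alpha, R_c=cfg.r_egg, P_enc=P_ball))
            continue
        if excess(cfg.r_max) > 0:
            R_c = cfg.r_max
        else:
            R_c = brentq(excess, cfg.r_egg * 1.0000001, cfg.r_max, xtol=1e-8)
        t_in = (R_c - cfg.r_egg) / params.v_h
        if t_in > cfg.t_max:
            rows.append(dict(alpha=alpha, R_c=R_c, P_enc=P_ball))
            continue
        t_out = cfg.t_max - t_in
        P = (4 * np.pi / 3) * R_c**3 * cfg.rho_egg + 4 * np.pi * R_c**2 * j_out * t_out
        rows.append(dict(alpha=alpha, R_c=R_c, P_enc=min(1.0, max(P, P_ball))))
    return pd.DataFrame(rows)
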