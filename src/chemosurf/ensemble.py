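"""Monte-Carlo estimation of the sperm-egg encounter probability.

A single egg of radius ``r_egg`` sits at the origin of a spherical domain of
radius ``r_max = (4 pi rho_egg / 3)^(-1/3)``, which represents an ensemble of
eggs at number density ``rho_egg``.  Sperm cells start uniformly distributed
in the shell with isotropic helix axes, swim for an exposure time ``t_max``
or until they hit the egg, and re-enter through the boundary with
flux-weighted initial conditions when they leave:

    P_b(r, h)  ~  max(0, -[(v_ext(r) + v_h h) . e_r]) ,

i.e. the theoretical in-flux of uniform, isotropic swimmers due to active
swimming plus convection.  The encounter probability is the captured
fraction with its binomial standard deviation.

The whole ensemble is advanced in lock-step with vectorised numpy
operations; a single seeded Generator drives initialisation and re-entry, so
capture counts are bitwise reproducible for a given seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield

import numpy as np
import pandas as pd

from .agents import ChemotaxisParams, segment_capture_fraction, step_arrays
from .field import SourceParams, tabulate_field
from .flow import ShearFlow, SphereDisturbance, shear_velocity

__all__ = [
    "DomainConfig",
    "EnsembleResult",
    "r_max_from_density",
    "initialize_ensemble",
    "boundary_reentry_sample",
    "influx_rate_per_particle",
    "run_ensemble",
    "simulate_trajectories",
    "stationary_encounter",
    "sweep_alpha",
    "locate_optimum",
]


def r_max_from_density(rho_egg: float) -> float:
    """Domain radius r_max = (4 pi rho_egg / 3)^(-1/3)."""
    if rho_egg <= 0:
        raise ValueError("rho_egg must be > 0")
    return float((4.0 * np.pi * rho_egg / 3.0) ** (-1.0 / 3.0))


@dataclass
class DomainConfig:
    """Spherical simulation domain mimicking an egg ensemble of density rho_egg."""

    rho_egg: float
    r_egg: float
    t_max: float
    n_sperm: int
    seed: int = 0
    r_max: float | None = None

    def __post_init__(self) -> None:
        expected = r_max_from_density(self.rho_egg)
        if self.r_max is None:
            self.r_max = expected
        elif abs(self.r_max - expected) > 1e-9 * expected:
            raise ValueError(
                f"r_max={self.r_max} inconsistent with rho_egg "
                f"(expected {expected})"
            )
        if self.r_max <= self.r_egg:
            raise ValueError("r_max must exceed r_egg")
        if self.n_sperm < 1:
            raise ValueError("n_sperm must be >= 1")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")


@dataclass
class EnsembleResult:
    """Encounter statistics of one Monte-Carlo ensemble.

    For the direct estimator the standard deviation is the binomial SD
    sqrt(P(1-P)/n); for the stationary (transit-rate) estimator it is the
    binomial error of the per-transit capture probability propagated
    through P = 1 - exp(-lambda t_max).
    """

    alpha: float
    n_total: int
    n_captured: int
    P: float
    sd: float
    mean_capture_time: float
    estimator: str = "direct"

    def __post_init__(self) -> None:
        assert 0.0 <= self.P <= 1.0
        if self.estimator == "direct":
            assert abs(self.sd - np.sqrt(self.P * (1 - self.P) / self.n_total)) < 1e-12


def initialize_ensemble(
    cfg: DomainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial positions uniform (by volume) in the shell r_egg <= |r| <= r_max
    and isotropic helix axes.  Returns arrays (r, h) of shape (n_sperm, 3)."""
    n = cfg.n_sperm
    u = rng.uniform(size=n)
    radii = (cfg.r_egg**3 + u * (cfg.r_max**3 - cfg.r_egg**3)) ** (1.0 / 3.0)
    r_dir = _isotropic(rng, n)
    h = _isotropic(rng, n)
    return radii[:, None] * r_dir, h


def _isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def boundary_reentry_sample(
    cfg: DomainConfig,
    flow: ShearFlow,
    params: ChemotaxisParams,
    rng: np.random.Generator,
    n: int = 1,
    t: float = 0.0,
    max_batches: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (r, h) on |r| = r_max from the flux-weighted influx distribution
    by rejection against uniform-isotropic proposals.

    Every accepted sample has strictly inward total velocity
    (v_ext + v_h h) . e_r < 0.
    """
    bound = flow.alpha * cfg.r_max + params.v_h
    acc_r, acc_h = [], []
    got, proposed = 0, 0
    batch = max(4 * n, 256)
    for _ in range(max_batches):
        e_r = _isotropic(rng, batch)
        h = _isotropic(rng, batch)
        r = cfg.r_max * e_r
        s = np.einsum(
            "ij,ij->i", shear_velocity(r, flow, t) + params.v_h * h, e_r
        )
        u = rng.uniform(size=batch)
        keep = u * bound < -s
        proposed += batch
        if np.any(keep):
            acc_r.append(r[keep])
            acc_h.append(h[keep])
            got += int(keep.sum())
        if got >= n:
            break
        if proposed > 1e4 and got / proposed < 1e-4:
            raise RuntimeError(
                "boundary re-entry rejection acceptance rate < 1e-4: "
                "mis-parameterized flow"
            )
    if got < n:
        raise RuntimeError("boundary re-entry sampling failed to accept enough")
    r = np.concatenate(acc_r)[:n]
    h = np.concatenate(acc_h)[:n]
    return r, h


def _default_dt(alpha: float, params: ChemotaxisParams, sigma_min: float | None) -> float:
    """dt = min(0.05/alpha, 0.5 s, sigma_min/(4 v_h)): resolves both the flow
    rotation and the crossing of the thinnest filament."""
    dt = 0.5
    if alpha > 0:
        dt = min(dt, 0.05 / alpha)
    if sigma_min is not None:
        dt = min(dt, sigma_min / (4.0 * params.v_h))
    return dt


def run_ensemble(
    cfg: DomainConfig,
    flow: ShearFlow,
    sphere: SphereDisturbance | None,
    field,
    params: ChemotaxisParams,
    dt: float | None = None,
    t_sim: float | None = None,
    rng: np.random.Generator | None = None,
) -> EnsembleResult:
    """Simulate the full ensemble and return encounter statistics.

    ``t_sim`` (default ``t_max``) allows a shortened simulation whose capture
    rate is extrapolated to ``t_max`` assuming a stationary Poisson encounter
    process, P(t_max) = 1 - exp(-lambda t_max) with
    lambda = -ln(1 - f_captured)/t_sim.  This keeps very strong flows (where
    dt must resolve 1/alpha) tractable; with t_sim = t_max it is the plain
    captured fraction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma_min = None
    if field is not None and params.chemotaxis_on:
        sigma_min = float(np.sqrt(2.0 * field.src.D * field.t))
    if dt is None:
        dt = _default_dt(flow.alpha, params, sigma_min)
    horizon = cfg.t_max if t_sim is None else min(t_sim, cfg.t_max)
    n = cfg.n_sperm
    r, h = initialize_ensemble(cfg, rng)
    t = np.zeros(n)
    captured = np.zeros(n, dtype=bool)
    t_capture = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    if horizon <= 0 or cfg.t_max <= 0:
        return _result(flow.alpha, n, captured, t_capture, cfg, horizon)
    while np.any(active):
        idx = np.flatnonzero(active)
        dt_i = np.minimum(dt, horizon - t[idx])
        r0 = r[idx]
        r1, h1 = step_arrays(r0, h[idx], dt_i, flow, sphere, field, params)
        frac = segment_capture_fraction(r0, r1, cfg.r_egg)
        hit = frac >= 0.0
        newly = idx[hit]
        captured[newly] = True
        t_capture[newly] = t[newly] + frac[hit] * dt_i[hit]
        active[newly] = False
        r[idx] = r1
        h[idx] = h1
        t[idx] += dt_i
        done = idx[t[idx] >= horizon * (1 - 1e-12)]
        active[done] = False
        # flux-weighted re-entry for cells that left the domain
        out = np.flatnonzero(active & (np.linalg.norm(r, axis=1) >= cfg.r_max))
        if len(out):
            r_new, h_new = boundary_reentry_sample(
                cfg, flow, params, rng, n=len(out)
            )
            r[out] = r_new
            h[out] = h_new
    return _result(flow.alpha, n, captured, t_capture, cfg, horizon)


def _result(alpha, n, captured, t_capture, cfg, horizon) -> EnsembleResult:
    n_cap = int(captured.sum())
    frac = n_cap / n
    if horizon < cfg.t_max and horizon > 0:
        lam = -np.log(max(1.0 - frac, 1e-300)) / horizon
        P = 1.0 - np.exp(-lam * cfg.t_max)
    else:
        P = frac
    P = min(max(P, 0.0), 1.0)
    sd = float(np.sqrt(P * (1 - P) / n))
    mean_t = float(np.nanmean(t_capture)) if n_cap else float("nan")
    return EnsembleResult(
        alpha=alpha, n_total=n, n_captured=n_cap, P=P, sd=sd, mean_capture_time=mean_t
    )


def simulate_trajectories(
    cfg: DomainConfig,
    flow: ShearFlow,
    sphere: SphereDisturbance | None,
    field,
    params: ChemotaxisParams,
    n: int = 10,
    dt: float | None = None,
    stride: int = 1,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Integrate ``n`` cells and return sampled trajectories.

    Each entry 'traj_###' is an array with columns
    (t, x, y, z, hx, hy, hz, c), sampled every ``stride`` steps until
    capture, exit, or t_max.  Intended for inspection and export
    (io.write_trajectories), not for statistics.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma_min = None
    if field is not None and params.chemotaxis_on:
        sigma_min = float(np.sqrt(2.0 * field.src.D * field.t))
    if dt is None:
        dt = _default_dt(flow.alpha, params, sigma_min)
    sub = DomainConfig(
        rho_egg=cfg.rho_egg, r_egg=cfg.r_egg, t_max=cfg.t_max,
        n_sperm=n, seed=cfg.seed,
    )
    r, h = initialize_ensemble(sub, rng)
    t = np.zeros(n)
    active = np.ones(n, dtype=bool)
    samples: list[list[np.ndarray]] = [[] for _ in range(n)]

    def sample(idx):
        if field is not None:
            c, _ = field.evaluate(r[idx])
        else:
            c = np.zeros(len(idx))
        for j, i in enumerate(idx):
            samples[i].append(
                np.concatenate([[t[i]], r[i], h[i], [np.atleast_1d(c)[j]]])
            )

    step_no = 0
    sample(np.flatnonzero(active))
    while np.any(active):
        idx = np.flatnonzero(active)
        dt_i = np.minimum(dt, cfg.t_max - t[idx])
        r1, h1 = step_arrays(r[idx], h[idx], dt_i, flow, sphere, field, params)
        frac = segment_capture_fraction(r[idx], r1, cfg.r_egg)
        hit = frac >= 0.0
        active[idx[hit]] = False
        r[idx] = r1
        h[idx] = h1
        t[idx] += dt_i
        active[idx[t[idx] >= cfg.t_max * (1 - 1e-12)]] = False
        active[np.linalg.norm(r, axis=1) >= cfg.r_max] = False
        step_no += 1
        if step_no % stride == 0:
            keep = np.flatnonzero(active)
            if len(keep):
                sample(keep)
    return {f"traj_{i:03d}": np.array(s) for i, s in enumerate(samples)}


def influx_rate_per_particle(
    cfg: DomainConfig,
    flow: ShearFlow,
    params: ChemotaxisParams,
    rng: np.random.Generator | None = None,
    n: int = 400000,
    t: float = 0.0,
) -> float:
    """Boundary-crossing rate per domain particle for a uniform isotropic
    population: (A/V) <max(0, -(v_ext + v_h h).e_r)> (Monte-Carlo average)."""
    if rng is None:
        rng = np.random.default_rng(0)
    e_r = _isotropic(rng, n)
    h = _isotropic(rng, n)
    r = cfg.r_max * e_r
    s = np.einsum("ij,ij->i", shear_velocity(r, flow, t) + params.v_h * h, e_r)
    mean_influx = float(np.mean(np.maximum(0.0, -s)))
    area = 4.0 * np.pi * cfg.r_max**2
    vol = (4.0 * np.pi / 3.0) * (cfg.r_max**3 - cfg.r_egg**3)
    return area * mean_influx / vol


def stationary_encounter(
    cfg: DomainConfig,
    flow: ShearFlow,
    sphere: SphereDisturbance | None,
    params: ChemotaxisParams,
    rng: np.random.Generator | None = None,
    dt: float | None = None,
    t_cap: float | None = None,
    n: int | None = None,
) -> EnsembleResult:
    """Encounter probability from the stationary capture rate.

    ``n_sperm`` particles are injected at the domain boundary from the
    flux-weighted influx distribution and followed for a single transit
    (until capture or exit).  The per-particle capture rate is
    lambda = Phi * p_cap with Phi the boundary-crossing rate of a uniform
    isotropic population, and P(t_max) = 1 - exp(-lambda t_max).

    In still water this reduces exactly to the ballistic swept-volume law
    1 - exp(-q t) with q = pi r_egg^2 v_h rho_egg.  At strong shear it
    cleanly measures the collapse of the encounter rate without the
    finite-time transient of cells that start adjacent to the egg.  Far
    from the egg (no disturbance, no signal) the equations of motion are
    integrated with large adaptive steps, exact for ballistic motion in
    linear shear; near the egg the step resolves the rotation time 1/alpha.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if params.chemotaxis_on:
        raise ValueError("stationary_encounter is for ballistic (chemotaxis-off) runs")
    phi = influx_rate_per_particle(cfg, flow, params, rng)
    n = int(n if n is not None else cfg.n_sperm)
    r, h = boundary_reentry_sample(cfg, flow, params, rng, n=n)
    # nudge inward so the exit test does not trigger immediately
    r *= 1.0 - 1e-9
    dt_fine = dt if dt is not None else _default_dt(flow.alpha, params, None)
    if t_cap is None:
        # generous for swim-dominated transits; convection-dominated ones are
        # far shorter anyway
        t_cap = min(cfg.t_max, max(5.0 * cfg.r_max / params.v_h, 10.0 * dt_fine))
    a = cfg.r_egg
    adaptive = not params.corotation_on
    t = np.zeros(n)
    captured = np.zeros(n, dtype=bool)
    t_capture = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    while np.any(active):
        idx = np.flatnonzero(active)
        r0 = r[idx]
        if adaptive:
            speed = (
                np.linalg.norm(shear_velocity(r0, flow), axis=1) + params.v_h
            )
            rn = np.linalg.norm(r0, axis=1)
            dt_i = np.maximum(dt_fine, 0.5 * (rn - 3.0 * a) / speed)
        else:
            dt_i = np.full(len(idx), dt_fine)
        dt_i = np.minimum(dt_i, t_cap - t[idx])
        r1, h1 = step_arrays(r0, h[idx], dt_i, flow, sphere, None, params)
        frac = segment_capture_fraction(r0, r1, a)
        hit = frac >= 0.0
        newly = idx[hit]
        captured[newly] = True
        t_capture[newly] = t[newly] + frac[hit] * dt_i[hit]
        active[newly] = False
        r[idx] = r1
        h[idx] = h1
        t[idx] += dt_i
        # transit over: left the domain or exceeded the time cap
        gone = (np.linalg.norm(r[idx], axis=1) >= cfg.r_max) | (
            t[idx] >= t_cap * (1 - 1e-12)
        )
        active[idx[gone & ~hit]] = False
    n_cap = int(captured.sum())
    p_cap = n_cap / n
    lam = phi * p_cap
    P = float(np.clip(1.0 - np.exp(-lam * cfg.t_max), 0.0, 1.0))
    # binomial error on p_cap propagated through the exponential
    sd_p = np.sqrt(max(p_cap * (1 - p_cap), 1.0 / n) / n)
    sd = float(cfg.t_max * np.exp(-lam * cfg.t_max) * phi * sd_p)
    mean_t = float(np.nanmean(t_capture)) if n_cap else float("nan")
    return EnsembleResult(
        alpha=flow.alpha,
        n_total=n,
        n_captured=n_cap,
        P=P,
        sd=sd,
        mean_capture_time=mean_t,
        estimator="stationary",
    )


def sweep_alpha(
    cfg: DomainConfig,
    alphas,
    params: ChemotaxisParams,
    src: SourceParams | None = None,
    sphere: SphereDisturbance | None = None,
    dt: float | None = None,
    t_sim=None,
    tab_kwargs: dict | None = None,
    method: str = "direct",
    log=None,
) -> pd.DataFrame:
    """Run the ensemble at each shear rate; returns a table with columns
    alpha, n, captured, P, sd, mean_capture_time.

    A fresh chemoattractant field is tabulated per alpha when chemotaxis is
    on.  Each alpha uses an independent RNG stream derived from
    (cfg.seed, index) so the sweep is reproducible point by point.
    """
    alphas = list(alphas)
    if len(alphas) < 4:
        raise ValueError("sweep requires at least 4 shear rates")
    rows = []
    for i, alpha in enumerate(alphas):
        flow = ShearFlow(alpha=float(alpha))
        field = None
        if params.chemotaxis_on and src is not None:
            field = tabulate_field(src, flow, src.t_release, **(tab_kwargs or {}))
        rng = np.random.default_rng([cfg.seed, i])
        if method == "stationary":
            res = stationary_encounter(cfg, flow, sphere, params, rng=rng, dt=dt)
        else:
            ts = t_sim(alpha) if callable(t_sim) else t_sim
            res = run_ensemble(
                cfg, flow, sphere, field, params, dt=dt, t_sim=ts, rng=rng
            )
        if log is not None:
            log(f"alpha={alpha:g}: captured {res.n_captured}/{res.n_total} "
                f"P={res.P:.3g} +- {res.sd:.2g}")
        rows.append(
            dict(
                alpha=res.alpha,
                n=res.n_total,
                captured=res.n_captured,
                P=res.P,
                sd=res.sd,
                mean_capture_time=res.mean_capture_time,
            )
        )
    return pd.DataFrame(rows)


def locate_optimum(table: pd.DataFrame) -> dict:
    """Argmax of P(alpha) with the local grid spacing as uncertainty.

    Returns dict(alpha_star, P_star, uncertainty, at_boundary).  Raises if
    all capture counts are zero (optimum undefined)."""
    tab = table.sort_values("alpha").reset_index(drop=True)
    if (tab["captured"] == 0).all():
        raise ValueError("optimum undefined: no captures at any shear rate")
    i = int(tab["P"].idxmax())
    alphas = tab["alpha"].to_numpy()
    at_boundary = i == 0 or i == len(tab) - 1
    if at_boundary:
        unc = abs(alphas[min(i + 1, len(tab) - 1)] - alphas[max(i - 1, 0)])
    else:
        unc = 0.5 * (alphas[i + 1] - alphas[i - 1])
    return dict(
        alpha_star=float(alphas[i]),
        P_star=float(tab["P"][i]),
        uncertainty=float(unc),
        at_boundary=bool(at_boundary),
    )
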