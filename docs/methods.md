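# Methods

## Model

A single spherical egg of radius `r_egg` sits at the origin of a co-moving
frame. The ambient flow is a simple shear `v(r) = α (r·e_y) e_x`; the egg,
being torque-free, spins at half the ambient vorticity and adds the
classical Stokes disturbance of a rigid sphere in linear flow (no-slip on
the surface, stresslet decay ∝ r⁻²). An optional *unsteady* mode lets the
shear triad undergo isotropic rotational Brownian motion with diffusivity
`D_rot`, mimicking how gametes below the Kolmogorov scale perceive
turbulence as shear of slowly wandering orientation.

The egg releases chemoattractant at constant rate `Qdot`. Because the flow
is linear, each released parcel remains exactly Gaussian; its covariance
obeys `Ċ = AC + CAᵀ + 2D·I`, with the steady-shear closed form
`C_yy = C_zz = 2Dτ`, `C_xy = Dατ²`, `C_xx = 2Dτ(1 + α²τ²/3)`. The
continuous-release field is the time integral of these Gaussians plus a
uniform background `c_bg`; gradients are obtained by differentiating the
Gaussian under the integral. The reference case evaluates the static field
at release time equal to the exposure time `t_max`.

Sperm cells are reduced to their helix axis `h`: they swim at `v_h` along
`h`, are advected by the flow, optionally co-rotate via the Jeffery
equation with effective aspect ratio `g`, and align `h` with the local
gradient at rate `v_φ |∇c| sinΨ/(c + c_b)` — the sensory-adaptation
normalisation makes the response depend on relative, not absolute,
concentration changes, down to the threshold `c_b`. The helix itself can
be decorated back onto the axis trajectory (`helical_overlay`, radius
`r0`); the dynamics samples the field at the centreline.

Encounters are estimated in a spherical domain of radius
`r_max = (4πρ_egg/3)^(−1/3)` that represents an egg ensemble of density
`ρ_egg`: positions start uniform in the shell, axes isotropic, and cells
leaving the domain re-enter with flux-weighted initial conditions
`P_b(r,h) ∝ max(0, −(v_ext + v_h h)·e_r)` drawn by rejection sampling.

## Parameters

| parameter | unit | fig2_arbacia | fig3_rufescens | fig4_purpuratus |
|---|---|---|---|---|
| shear rate α (sweep variable) | 1/s | 0–1.2 | 0–10 | 0–1000 |
| release rate Qdot | fmol/min | **0.46** | 0.6 | 0.46 |
| diffusivity D | μm²/s | 239 | 660 | 239 |
| exposure/release time t_max | min | **6** | 2 | 2 |
| background c_bg | nM | 0 | **4** | **2000** |
| swim speed v_h | μm/s | 160 | 150 | 80 |
| response parameter v_φ | μm/s | 400 | 300 | — (off) |
| adaptation threshold c_b | pM | 10 | 10 | — |
| helix radius r0 | μm | **7** | 7 | 7 |
| aspect ratio g | – | **5** | 5 | **5** |
| egg radius r_egg | μm | 50 | 100 | 50 |
| egg density ρ_egg | 1/m³ | 1000 | 2·10⁸ | 5·10⁹ |
| sperm density ρ_sperm | 1/m³ | 10⁵ | 2·10⁹ | 1.5·10¹¹ |
| fertilizability p_f | – | 0.1 | **0.6** | **0.1** |

Bold values are printed in the study being modelled; the rest are
reconstructed (tagged per-parameter in the preset files). The
reconstruction is anchored on printed *derived* quantities: `ρ_egg·v_h/4`
must equal the printed ballistic fluxes (0.04 m⁻²s⁻¹ and 7.5·10³ m⁻²s⁻¹),
and for the strong-flow scenario `2πv_h/(0.1 r_egg)` must reproduce the
printed ~100 s⁻¹ drop scale. The two chemotaxis-response parameters
(`v_φ`, `c_b`), for which no value is printed anywhere, were calibrated
once against the printed headline observables of the sea-urchin scenario
(interior optimum near 0.1 s⁻¹ with ~4-fold enhancement over still water;
chemotaxis less effective than still water only above ~0.3 s⁻¹) and then
frozen. `c_b = 10 pM` sits in the upper range of reported chemoattractant
sensitivities; `v_φ = 400 μm/s = 2.5 v_h` is an *effective* alignment-rate
scale, not a translational speed — inward spiralling in a radial far field
formally requires `v_φ > v_h` in this coarse-grained law.

## Estimators

Three encounter estimators are provided, all reporting binomial (or
propagated) standard deviations:

1. **Direct** (`run_ensemble`): the captured fraction of `n_sperm`
   trajectories integrated for `t_max` — the default for chemotactic runs.
   Explicit midpoint steps with `dt = min(0.05/α, 0.5 s, σ_min/(4 v_h))`
   resolve both the flow rotation and the thinnest filament crossing;
   capture uses sub-step linear interpolation of the trajectory segment
   against the egg sphere, so cells cannot tunnel through the egg. An
   optional shortened horizon extrapolates via a Poisson rate.
2. **Stationary transit rate** (`stationary_encounter`), for ballistic
   (chemotaxis-off) runs: particles are injected from the boundary-influx
   distribution and followed for one domain transit; the capture rate is
   `λ = Φ·p_cap` with `Φ` the boundary-crossing rate of a uniform
   isotropic population, and `P(t_max) = 1 − exp(−λ t_max)`. In still
   water this reduces *exactly* to the swept-volume law
   `1 − exp(−π r_egg² v_h ρ_egg t)`. Far from the egg the ballistic-in-
   shear motion is integrated exactly by the midpoint rule, so steps adapt
   to the distance; only the near-egg region uses `dt ≈ 0.05/α`.
3. **Eddy-lifetime cap** for strong turbulence: perfectly *steady* shear
   supports an unphysical capture channel — rare entries near the
   zero-velocity shear plane meander for many seconds and always reach the
   egg, so the steady-state rate never collapses however strong the flow.
   Real small-scale turbulence decorrelates on the Burgers-vortex decay
   time ≈ 25/α, so no such configuration persists. Strong-flow runs
   therefore cap each encounter attempt at `min(t_max, 25/α)`; this keeps
   the fast boundary-layer channel (crossing δ ~ 0.1 r_egg within the
   half-rotation time 2π/α) and removes the steady-shear artifact. With
   this cap the ballistic curve is flat at the closed form up to α ≈ 3 s⁻¹
   and fully collapsed above ~30–100 s⁻¹; the collapse completes somewhat
   below the 2πv_h/(0.1 r_egg) ≈ 100 s⁻¹ scale estimate.

The ensemble is advanced as vectorised arrays with a single seeded
`numpy.random.Generator` (initialisation and re-entry draws in a fixed
order), so capture counts are bitwise reproducible for a given seed and
configuration; there is no thread-level nondeterminism.

## Field tabulation

Direct evaluation integrates the Gaussian propagator over parcel age with
Gauss–Legendre nodes on logarithmically growing panels (reference:
adaptive quadrature, relative tolerance 1e-8; the two agree to ~1e-12).
For ensemble runs the field and its analytic gradient are tabulated on a
sinh-stretched rectilinear grid (241×145×145 by default, extents set by
the dispersion scales 6√C_xx and 8√(2Dt)), exploiting the point symmetry
c(x,y,z) = c(−x,−y,z) = c(x,y,−z). Trilinear interpolation reproduces
direct quadrature within 1% at random points above a concentration floor
(`validate()` enforces this); within 1.5 mm of the egg, where the field is
steep, evaluation falls back to direct quadrature, and outside the grid
the field is the uniform background.

## Filament fit and theory

For each sampled axial position x > 0 the cross-section maximum locates
the centreline offset y₀(x); a weighted least-squares fit of ln c over the
(y,z) patch gives σ(x) and the anisotropy a_y; an exponential fit along
the ridge gives c₀ and k (residual rms reported — the true axial profile
is only approximately exponential, log-residuals ≈ 0.35). Fits use
|x| within [5 r_egg, ~2.5√C_xx], where the filament form is valid. The
fitted parameters obey the scaling laws 1/k ∝ α (exponent 1.00 ± 0.02),
c₀ ∝ 1/α (−0.99 ± 0.02), σ flat within a few percent across a decade
of α.

Linearising the alignment law inside the filament gives the transverse
oscillation frequency ω = √(v_h v_φ)/σ and axial damping rate v_φ k,
hence the surfing parameter

    γ = K · k σ √(v_φ / v_h),

with one dimensionless calibration constant K. `calibrate_gamma` measures
the log-decrement of surfing oscillations in a full agent simulation
(K ≈ 0.7 for the sea-urchin scenario at α = 0.1); calibrated once, the
predicted damping at other shear rates matches simulation within a few
percent. The oscillator itself has log-decrement πγ per cycle (verified to
<1%).

The encounter integral uses the criterion-mode inner search by default:
p_in = 1 where the filament is wide enough for the first chemotactic turn
(L = ln(c₀e^{−k|x|}/c_b) ≥ v_h/v_φ, i.e. the turning radius at the
level-set edge fits inside the half-width) and the surf time
t_in = |x|/v_surf fits in t_max, with v_surf = v_h·J₀(θ_max) the
axial projection at the oscillation pitch amplitude. A Monte-Carlo mode
integrates full agent dynamics from level-set entry states instead. The
x-integral runs over 400 uniform points with |x| < 2 r_egg excluded
(far-field validity); j_out defaults to the ballistic flux ρ_egg v_h/4 and
can be fitted to a simulated curve by a least-squares scale.

For the high-background (near-field) regime the filament theory does not
apply; `near_field_estimate` finds the radius R_c where the
direction-averaged excess concentration equals (v_h/v_φ)(c_bg + c_b) — the
point where the adaptively dimmed turning just outruns swimming past the
egg — and evaluates the two-stage structure on that sphere, flooring at
the non-chemotactic ballistic baseline.

## What the scenarios do and do not emulate

The presets define the study conditions (densities, rates, exposure times
above); they emulate a *single* egg in an unbounded shear with periodic
flux re-entry. Not represented: multiple explicitly resolved eggs,
sperm–sperm interaction and polyspermy, chemokinesis (speed regulation),
chemoattractant degradation or egg-surface absorption, field distortion by
the egg's flow disturbance (the propagator stays exact; the disturbance
decays within a few egg radii), flow modulation of the flagellar beat, and
fully developed turbulence (steady or Brownian-frame shear only). Passing
tests therefore validate the model chain under these idealised conditions,
not field measurements.

## Numerical choices and degenerate inputs

- Adaptive quadrature failure raises with diagnostics; fixed-node panels
  start at τ₀ = r_egg²/(150 D) (earlier ages contribute e^{−40} at the
  clamp radius).
- Positions inside the egg are clamped to its surface for field and
  velocity evaluation (a warning is issued on the public field API).
- `h` is renormalised after every step; drift without renormalisation is
  < 1e-8 per 10⁴ RK4 steps over a Jeffery orbit.
- Empty level sets return zero area/circumference rather than erroring;
  an all-zero sweep makes the optimum undefined (raises).
- The denominator c + c_b never vanishes since c_b > 0.
- Rejection sampling aborts if the acceptance rate falls below 1e-4
  (mis-parameterised flow).
- Sweep points use independent RNG streams seeded as (seed, index).

## Known limitations

- The exact dimensionless prefactor of γ and the supplement-level
  power-law exponents of the filament parameterisation are reconstructed
  by fitting, not transcribed; the fit-based route reproduces the printed
  α-scalings but individual prefactors carry a calibration constant.
- The steady-shear strong-flow artifact described above means ballistic
  high-α results are only meaningful with the eddy-lifetime cap.
- The unsteady-shear mode is exploratory: concentration fields under a
  Brownian frame are computed exactly via the deformation-gradient
  integral but are not tabulated, so full unsteady ensembles are slow.
- With co-rotation enabled the strong-flow collapse moves to much smaller
  α (~3 s⁻¹): Jeffery tumbling destroys the coherent inward swimming that
  crossing the boundary layer requires. Strong-flow presets default to
  co-rotation off.
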