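# chemosurf

Agent-based simulation and analytical theory of **sperm chemotaxis in
small-scale turbulent shear flow**.

Marine invertebrates with external fertilization (sea urchins, abalone)
release sperm and egg cells directly into the sea. Turbulence mixes the
gametes down to the Kolmogorov scale (1–10 mm); below that scale the flow
acts as a simple shear, which stretches the chemoattractant cloud released
by each egg into a long, thin **concentration filament** and convects and
co-rotates the swimming sperm cells. Sperm perform helical chemotaxis: the
helix axis **h** aligns with the local gradient at a rate proportional to
the adaptively normalised gradient,

    dΨ/dt = −v_φ |∇c| sin Ψ / (c + c_b),     Ψ = ∠(∇c, h),

so a cell that finds a filament "surfs" along it toward the egg in a damped
oscillation. Stronger flow makes filaments longer (decay length 1/k ∝ α)
but effectively thinner (base concentration c₀ ∝ 1/α at flow-independent
cross-section σ), and these opposing effects produce an **optimal shear
rate α\*** at which the sperm–egg encounter probability is maximal.

The package provides:

- exact advection–diffusion fields for a continuously releasing source in
  linear shear (Gaussian-moment propagators, closed-form covariance
  C_xx = 2Dτ(1+α²τ²/3), C_xy = Dατ², C_yy = C_zz = 2Dτ), with fast
  validated tabulation and analytic gradients;
- the classical Stokes flow around a freely rotating spherical egg in shear
  and Jeffery co-rotation of prolate swimmers (aspect ratio g);
- a vectorised Monte-Carlo ensemble in a spherical domain of radius
  r_max = (4πρ_egg/3)^(−1/3) with flux-weighted boundary re-entry,
  P_b(r,h) ∝ max(0, −(v_ext + v_h h)·e_r);
- the filament-surfing theory: the surfing oscillator
  Ÿ = (−(1−Ẏ²)Y ± γ(1−Ẏ²)Ẏ)·c/(c+c_b), the fitted filament form
  c = c₀ e^{−k|x|} exp(−((y−y₀)²/a_y² + z²)/2σ²), level-set geometry
  A(x), S(x), and the two-stage encounter integral
  P = ∫ dx p_in(x) [A(x)ρ_egg + S(x) j_out t_out(x)];
- fertilization kinetics P_fert = 1 − exp(−p_f P ρ_sperm/ρ_egg) and the
  strong-flow ballistic limit with its collapse above α ~ 2πv_h/(0.1 r_egg).

Three scenario presets ship with the package: `fig2_arbacia` (sea urchin
*Arbacia punctulata*, natural spawning conditions — the optimal-shear-rate
study), `fig3_rufescens` (red abalone *Haliotis rufescens* in a
Taylor-Couette chamber with high chemoattractant background), and
`fig4_purpuratus` (sea urchin *Strongylocentrotus purpuratus* in strong
surf-zone turbulence, chemotaxis ineffective). See `docs/methods.md` for
the model details and parameter provenance.

## Worked example

The analytical theory curve for the sea-urchin scenario (deterministic,
runs in a few seconds):

```python
import chemosurf as cs

sc = cs.load_scenario("fig2_arbacia")
tab = cs.theory_curve([0.03, 0.06, 0.1, 0.15, 0.2, 0.3, 0.45, 0.9],
                      sc.source(), sc.domain(), sc.chemotaxis())
print(tab)
```

```
   alpha     gamma  P_theory         V_tot
0   0.03  0.588884  0.000690  2.255794e-08
1   0.06  0.298658  0.001075  3.525366e-08
2   0.10  0.179284  0.001400  4.716539e-08
3   0.15  0.119497  0.001636  5.832039e-08
4   0.20  0.089627  0.001760  6.703564e-08
5   0.30  0.059750  0.001784  8.006883e-08
6   0.45  0.039837  0.001682  9.316732e-08
7   0.90  0.019918  0.001419  1.113809e-07
```

The chemotactic volume `V_tot` (m³) grows monotonically with shear rate,
yet the predicted encounter probability `P_theory` peaks at α ≈ 0.2–0.3 s⁻¹
and falls again — the optimum is set by filament *geometry* (the surfing
parameter `gamma` decreasing as filaments grow longer and thinner), not by
plume volume. The corresponding Monte-Carlo simulation (green-triangle
analogue; ~7 min at 20 000 trajectories per point):

```sh
chemosurf simulate --scenario fig2_arbacia \
    --alphas 0,0.03,0.06,0.1,0.15,0.2,0.45,0.9 --n 20000 --seed 42 \
    --out results.csv
chemosurf theory --scenario fig2_arbacia \
    --alphas 0.03,0.06,0.1,0.15,0.2,0.45,0.9 --jout fit:results.csv \
    --out theory.csv
chemosurf report --results results.csv --theory theory.csv --out report.png
```

A `simulate` run with seed 42 prints per-point capture counts such as
`alpha=0.1: captured 30/20000 P=0.0015 +- 0.00027` and
`alpha=0: captured 10/20000 P=0.0005 +- 0.00016`: an interior maximum on
the 0.1–0.2 s⁻¹ plateau, roughly four-fold above still water, while
without chemotaxis (`--no-chemotaxis`) the encounter probability stays
below 10⁻⁵.

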