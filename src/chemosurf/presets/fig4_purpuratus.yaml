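# Sea urchin Strongylocentrotus purpuratus in strong turbulence (surf-zone
# conditions): high egg density, very high chemoattractant background
# (500-4000 nM) that renders chemotaxis ineffective -- chemotaxis is off and
# encounters are purely mechanical (swimming + convection + co-rotation).
# Printed anchors: drop of fertilization above alpha ~ 100 1/s, consistent
# with 2*pi*v_h/(0.1*r_egg); fertilizability p_f = 10%;
# alpha(eps) = a*sqrt(eps/nu) with fitted a = 0.075.
name: fig4_purpuratus
flow:
  alpha: {value: 100.0, unit: "1/s", provenance: paper-printed}
  unsteady: false
  D_rot: {value: 0.0, unit: "rad^2/s", provenance: reconstructed}
  sphere_enabled: true
source:
  Qdot: {value: 0.46, unit: "fmol/min", provenance: reconstructed}
  D: {value: 239.0, unit: "um^2/s", provenance: reconstructed}
  t_release: {value: 2.0, unit: "min", provenance: reconstructed}
  c_bg: {value: 2000.0, unit: "nM", provenance: paper-printed}
chemotaxis:
  v_h: {value: 80.0, unit: "um/s", provenance: reconstructed}
  v_phi: {value: 0.0, unit: "um/s", provenance: reconstructed}
  c_b: {value: 1.0, unit: "pM", provenance: reconstructed}
  r0: {value: 7.0, unit: "um", provenance: reconstructed}
  g: {value: 5.0, unit: "", provenance: paper-printed}
  chemotaxis_on: false
  corotation_on: false
domain:
  rho_egg: {value: 5000000000.0, unit: "1/m^3", provenance: reconstructed}
  r_egg: {value: 50.0, unit: "um", provenance: reconstructed}
  t_max: {value: 2.0, unit: "min", provenance: reconstructed}
  n_sperm: 10000
kinetics:
  p_f: {value: 0.1, unit: "", provenance: paper-printed}
  rho_sperm: {value: 150000000000.0, unit: "1/m^3", provenance: reconstructed}
turbulence:
  nu: {value: 0.000001, unit: "m^2/s", provenance: reconstructed}
  a: {value: 0.075, unit: "", provenance: paper-printed}
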