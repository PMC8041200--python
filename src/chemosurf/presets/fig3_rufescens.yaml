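# Red abalone Haliotis rufescens in a Taylor-Couette chamber at moderate
# shear.  The time between preparing the egg suspension and the experiment
# accumulates a chemoattractant background c_bg ~ 4 nM, orders of magnitude
# above the sensing threshold, so the chemotactically useful region is a
# small near-spherical neighbourhood of each egg (near-field regime) and no
# optimal shear rate appears.
# Printed anchors: ballistic flux rho_egg*v_h/4 = 7.5e3 m^-2 s^-1,
# c_bg ~ 4 nM, fertilizability p_f ~ 60%.
name: fig3_rufescens
flow:
  alpha: {value: 0.5, unit: "1/s", provenance: reconstructed}
  unsteady: false
  D_rot: {value: 0.0, unit: "rad^2/s", provenance: reconstructed}
  sphere_enabled: true
source:
  Qdot: {value: 0.6, unit: "fmol/min", provenance: reconstructed}
  D: {value: 660.0, unit: "um^2/s", provenance: reconstructed}
  t_release: {value: 2.0, unit: "min", provenance: reconstructed}
  c_bg: {value: 4.0, unit: "nM", provenance: paper-printed}
chemotaxis:
  v_h: {value: 150.0, unit: "um/s", provenance: reconstructed}
  v_phi: {value: 300.0, unit: "um/s", provenance: reconstructed}
  c_b: {value: 0.01, unit: "nM", provenance: reconstructed}
  r0: {value: 7.0, unit: "um", provenance: reconstructed}
  g: {value: 5.0, unit: "", provenance: reconstructed}
  chemotaxis_on: true
  corotation_on: false
domain:
  rho_egg: {value: 200000000.0, unit: "1/m^3", provenance: reconstructed}
  r_egg: {value: 100.0, unit: "um", provenance: reconstructed}
  t_max: {value: 2.0, unit: "min", provenance: reconstructed}
  n_sperm: 10000
kinetics:
  p_f: {value: 0.6, unit: "", provenance: paper-printed}
  rho_sperm: {value: 2000000000.0, unit: "1/m^3", provenance: reconstructed}
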