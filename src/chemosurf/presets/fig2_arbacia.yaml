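# Sea urchin Arbacia punctulata in its natural spawning habitat:
# low egg density, 6 min exposure, continuous chemoattractant (resact-like
# peptide) release.  The scenario with an optimal shear rate near 0.1 1/s.
#
# provenance: 'paper-printed'  = printed in the main text of the study modelled
#             'reconstructed'  = chosen here, consistent with printed derived
#                                quantities (e.g. rho_egg*v_h/4 = 0.04 m^-2 s^-1)
#                                and literature ranges
name: fig2_arbacia
flow:
  alpha: {value: 0.1, unit: "1/s", provenance: paper-printed}
  unsteady: false
  D_rot: {value: 0.0, unit: "rad^2/s", provenance: reconstructed}
  sphere_enabled: true
source:
  Qdot: {value: 0.46, unit: "fmol/min", provenance: paper-printed}
  D: {value: 239.0, unit: "um^2/s", provenance: reconstructed}
  t_release: {value: 6.0, unit: "min", provenance: paper-printed}
  c_bg: {value: 0.0, unit: "nM", provenance: reconstructed}
chemotaxis:
  v_h: {value: 160.0, unit: "um/s", provenance: reconstructed}
  v_phi: {value: 400.0, unit: "um/s", provenance: reconstructed}
  c_b: {value: 0.01, unit: "nM", provenance: reconstructed}
  r0: {value: 7.0, unit: "um", provenance: paper-printed}
  g: {value: 5.0, unit: "", provenance: paper-printed}
  chemotaxis_on: true
  corotation_on: true
domain:
  rho_egg: {value: 1000.0, unit: "1/m^3", provenance: reconstructed}
  r_egg: {value: 50.0, unit: "um", provenance: reconstructed}
  t_max: {value: 6.0, unit: "min", provenance: paper-printed}
  n_sperm: 20000
kinetics:
  p_f: {value: 0.1, unit: "", provenance: reconstructed}
  rho_sperm: {value: 100000.0, unit: "1/m^3", provenance: reconstructed}
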