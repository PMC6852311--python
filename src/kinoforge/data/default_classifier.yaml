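# Default conformational-classifier configuration (version 1).
#
# The alphaC thresholds (4.0 / 8.5 angstrom, 100 degrees) follow the
# published Lys-Glu salt-bridge rules.  The A-loop and P-loop intervals and
# the DFG pseudodihedral intervals are package defaults chosen from
# kinase-domain structural conventions; they are deliberately configuration,
# not code, and users with access to curated labelled structures can refit
# them with scripts/calibrate_classifier.py.
#
# Angular intervals are [lo, hi] in degrees, closed at both ends; an
# interval with lo > hi wraps through 180/-180.  Distances are in angstrom.
version: 1
dfg:
  in_interval: [-150.0, -30.0]
  out_interval: [30.0, 150.0]
  # atom quadruple for the DFG pseudodihedral; "centroid:" averages atoms
  quadruple:
    - {ref_offset: -1, atom: CA}
    - {ref_offset: 0, atom: CA}
    - {ref_offset: 0, atom: CG}
    - {ref_offset: 0, centroid: [OD1, OD2]}
alphac:
  d_in_max: 4.0
  d_out_min: 8.5
  chi_inter_max: 100.0
  glu_chi_index: 1
ploop:
  min_conditions: 3
  classes:
    collapsed:
      psi_gmotif_m1: [-80.0, 0.0]
      psi_gmotif_p1: [-80.0, 0.0]
      xi_gmotif_p1_p2: [-120.0, 0.0]
      d_phi_hrd_p4: [6.0, 16.0]
    stretched:
      psi_gmotif_m1: [90.0, 180.0]
      psi_gmotif_p1: [90.0, 180.0]
      xi_gmotif_p1_p2: [60.0, 180.0]
      d_phi_hrd_p4: [18.0, 30.0]
aloop:
  classes:
    closed_type2:
      xi_dfg_m1_d: [30.0, 150.0]
      xi_dfg_f_g: [-150.0, -30.0]
      d_hrd_m4_dfg_p3: [5.0, 17.0]
    open_dfg_out:
      xi_dfg_m1_d: [-150.0, -30.0]
      xi_dfg_f_g: [30.0, 150.0]
      d_hrd_m4_dfg_p3: [19.0, 30.0]
    closed_a_under_p:
      xi_dfg_m1_d: [30.0, 150.0]
      xi_dfg_f_g: [30.0, 150.0]
      d_hrd_m4_dfg_p3: [5.0, 17.0]
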