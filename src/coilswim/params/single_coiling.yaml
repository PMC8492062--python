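# Single coiling model (~17-24 hpf): rostral IC pacemaker kernel drives ipsilateral
# chains of MNs and V0ds through gap junctions; V0ds send glycinergic projections
# across the midline. One model somite stands for three biological somites.
model: single_coiling
n_somites: 10
somite_length: 1.6          # a.d.u.
cv: 4.0                     # a.d.u./ms conduction speed
dt: 0.1                     # ms

populations:
  IC:
    count: 5
    izhikevich: {a: 0.0005, b: 0.5, c: -30.0, d: 5.0, vmax: 0.0, vr: -60.0, vt: -45.0, k: 0.05, C: 50.0}
    position: {offset: 1.0, spacing: 0.0}    # rostral kernel, all at x = 1.0
    drive: {left: 50.0, right: 0.0, onset: 0.0}
  MN:
    count: 10
    izhikevich: {a: 0.5, b: 0.1, c: -50.0, d: 0.2, vmax: 10.0, vr: -60.0, vt: -45.0, k: 0.05, C: 20.0}
    position: {offset: 5.0, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}
  V0d:
    count: 10
    izhikevich: {a: 0.5, b: 0.01, c: -50.0, d: 0.2, vmax: 10.0, vr: -60.0, vt: -45.0, k: 0.05, C: 20.0}
    position: {offset: 5.0, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}

synapse:
  e_glut: 0.0
  e_gly: -45.0               # depolarized chloride at this stage
  tau_r: 0.5
  tau_f: 1.0
  v_thr: -15.0

gap_weights:                 # symmetric conductance scales
  IC_IC: 0.001
  IC_MN: 0.04
  IC_V0d: 0.05
  MN_MN: 0.1
  V0d_V0d: 0.04
  MN_V0d: 0.01

chem_weights:
  V0d_MN: 0.3                # glycinergic, contralateral, i-5..i+5
  V0d_IC: 0.3                # glycinergic, all contralateral ICs
  MN_Muscle: 0.015

gap_rules:
  ic_block: 4                # each IC couples the first N somites of each ipsilateral chain
  neighbor_extent: 3         # +/- nearest neighbors within and across chains

chem_rules:
  v0d_extent: 5              # i-5..i+5 for V0d -> contralateral MN

muscle: {R: 25.0, C: 10.0}

body:
  somites_per_muscle: 3      # biological somites per muscle cell (reporting only)
  segment_length: 1.0        # a.d.u. per midline link
  zeta: 1.0                  # damping ratio (critically damped)
  omega0: 0.6                # rad/ms natural frequency; bandwidth well above drive
  gain: 300.0                # forcing gain, calibrated for ~1 s full coils
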