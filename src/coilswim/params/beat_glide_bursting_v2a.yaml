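# Beat-and-glide variant with bursting V2as: V2as take the chattering parameter
# set (and a slightly larger tonic drive); V0vs fire tonically. Synapse weights
# from V2as are reduced and commissural weights onto V2as increased.
model: beat_glide_bursting_v2a
n_somites: 15
somite_length: 1.6
cv: 0.8
dt: 0.1
populations:
  MN:
    count: 15
    izhikevich:
      a: 0.5
      b: 0.01
      c: -55.0
      d: 100.0
      vmax: 10.0
      vr: -65.0
      vt: -58.0
      k: 0.5
      C: 20.0
    position:
      offset: 5.0
      spacing: 1.6
    drive:
      left: 0.0
      right: 0.0
      onset: 0.0
  dI6:
    count: 15
    izhikevich:
      a: 0.1
      b: 0.002
      c: -55.0
      d: 4.0
      vmax: 10.0
      vr: -60.0
      vt: -54.0
      k: 0.3
      C: 10.0
    position:
      offset: 5.1
      spacing: 1.6
    drive:
      left: 0.0
      right: 0.0
      onset: 0.0
  V0v:
    count: 15
    izhikevich:
      a: 0.1
      b: 0.002
      c: -55.0
      d: 4.0
      vmax: 10.0
      vr: -60.0
      vt: -54.0
      k: 0.3
      C: 10.0
    position:
      offset: 5.1
      spacing: 1.6
    drive:
      left: 0.0
      right: 0.0
      onset: 0.0
  V2a:
    count: 15
    izhikevich:
      a: 0.01
      b: 0.002
      c: -55.0
      d: 8.0
      vmax: 10.0
      vr: -60.0
      vt: -54.0
      k: 0.3
      C: 10.0
    position:
      offset: 5.1
      spacing: 1.6
    drive:
      left: 3.05
      right: 3.05
      onset: 0.0
  V1:
    count: 15
    izhikevich:
      a: 0.1
      b: 0.002
      c: -55.0
      d: 4.0
      vmax: 10.0
      vr: -60.0
      vt: -54.0
      k: 0.3
      C: 10.0
    position:
      offset: 7.1
      spacing: 1.6
    drive:
      left: 0.0
      right: 0.0
      onset: 0.0
synapse:
  e_glut: 0.0
  e_gly: -70.0
  tau_r: 0.5
  tau_f: 1.0
  v_thr: -15.0
gap_weights:
  MN_MN: 0.005
  dI6_MN: 0.0001
  dI6_dI6: 0.04
  V0v_MN: 0.005
  V0v_V0v: 0.05
  V2a_MN: 0.005
  V2a_V2a: 0.005
chem_weights:
  dI6_MN: 1.5
  dI6_dI6: 0.25
  dI6_V2a: 2.0
  V0v_V2a: 0.75
  V2a_MN: 0.5
  V2a_dI6: 0.75
  V2a_V0v: 0.275
  V2a_V2a: 0.3
  V2a_V1: 0.5
  V1_MN: 1.0
  V1_dI6: 0.2
  V1_V0v: 0.1
  V1_V2a: 0.5
  MN_Muscle: 0.1
gap_rules:
  neighbor_extent: 3
chem_rules:
  dI6_asc: 1
  dI6_desc: 3
  v0v_asc: 1
  v0v_desc: 3
  v2a_desc: 6
  v2a_asc: 2
  v1_asc: 2
  di6_noise_sd: 0.1
muscle:
  R: 1.0
  C: 3.0
body:
  somites_per_muscle: 2
  segment_length: 1.0
  zeta: 1.0
  omega0: 0.6
  gain: 5.0               # calibrated: tail amplitude ~1 somite length at 20-60 Hz
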