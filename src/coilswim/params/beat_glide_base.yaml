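# Beat-and-glide swimming base model (>2-3 dpf): no pacemaker kernel; rhythm arises
# from the network. V2as drive the ipsilateral circuit (tonic firing), V0vs are the
# bursting commissural excitatory population, dI6s give commissural inhibition and
# V1s ascending ipsilateral inhibition. One model somite = two biological somites.
model: beat_glide_base
n_somites: 15
somite_length: 1.6
cv: 0.8
dt: 0.1

populations:
  MN:
    count: 15
    izhikevich: {a: 0.5, b: 0.01, c: -55.0, d: 100.0, vmax: 10.0, vr: -65.0, vt: -58.0, k: 0.5, C: 20.0}
    position: {offset: 5.0, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}
  dI6:
    count: 15
    izhikevich: {a: 0.1, b: 0.002, c: -55.0, d: 4.0, vmax: 10.0, vr: -60.0, vt: -54.0, k: 0.3, C: 10.0}
    position: {offset: 5.1, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}
  V0v:
    count: 15
    izhikevich: {a: 0.01, b: 0.002, c: -55.0, d: 8.0, vmax: 10.0, vr: -60.0, vt: -54.0, k: 0.3, C: 10.0}
    position: {offset: 5.1, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}
  V2a:
    count: 15
    izhikevich: {a: 0.1, b: 0.002, c: -55.0, d: 4.0, vmax: 10.0, vr: -60.0, vt: -54.0, k: 0.3, C: 10.0}
    position: {offset: 5.1, spacing: 1.6}
    drive: {left: 2.89, right: 2.89, onset: 0.0}
  V1:
    count: 15
    izhikevich: {a: 0.1, b: 0.002, c: -55.0, d: 4.0, vmax: 10.0, vr: -60.0, vt: -54.0, k: 0.3, C: 10.0}
    position: {offset: 7.1, spacing: 1.6}   # distributed from segment 2 caudally
    drive: {left: 0.0, right: 0.0, onset: 0.0}

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
  dI6_MN: 1.5              # glycinergic, contralateral
  dI6_dI6: 0.25            # glycinergic, contralateral; scaled by Gaussian(1, 0.1)
  dI6_V2a: 1.5             # glycinergic, contralateral
  V0v_V2a: 0.4             # glutamatergic, contralateral
  V2a_MN: 0.5              # glutamatergic, ipsilateral
  V2a_dI6: 0.5
  V2a_V0v: 0.3
  V2a_V2a: 0.3
  V2a_V1: 0.5
  V1_MN: 1.0               # glycinergic, ipsilateral ascending
  V1_dI6: 0.2
  V1_V0v: 0.1
  V1_V2a: 0.5
  MN_Muscle: 0.1

gap_rules:
  neighbor_extent: 3

chem_rules:
  dI6_asc: 1               # ascending branch: segment i-1
  dI6_desc: 3              # descending branch: segments i+1..i+3
  v0v_asc: 1
  v0v_desc: 3
  v2a_desc: 6              # segments i+1..i+6 (dI6, MN, V0v, V2a, V1)
  v2a_asc: 2               # ascending to MN and V0v, segments i-1..i-2
  v1_asc: 2                # segments i-1..i-2
  di6_noise_sd: 0.1        # sd of Gaussian(1, sd) scale on dI6 -> dI6 weights

muscle: {R: 1.0, C: 3.0}

body:
  somites_per_muscle: 2
  segment_length: 1.0
  zeta: 1.0
  omega0: 0.6
  gain: 5.0               # calibrated: tail amplitude ~1 somite length at 20-60 Hz
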