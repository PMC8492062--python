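# Double coiling model (~24 hpf): the single-coiling electrical scaffold plus
# commissural excitation (V0v -> contralateral IC) and ipsilateral descending
# excitation (V2a -> V0v), forming a hybrid electrical-chemical circuit.
model: double_coiling
n_somites: 10
somite_length: 1.6
cv: 1.0
dt: 0.1

populations:
  IC:
    count: 5
    izhikevich: {a: 0.0002, b: 0.5, c: -40.0, d: 5.0, vmax: 0.0, vr: -60.0, vt: -45.0, k: 0.03, C: 50.0}
    position: {offset: 1.0, spacing: 0.0}
    drive: {left: 35.0, right: 35.0, onset: 0.0, right_onset: 1500.0}
  MN:
    count: 10
    izhikevich: {a: 0.5, b: 0.1, c: -50.0, d: 100.0, vmax: 10.0, vr: -60.0, vt: -50.0, k: 0.05, C: 20.0}
    position: {offset: 5.0, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}
  V0d:
    count: 10
    izhikevich: {a: 0.02, b: 0.1, c: -30.0, d: 3.75, vmax: 10.0, vr: -60.0, vt: -45.0, k: 0.09, C: 6.0}
    position: {offset: 5.0, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}
  V0v:
    count: 10
    izhikevich: {a: 0.02, b: 0.1, c: -30.0, d: 11.6, vmax: 10.0, vr: -60.0, vt: -45.0, k: 0.05, C: 20.0}
    position: {offset: 5.1, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}
  V2a:
    count: 10
    izhikevich: {a: 0.5, b: 0.1, c: -40.0, d: 100.0, vmax: 10.0, vr: -60.0, vt: -45.0, k: 0.05, C: 20.0}
    position: {offset: 5.1, spacing: 1.6}
    drive: {left: 0.0, right: 0.0, onset: 0.0}

synapse:
  e_glut: 0.0
  e_gly: -58.0
  tau_r: 0.5
  tau_f: 1.0
  v_thr: -15.0

gap_weights:
  IC_IC: 0.0001
  IC_MN: 0.03
  IC_V0d: 0.05
  IC_V0v: 0.0005
  MN_MN: 0.07
  V0d_V0d: 0.04
  MN_V0d: 0.0001
  V0v_V0v: 0.05
  MN_V0v: 0.0001
  V0v_V0d: 0.0            # no weight printed for this pair; override to enable
  IC_V2a: 0.15
  MN_V2a: 0.005
  V2a_V2a: 0.005

chem_weights:
  V0d_MN: 2.0             # glycinergic
  V0d_IC: 2.0             # glycinergic
  V0d_V2a: 2.0            # glycinergic
  V0v_IC: 0.175           # glutamatergic, all contralateral ICs
  V2a_V0v: 0.04           # glutamatergic, ipsilateral
  MN_Muscle: 0.02

gap_rules:
  ic_block: 4
  neighbor_extent: 3
  ic_v2a_mode: all   # 'all' or 'block' (first ic_block somites)
  ic_v2a_reciprocal: true

chem_rules:
  v0d_extent: 5           # V0d -> contralateral MN and V2a, i-5..i+5
  v2a_v0v_extent: 3       # same-segment +/- 3 (unstated in source data; configurable)

muscle: {R: 50.0, C: 5.0}

body:
  somites_per_muscle: 3
  segment_length: 1.0
  zeta: 1.0
  omega0: 0.6
  gain: 110.0
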