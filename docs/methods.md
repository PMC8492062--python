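# Methods

## Neurons and integration

All neurons are 9-parameter Izhikevich units (`a, b, c, d, Vmax, Vr, Vt, k,
C`) advanced by plain forward Euler at dt = 0.1 ms; muscle cells and body
pendulums use the same step.  Initial conditions are `V = Vr, u = 0`; the
first 200 ms of every simulation are excluded from analysis, and all
chemical synapses are silent for the first 50 ms.  Spikes are recorded at the
step where V first reaches Vmax; the stored trace is clamped at Vmax at that
sample before the reset `V ← c, u ← u + d`.  A spike also (re)triggers every
outgoing chemical synapse when V crosses the synaptic threshold (−15 mV)
from below.

Parameter sheets (one YAML file per model variant, under
`coilswim/params/`) carry every population's parameters, positions, drives,
and the synaptic weight tables; any entry can be overridden by dotted path.

## Synapse semantics

The reference equations for this model family leave several operational
choices open (an Ohmic gap-junction law written without the postsynaptic
term, a single-trigger synaptic kernel, weights with unstated units).  The
implementation fixes them as follows; each choice was selected so that the
three circuits reproduce their hallmark behaviors, and each has a config
switch where an alternative is plausible.

**Gap junctions.**  The default current is the *difference of deviations
from rest*,

```
I_gap = G_eff · [ (Vpre(t − D/cv) − Vr_pre) − (Vpost(t) − Vr_post) ]
```

For populations sharing the same resting potential this is exactly the
conventional transjunctional form `G(Vpre − Vpost)`; where resting
potentials differ (the swimming MNs rest at −65 mV, interneurons at −60 mV)
it removes the standing bias that would otherwise flow at rest.  This
matters because the tonic V2a drive (2.89) sits only ≈ 7 % above the V2a
rheobase (2.71): any resting bias either silences the swimming network or
never lets it glide.  The literal printed form `I = Vpre·G` puts every
neuron under a large constant negative current (≈ −30 for a mid-chain
motoneuron) and produces no activity at all in any model; it remains
available as `gap_mode = 1` (and the plain difference form as `gap_mode = 0`).

`G_eff` is twice the table conductance (`gap_scale = 2`).  The circuit
descriptions state electrical couplings from both endpoints ("each neuron in
a chain formed electrical synapses with its three nearest … and vice-versa"),
so the connection list realizes each junction in both directions at the
printed weight and the engine applies the conductance per listing.  This
factor is load-bearing: at 1× the coiling wave stalls around somite 4–5
(the source-driven depolarization attenuates below threshold), at 2× it
recruits the full body and still terminates with the pacemaker burst.

**Chemical synapses.**  The kernel is event-triggered with renewal: each
suprathreshold crossing of the presynaptic membrane restarts the kernel
clock at `t_cross + delay` (superposition of successive events is available
via `chem_sum_kernels`).  The current is

```
I_chem = (Vpost − Erev) · (e^(−s/τr) − e^(−s/τf)) · W · C_post,   s = t − t0
```

i.e. the tabulated weights are interpreted as *voltage-rate* coefficients
(the synaptic term enters dV/dt directly, a common idiom in Izhikevich-style
code).  Without the `C_post` factor the printed weights are two orders of
magnitude too small to matter: a V2a→V0v weight of 0.04 could then never
recruit the commissural excitatory cells whose delayed activation generates
the second coil, and synaptic bursts would be ~0.1 mV events.  With it,
glycinergic bursts are millivolt-scale, the double-coiling V0d→IC synapse
(weight 2.0) can clamp the contralateral pacemaker near Egly = −58 mV during
a coil, and the V0v→IC synapse triggers the second coil — the mechanism the
double-coiling circuit was designed around.  Note the elegant guard in the
single-coiling model: Egly = −45 mV equals the firing threshold, so
commissural glycinergic bursts depolarize silent-side neurons at most *to*
threshold, never past it, regardless of weight.

Neuromuscular transmission uses the same kernel but as a pure current
`I = W · (e^(−s/τf) − e^(−s/τr))` without a postsynaptic driving force: a
muscle cell rests at 0, which is also the glutamatergic reversal potential,
so a conductance-based muscle synapse would be permanently inert.  Muscle
potentials are therefore in arbitrary units, as in the source data.

**Delays.**  Conduction delays are Euclidean distance over `cv`, with `cv`
in a.d.u./ms (4.0, 1.0, 0.8 for the three models) — the only unit reading
consistent with the stated 3–4 ms intersegmental delays of the swimming
model.  Delays shift the presynaptic trigger (and the gap-junction source
potential); the driving force is evaluated at the current time.

## Musculoskeletal model and calibration

Muscle cells are passive RC membranes `V' = −V/(RC) + Isyn/C` (the leak is
negative; an unstable positive leak would contradict a passive membrane)
with (R, C) = (25, 10), (50, 5), (1, 3) for the three stages.  Body angles
follow uncoupled damped pendulums
`θ'' + 2ζω0 θ' + ω0² θ = g (VR − VL)` and the midline is reconstructed as
`x_i = x_{i−1} + l cos θ_i`, `y_i = y_{i−1} − l sin θ_i` (the cosine keeps a
straight body at its full length; positive θ is rightward curvature).

ζ, ω0 and g are calibration constants of this package, chosen once per
model and fixed: ζ = 1 (critically damped), ω0 = 0.6 rad/ms (bandwidth well
above an 80 Hz drive), and g = 300 / 110 / 5 for single coiling / double
coiling / swimming.  The coiling gains were set so a coil is a full-body
bend lasting about one second; the swimming gain so the tail-tip amplitude
is about one somite length, comfortably above the 0.5 a.d.u. crossing
threshold of the tail-beat detector.

The integrated motor output is the bilateral muscle sum convolved with a
unit-amplitude 50 ms boxcar; the episode detector applies its 0.5-unit
threshold to this trace normalized per muscle cell (the absolute scale of
the sum is arbitrary; per-cell normalization makes the fixed threshold
meaningful across body sizes).

## Analysis conventions

* **Episodes** — maximal intervals of the normalized smoothed output ≥ 0.5;
  inter-episode intervals are the gaps between them.
* **Tail beats** — hysteresis crossings of the tail-tip lateral displacement
  at ±0.5 a.d.u.; each crossing to the other side counts as one beat, so the
  instantaneous frequency is the reciprocal of the interval between
  consecutive crossings (a full left-right cycle contains two beats; the
  full-cycle reading is available via `per_half_cycle=False`).  Intervals
  above 100 ms fall between episodes and are discarded.
* **Left-right alternation** — minimum of the normalized, non-mean-subtracted
  cross-correlation of left and right muscle activity over lags within
  ±10 ms (±20 ms selectable); 0 is perfect alternation, 1 synchrony; a
  silent side yields NaN.
* **Phase delays** — cross-correlation peak lag over the reference period
  (autocorrelation peak, or the mean coil-event duration for the coiling
  models), in radians, negative when the reference leads.
* **Coil events** — maximal constant-side intervals where the largest
  segment |θ| ≥ 0.5 rad and lasting ≥ 100 ms; an event is *full* if at least
  2/3 of segments exceed the threshold during it, else *truncated*;
  consecutive opposite-side full coils whose onsets lie within 1000 ms chain
  into double (2) or multiple (≥ 3) coilings.  Events clipped by the
  analysis window are marked censored and excluded from duration averages
  (but counted for frequencies).  All of these constants are declared
  calibration values, set once so the base single-coiling run yields six
  single coils of ≈ 1 s and never changed between conditions.

## Noise semantics

Sensitivity batteries scale one parameter set with Gaussian(1, σ) factors:
σd multiplies the motor-command amplitude with a single fresh draw per time
step (the command is one quantity, so the draw is shared by all driven
neurons); σp scales each membrane parameter of each neuron independently,
once per run (signed — some parameters legitimately sit near zero); σw
scales each synaptic weight once (clamped at 0; chemical-only and gap-only
variants exist); σl scales each neuron's projection extents per rule and
direction, rounds to whole segments, and rebuilds target sets and delays
from the perturbed lengths.  Structural draws happen in a fixed order
(lengths → weights → membrane parameters) from one generator per run, so a
seed fully determines a battery.

## Problem sizes

The shipped batteries use the study's own scales: 10 s single-coiling runs,
five 100 s double-coiling runs (σd = 0.5, σp = 0.01, σw = 0.05), ten 10 s
beat-and-glide runs, and three 5 s epochs for lesion protocols.  The numba
engine advances the 150-neuron swimming model at roughly 10⁵ steps/s on one
core.

## Known limitations

* The double-coiling network reproduces the double-coil-majority behavior in
  its base (noise-free) condition, but under the combined structural-noise
  battery it is prone to an absorbing "latched" state — the excitable V0d/V0v
  chains (whose post-spike reset sits above threshold) can lock into
  continuous firing and hold the IC pacemakers in depolarization block.  The
  reference battery did not show this, so the pooled noisy coil-class
  percentages and the double-coil duration come out far from the reference
  values; the base-condition proportions are close (≈ 56 % doubles).
* Beat-and-glide episodes are slightly short (≈ 180–220 ms vs 234 ms) and
  glides substantially short (≈ 130 ms vs 242 ms): between episodes this
  reconstruction retains low-level motor activity instead of full quiescence.
  Tail-beat frequencies run high by ~20 % (≈ 37 Hz vs 30 Hz) under the
  per-crossing beat definition, with the population inside the 20–60 Hz
  developmental band.
* Silencing V1 lengthens episodes and fuses glides as reported, but lowers
  rather than raises the tail-beat frequency in this reconstruction.
* The 30-somite builders reuse the base weight tables (the original
  large-body retunings are not reference); every weight is overridable.
* The pendulum chain is mechanically uncoupled and there is no hydrodynamics;
  midline kinematics are illustrative, not propulsive.
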