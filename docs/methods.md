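# Methods

## The model

`spinarm` simulates goal-directed elbow flexion in the horizontal plane
(zero gravity) as a closed sensorimotor loop with no dynamics in its
descending commands. The loop has four coupled layers:

**Plant.** A forearm+hand compound rotates about the elbow between hard
stops at 0° (full extension) and 120° (full flexion). Segment masses and
lengths follow standard anthropometry scaled to a uniform bone density
(humerus 337 mm / 1.164 kg, forearm 283 mm / 0.802 kg, hand 193 mm /
0.966 kg); the forearm is treated as a uniform rod pivoted at the elbow
and the hand as a point mass at forearm length plus half the hand length,
giving I ≈ 0.161 kg·m². Two antagonistic linear Hill muscles (biceps,
triceps) act through constant moment arms obtained from their endpoint
lengths: the biceps shortens from 34 cm to 25 cm over 0→120°
(−0.075 cm/deg), the triceps lengthens from 27.5 cm to 34.5 cm
(+0.058 cm/deg). Each muscle integrates

    dT/dt = (Kse/B) · (Kpe·max(0, L − Ls) + B·dL/dt − (1 + Kpe/Kse)·T + A)

with Kse = 1000 N/m, Kpe = 100 N/m, B = 1 N·s/m. The active drive A is
the product of a sigmoidal stimulus–tension curve of the muscle membrane
potential (amplitude 400/300 N, x-offset −20/−30 mV, y-offset −4.5/−4 N
for biceps/triceps, clamped at 0 so a muscle at the −60 mV rest potential
produces no force) and an inverted-parabola length–tension factor
1 − ((L − 38.5 cm)/Lwidth)² with Lwidth = 14 cm (biceps) and 35 cm
(triceps). With these constants the biceps spans roughly 7–90 % of
maximal tension over its operating range and the triceps 90–99 %, which
is what fixes the parabola's half-width at Lwidth (not Lwidth/2): the
printed tension-percent ranges only agree with that reading.

Three constants are the package's own, because no source fixes them:

* *Sigmoid steepness.* The tabulated steepness (100) is stored divided
  by 500 (0.2/mV). The lower bound on this scale is set by the
  requirement of zero force at rest (k ≥ ~0.144/mV); the upper bound by
  the fact that the muscle membrane, driven through a graded junction
  toward a −10 mV reversal, can only reach ≈ −15 mV, so the sigmoid's
  rise must sit inside the −45…0 mV band to be usable.
* *Parallel-spring slack lengths.* The springs are slack-clamped with
  slack lengths at the top of each muscle's operating range (34 / 34.5
  cm). Any shorter slack length gives the triceps several newtons of
  passive tension inside the range; the plant would then drift out of
  any flexed posture, and no movement could be held with silent
  motoneurons, contradicting both the quiescent-plant invariant and the
  behavior the model is meant to produce.
* *Joint damping*, 0.3 N·m·s/rad, standing in for all unmodelled passive
  dissipation (tissue, ligaments). With an order of magnitude less, the
  arm coasts for seconds after the muscles fall silent and no movement
  can settle to a plateau; with much more, movements of the observed
  force scale become too slow to pass the 2 s duration gate. 0.3 gives a
  coast time constant of ≈ 0.5 s, far below the muscle torque scale.

**Afferents.** Each muscle carries a spindle modelled as a miniature
intrafusal Hill element that shares the muscle's length trajectory; the
Ia potential is rest (−65 mV) + k_T·T_sp + k_dT·dT_sp/dt, clamped to
rest when the spindle is slack and saturating at −10 mV. The tension
term encodes length, the tension-rate term (carried by the serial-spring
velocity) encodes stretch velocity and acceleration transients. One
mixed gamma motoneuron per muscle adds an active intrafusal drive
(gamma_gain · suprathreshold gamma potential), raising both tonic and
dynamic sensitivity — this is what lets a gamma-driven spindle keep
responding during release, when a passive spindle has gone slack and
silent. Gains (k_T = 200 mV/N, k_dT = 8 mV·s/N, gamma 0.002 N/mV,
spindle Kpe 2, Kse 20, B 0.5) were hand-set so that the resting flexor
spindle at full extension reads ≈ −32 mV, release silence and gamma
rescue reproduce classic fusimotor traces, and stretch ramps show an
onset transient above the tonic plateau. The Golgi tendon organ is a
memoryless saturating affine map, Ib = −65 mV + 0.2 mV/N · T, capped at
−10 mV; the source gives no tendon-organ equations, so the simplest
monotone transducer is used.

**Network.** Twelve non-spiking spinal neurons (alpha and gamma
motoneurons, propriospinal (PN), Ia-, Ib- and Renshaw interneurons, one
per muscle side), two muscle-membrane nodes, and four afferent nodes.
Each integrated node is a leaky integrator (τ = 10 ms, rest −60 mV,
floor −80 mV — injected current cannot drive a membrane far below the
inhibitory reversal). Transmission is graded: postsynaptic conductance
rises linearly from 0 at a presynaptic threshold of −60 mV to the
maximal conductance at −20 mV; excitatory reversal −10 mV, inhibitory
−70 mV. The full wiring has 30 spinal synapses, mirror-symmetric 15 per
side: Ia→MN, Ia→PN, Ia→IaIN, Ib→IbIN, Ib→PN, PN→MN, MN→Renshaw,
Renshaw→MN, Renshaw→IaIN, reciprocal IaIN→antagonist-MN and
IaIN→antagonist-IaIN, autogenic IbIN→MN, crossed IbIN→antagonist-MN and
IbIN→antagonist-IbIN, and crossed PN→PN inhibition. The five variants
delete elements wholesale; their descending-parameter counts name them
(full50 = 12 neurons + 30 synapses + 8 GO interneurons; noIb36;
iaOnly14; noIa34 keeps the gamma motoneurons as SET targets;
noFeedback38 drops them because without spindles they are inert — these
two bookkeeping choices are the only ones that reproduce the printed
counts with this wiring).

**Commands.** A trial is one normalized vector in [0,1]^n ordered as SET
neuron currents, SET synapse gains, GO interneuron currents. SET steps
on at t = 1 s, GO at t = 5 s, both held to the trial end at 10 s; the
commands carry no dynamics whatsoever, so all temporal structure in the
muscle commands is generated by the loop. Currents decode affinely to
±100 leak-units (±30 is too weak for a SET command to hold a motoneuron
under threshold against strong tonic spindle drive — the preparatory
strategy the lesion analyses display); gains to [0,1]× the maximal
conductance. GO targets the 8 interneurons by default; a config switch
(`go_includes_alpha`) adds the two alpha MNs, reflecting an alternative
reading of the lesion narrative, and is off everywhere in this package.

**Integration.** The coupled system (joint, two muscle tensions, two
spindle tensions, all membrane potentials; afferent potentials are
algebraic) is one smooth ODE between command switch times, integrated
with fixed-step RK4 at 1 ms in three phases (pre-SET, SET, SET+GO),
recorded at 10 ms (1001 samples). Afferents and synapses read the same
synchronous state inside the derivative; lesions clamp node potentials
or zero synapse conductances. Non-finite states mark the trial failed
(treated as an invalid movement, never an exception). The inner loop is
compiled with numba; a pure-Python fallback keeps results identical.

## Scoring

A produced trace is compared to the minimum-jerk ideal
θ(t) = A·(10τ³ − 15τ⁴ + 6τ⁵). The amplitude is measured (final plateau
minus initial posture); onset (≥ GO time) and duration are fitted by a
vectorized grid search plus Nelder–Mead refinement of the mean squared
error over t ∈ [2, 10] s, with the template flat before onset. The cost
is that tracking MSE (deg², mean over samples — the source uses "MSE"
and a sum interchangeably; the mean makes the printed threshold of 1
meaningful) plus co-contraction penalties over the preparatory (2–5 s)
and maintained (7–10 s) windows: the time-averaged product of the two
motoneurons' suprathreshold depolarizations, each factor clamped at zero
below −60 mV (the literal product would reward doubly-silent MNs),
scaled by 100. A movement is valid when cost < 1, amplitude ∈ [10°,
110°], 5–95 % duration ≤ 2 s, and the direction is flexion.

EMG is the muscle membrane potential itself (transmission is graded, so
the envelope needs no rectification). The peak detector reports every
local maximum above the −60 mV baseline with its flanking minima,
plateaus collapsing to their center sample. A movement is triphasic when
an extensor burst has flexor bursts on both sides of it in time
(AG1/ANT/AG2); at the EMG level only movement-phase (t ≥ 5 s) bursts
strong enough to elicit force count (the stimulus–tension curve leaves
zero at ≈ −42 mV for the biceps, ≈ −51 mV for the triceps), which
excludes microvolt numerical ripples and preparatory transients; at the
motoneuron level any suprathreshold movement-phase burst counts, so the
EMG-triphasic set is a subset of the MN-triphasic set by construction.

## Exploration

Seeding minimizes the cost against a fixed target template (default 30°,
0.6 s — a typical fast flexion) with a box-bounded CMA-ES (σ₀ = 0.005,
bounds [0,1]); every valid movement met on the way is harvested. Because
the cost is exactly flat on the fully-quiescent plateau (no motoneuron
above threshold produces identical traces), each restart starts from the
best of a random prescan of the cube (150 draws, counted against the run
budget) rather than an arbitrary point.

The goal-exploration loop then alternates: sample a behavior-space goal
on the periphery of (extend) or in a hole inside (fill) the occupied
region of a 5° × 10°/s grid; retrieve the archived movement nearest the
goal (Euclidean in amplitude/110, speed/300 units; ties to the lowest
id); replay its vector with iid Gaussian noise (σ = 0.02 per coordinate,
clipped to [0,1]); keep the outcome only if valid. Goals per extend
round scale with the boundary length up to a cap (10). Area = occupied
cells; density = valid movements per occupied cell.

## What the synthetic fixtures do and do not show

Test fixtures are built from exact minimum-jerk templates plus
parameterized activity bumps and white noise; they exercise the scoring
stack (fit recovery to 1 %/2 %, noise floors, peak/triphasic logic)
independently of the simulator. They do not probe closed-loop dynamics;
those are tested on the simulator itself (quiescence, determinism,
lesion identities, archive invariants).

## Known limitations

* The behavior domain discovered at desk-scale budgets (thousands of
  runs) is a slow spindle-servo family — amplitudes ≈ 10–25°, peak
  speeds ≈ 5–25°/s — in which the flexor motoneuron rides just above
  threshold and movement pace is set by spindle drive withdrawal. The
  fast ballistic family with an active extensor braking burst (the
  regime that carries the triphasic pattern) exists in the plant's
  force budget but was not reached by seeding or exploration at these
  budgets under several gain and damping settings: crossing into it
  needs a coordinated launch-brake-settle strategy change that small
  random perturbations do not make. The triphasic analyses therefore
  run, but typically find no triphasic entries at this scale.
* The five wiring tables reconstruct circuit diagrams that are nowhere
  enumerated textually; edge-level differences from the original are
  possible, though all pathways named in the lesion analyses are
  present.
* Spindle, tendon-organ, synaptic and command-range constants are
  hand-set to qualitative physiology (the original tuned the same
  quantities by hand against electrophysiological recordings); absolute
  potentials and forces are not comparable between implementations.
* A single mixed gamma motoneuron per muscle; no separate static and
  dynamic fusimotor control. No gravity, one joint, two muscles.
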