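# spinarm

Closed-loop simulation of spinal sensorimotor control of elbow flexion,
with a goal-exploration process that maps the repertoire of movements the
spinal circuitry can produce on its own.

## The scientific question

During rapid single-joint movements, antagonistic muscles show a
stereotyped *triphasic* EMG sequence: a first agonist burst (AG1) that
launches the limb, an antagonist burst (ANT) that brakes it, and a second
agonist burst (AG2) that damps the stop. Whether this patterning is
composed in the brain or can be generated by spinal sensorimotor circuits
interacting with the limb is a long-standing question. `spinarm` builds
the testbed for the spinal hypothesis: an elbow driven by two antagonistic
Hill muscles (biceps/triceps), muscle-spindle (Ia) and Golgi-tendon-organ
(Ib) afferents, and a network of non-spiking spinal neurons
(alpha/gamma motoneurons, propriospinal, Ia, Ib and Renshaw
interneurons) with graded synapses. Descending input is restricted to
constant step commands — SET at t = 1 s configures neuron excitabilities
and the 30 synaptic gains, GO at t = 5 s feeds the 8 interneurons — so
any temporal structure in the muscle commands must emerge from the
loop itself.

The model is the full 50-parameter network plus four reduced variants
(`noIb36`, `iaOnly14`, `noIa34`, `noFeedback38`) for dissecting which
feedback pathways are necessary.

Movements are scored against the minimum-jerk template
θ(t) = A·(10τ³ − 15τ⁴ + 6τ⁵): the cost is the mean squared tracking
error over t ∈ [2, 10] s plus co-contraction penalties in the
preparatory and post-movement windows, and a movement is *valid* when
cost < 1, amplitude ∈ [10°, 110°] and duration ≤ 2 s. Because no single
command produces all behaviors, the package explores the command space
with a random Goal Exploration Process (rGEP): CMA-ES finds initial
valid movements (seeds), then the loop repeatedly picks a goal in
(amplitude, peak-speed) behavior space on the periphery or in holes of
the known domain, replays the nearest archived solution's parameters
with small Gaussian noise, and archives valid outcomes.

## Worked example

Seed the command space of the full model, explore, and replay the
largest discovered movement with its flexor spindle silenced:

```python
import numpy as np
from spinarm import circuits, simulate, explore
from spinarm.simulate import LesionSpec

topo = circuits.build_topology("full50")
model = simulate.default_model(topo)

seeds = explore.seed_search(
    topo, explore.SeederConfig(budget=2500, target_amplitude=30.0,
                               target_duration=0.6, rng_seed=1,
                               n_restarts=2),
    model=model)
print(f"{len(seeds)} valid seed movements found")

archive, history = explore.run_gep(
    seeds, topo,
    explore.GEPConfig(n_extend_rounds=30, n_fill_rounds=5, rng_seed=2),
    model=model)
area, density = explore.grid_metrics(archive)
print(f"{len(archive)} valid movements after {history[-1]['runs']} runs")
print(f"behavior-domain area {area} cells, density {density:.1f}")

entry = max(archive, key=lambda e: e.behavior[0])
lesioned = simulate.run_trial(
    entry.vector, topo, model=model,
    lesion=LesionSpec(clamped_neurons={"Flx1a": -65.0}))
print(f"largest movement {entry.behavior[0]:.1f} deg; with the flexor "
      f"spindle clamped: {np.max(np.abs(lesioned.angle)):.2f} deg")
```

prints (≈3 minutes on one CPU):

```
47 valid seed movements found
117 valid movements after 350 exploration runs
behavior-domain area 5 cells, density 23.4
largest movement 21.8 deg; with the flexor spindle clamped: 0.00 deg
```

The last line is the signature of spinal closed-loop control: every
discovered movement is launched by spindle drive, so clamping the Flx1a
afferent at its silent potential abolishes the movement entirely.

A `spinarm` command-line tool wraps the same functionality
(`spinarm run`, `seed`, `explore`, `metrics`, `lesion`, `correlate`);
traces are written as tidy CSV with a JSON sidecar, archives as CSV plus
a run manifest.

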