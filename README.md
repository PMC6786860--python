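# eqspike

An equation-oriented simulator for spiking neural networks — and for the
non-neuronal parts of a computational experiment (muscles, stimuli,
environments) — aimed at computational neuroscientists who want defining a
new model to be no harder than writing down its equations.

Models are plain-text differential equations annotated with physical units:

```text
dv/dt = (ge + gi - (v - El)) / taum : volt
dge/dt = -ge / taue : volt
gna : siemens/metre**2 (constant)
```

Every equation, threshold condition, reset statement and connectivity
expression is checked for **dimensional consistency** before anything runs
(`volt + amp` is an error, a differential right-hand side must carry
`declared unit / time`).  Validated expressions are compiled to vectorized
kernels and executed on a fixed per-timestep schedule: graded/summed
synaptic updates, numerical integration, threshold tests, delayed spike
delivery, resets, and recording.

Key capabilities:

- **Exact integration** — linear constant-coefficient systems are detected
  symbolically and advanced with the matrix-exponential affine update
  `x' = e^{A·dt} x + k`, error-free per step; heterogeneous (per-instance)
  coefficients get one update matrix per instance.  Nonlinear models use
  exponential Euler, classical RK4 or forward Euler; models with the white
  noise symbol `xi` (dimension `second⁻¹ᐟ²`) use Euler–Maruyama.
- **Graded synapses** via *summed variables*: a per-synapse expression whose
  per-target sum is written into a postsynaptic variable each timestep —
  continuous interactions, not only spike events.
- **Expression-based connectivity** (`"label_pre != label_post and not
  (label_pre == PY and label_post == ABPD)"`), per-synapse state, and
  per-synapse delays delivered exactly on the simulation grid through spike
  queues; multiple named pathways per synapse population.
- **Linked variables** that let one group read another group's state
  continuously (e.g. retinal neurons reading eye and stimulus position), and
  **user-registered functions** callable from model code (e.g. `sound(t)`
  sampling a stored waveform).
- **Procedural experiments**: `store()` / `restore()` snapshot the complete
  simulation state (clock, state arrays, spike queues, monitor buffers, RNG)
  bit-exactly, so protocols like bisection threshold search are ordinary
  Python loops around `run()`.

## A worked example

```python
import numpy as np
import eqspike as eq
from eqspike.units import ms, mV

group = eq.NeuronGroup(
    1, "dv/dt = (v_rest - v + drive)/tau : volt",
    threshold="v > -50*mV", reset="v = -60*mV", refractory=5*ms,
    namespace={"tau": 10*ms, "v_rest": -70*mV, "drive": 25*mV})
group.set_state("v", -70*mV)
spikes = eq.SpikeMonitor(group)
net = eq.Network(group, spikes, dt=0.1*ms)
net.run(100*ms)
print("spike times (ms):", np.round(spikes.t.value * 1e3, 1))
print("updater:", type(group.updater).__name__)
```

prints

```text
spike times (ms): [16.1 27.1 38.1 49.1 60.1 71.1 82.1 93.1]
updater: ExactUpdater
```

The neuron charges from −70 mV toward −45 mV with τ = 10 ms, crosses the
−50 mV threshold after τ·ln(25/5) ≈ 16.1 ms, and then fires periodically:
each interval is the 5 ms refractory period plus the ~6.1 ms recharge from
the −60 mV reset.  `ExactUpdater` confirms the model was recognized as
linear and integrated with the matrix exponential rather than an
approximate scheme.

## Case studies

Five self-contained fixtures double as examples and test subjects
(`eqspike.case_studies`), each runnable from the shell, e.g.

```bash
eqspike run pyloric --seed 1 --out out/
eqspike run pitch --out out/
```

- **pyloric** — the triphasic pyloric circuit of the crustacean
  stomatogastric ganglion: three bursting neurons (AB/PD, LP, PY) with
  graded fast glutamatergic and slow cholinergic synapses, a spike-triggered
  calcium trace (`reset="Ca += 0.1"`), and activity-dependent conductance
  regulation that drives each cell's mean calcium to a cell-type-specific
  target.
- **ocular** — a closed sensorimotor loop: an eye moved by antagonistic
  muscles (spike-triggered twitches) tracks an object drifting as an
  Ornstein–Uhlenbeck process, via a retina with Gaussian position tuning and
  eccentricity-weighted projections to motoneurons.
- **threshold** — bisection search for the voltage threshold of 100
  conductance-based neurons with sodium densities from 15 to 100 mS/cm²,
  built on `store()`/`restore()`.
- **cuba / cuba-het** — the classical current-based sparsely connected
  integrate-and-fire benchmark (4000 neurons, 80% excitatory, p = 0.02, mean
  in-degree 80), with homogeneous time constants (exact integration, shared
  update matrix) or per-neuron constants drawn in [90%, 110%] of the
  homogeneous values.
- **pitch** — delay-line coincidence detection of the period of a tone
  sequence: an adaptive-threshold input cell converts `sound(t)` into
  spikes; detectors receiving the train twice (one pathway undelayed, one
  with incremental delays) respond most when the delay difference matches
  the stimulus period.

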