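# Methods

## Model description language

A model is a list of entries, one per line: differential equations
(`dX/dt = rhs : unit (flags)`), subexpressions (`X = rhs : unit`), and
parameters (`X : unit (flags)`).  The right-hand-side grammar is
deliberately small — identifiers, numeric literals, `+ - * / **`,
parentheses, function calls, comparisons, and the word booleans
`and/or/not` — and is parsed by whitelisting the corresponding subset of the
host language's own grammar, so source order of operations is preserved
exactly and nothing outside the grammar (attribute access, indexing,
conditionals, keyword arguments) can appear in model code.

Numeric literals are dimensionless by definition; every dimensioned constant
enters through the namespace.  This makes dimension inference *total*: given
a dimension for each free identifier, every expression has a unique derived
dimension, and validation reduces to comparing the derived dimension of each
rhs with the declared one (`declared/time` for differential entries).
Dimensions are 7-vectors of rational exponents over the SI base dimensions;
rationals (not integers) because the white-noise symbol `xi` carries
dimension time^(−1/2).  Values are stored SI-scaled; display units exist
only at parse/format time.  Single-letter SI symbols (`s`, `g`, `m`, `V`,
`A`, …) are intentionally not registered as unit names because they are
among the most common model variable names; prefixed abbreviations (`ms`,
`mV`, `nS`, `mS/cm2`, …) and full names are.

Statement strings (reset, synaptic events, state initialization) reuse the
same expression grammar plus plain and augmented assignment, executed
top-to-bottom; a read after an assignment in the same block sees the new
value.  Suffixes `_pre`/`_post` inside synaptic code resolve to
source/target group variables indexed by each synapse's endpoints.

## Compilation and the execution schedule

Validated expressions are rendered to numpy-vectorized source (word booleans
become `logical_and/or/not`; chained comparisons are split) and compiled
once; evaluation is a single `eval` of the code object over a namespace of
state arrays and constants — one fused vector operation per expression per
timestep.  A reference scalar (tree-walking) interpreter defines the
semantics and serves as the oracle in tests.

Each timestep executes a fixed slot order:

1. summed/graded synaptic updates and per-synapse integration,
2. group state updates,
3. threshold tests (on the post-integration state),
4. spike delivery (this step's spikes are enqueued, then due synapses pop
   and run their event statements),
5. resets,
6. monitors (so recorded voltages show post-reset values on spike steps).

Summed variables run *before* the target group's integration so that the
integration of a step sees that step's synaptic drive — graded synapses are
continuous interactions.  Summed targets are **set**, not incremented
(instances without synapses read 0), and two populations may not sum into
the same target variable.  Delays are rounded to the nearest whole number
of timesteps (ties up) at run start; the spike queue is keyed by absolute
due step, delivers each insertion exactly once, and grows transparently —
delay-0 events are delivered in the same timestep's delivery slot.

Refractoriness is counted in whole steps (`ceil(refractory/dt)`): the
threshold is suppressed during the window, and differential variables
flagged `unless_refractory` are frozen.  Consequently successive spike
times of one instance always differ by at least the refractory period.

## Integration methods

Method selection per group/pathway (overridable via `method=`):

- **exact** for deterministic systems whose inlined right-hand sides are
  linear with constant coefficients.  Linearity is established symbolically:
  the Jacobian w.r.t. the state variables and the remainder must be free of
  state variables, of `t`, and of opaque functions.  Coefficients may
  reference `constant`-flagged per-instance parameters (heterogeneous time
  constants), in which case one `(M, k)` pair is precomputed per instance;
  non-constant parameters (e.g. summed-variable targets, which change every
  step) deliberately fail detection so a step-wise method is used.  The
  affine update is computed through the augmented matrix exponential
  `exp([[A, b],[0, 0]]·dt) = [[M, k],[0, 1]]`, which handles singular `A`
  (pure drift) without special cases.  Update matrices are precomputed at
  run start and recomputed only if dt changes; changing a "constant"
  parameter between runs without rebuilding is unsupported.
- **exponential Euler** (default for deterministic nonlinear systems): each
  rhs `f` is decomposed symbolically as `f = a + b·x` with `b = ∂f/∂x`
  evaluated on the current state (other variables frozen), and `x` updated
  exactly under that local affine model, with a series limit for `|b·dt| <
  1e-12`.  This is the standard robust choice for conductance-based
  (Hodgkin–Huxley-type) models at dt of a few hundredths of a millisecond.
- **euler** and classical **rk4** as plain explicit alternatives (rk4 is
  used for the bursting pyloric cells, whose rhs is polynomial).
- **euler_maruyama**, forced whenever `xi` appears.  `xi` is validated to
  appear only linearly and only in differential equations; the step binds
  `xi → η/√dt` (η standard normal per instance per step, from the network
  RNG) and takes one Euler step, which is algebraically identical to
  `x + f·dt + g·√dt·η` for any rhs linear in `xi`.

Rate functions with removable singularities (the `x/(e^x − 1)` forms of
Hodgkin–Huxley kinetics) are written with the built-in `exprel`, which is
exact at 0, so a scan or bisection landing exactly on the singular voltage
cannot produce NaNs.

All state update paths check for non-finite values each step and abort with
the variable name and time.

## Determinism, seeding and snapshots

One numpy Generator per network drives every stochastic element —
`rand()`/`randn()` in expressions and thresholds, Bernoulli connectivity,
Euler–Maruyama noise — with a defined consumption order (the schedule
order), so (seed, model, dt, duration) fully determine every output, and
two consecutive `run()` calls equal one long run bit-exactly.
`store()`/`restore()` copy the clock, all state arrays, spike queues,
monitor buffers (truncated on restore) and the RNG state; a restored
continuation reproduces the original bit-exactly.  Construction-time draws
(connectivity, initial values) use the RNG the caller supplies to the
builders, so fixtures are reproducible end-to-end from one seed.

## The case-study fixtures and their constants

The fixtures emulate four experiments plus a benchmark.  Constants that the
underlying systems do not pin down are this package's own choices, made once
to produce the documented qualitative behaviour, and kept in one `CONSTANTS`
block per fixture module.

**Pyloric circuit.**  Each cell is a Hindmarsh–Rose-type three-variable
burster mapped to physical voltage by `x = (v − v_mid)/v_s` (v_mid = −40 mV,
v_s = 20 mV; fast time scale 4 ms, slow 1 s), so spikes peak near 0 mV and
rest sits near −72 mV; spike detection is the upward crossing of −20 mV with
an 8 ms refractory gate.  Each spike increments a calcium trace by 0.1,
which decays with τ_Ca = 200 ms; a regulation variable integrates
(Ca − Ca_target)/τ_reg (τ_reg = 1 s) and sets two regulated conductances
through a falling sigmoid, implementing integral feedback of mean activity.
The regulated current uses a fixed 60 mV driving force rather than a
reversal-potential term: a voltage-dependent driving force of the necessary
magnitude adds enough local negative slope to stabilize the depolarized
fixed point of the fast subsystem and silence the burster, which is a
property of this reduced model, not of the biology.  Targets (0.12, 0.08,
0.05 for AB/PD, LP, PY) lie well inside the attainable range of the cell's
rate–drive curve (≈0–11 Hz average over bursts).  Fast graded synapses are
an instantaneous sigmoid of presynaptic voltage times an inhibitory driving
force, connected by the five-pair condition; slow cholinergic synapses
integrate a per-synapse activation `m_slow` (τ = 200 ms) and run from the
pacemaker to LP and PY.  Cells start quiescent (regulation initially
suppresses the drive), so early mean calcium is far from target and the
50-second run shows clear convergence; dt = 0.2 ms with RK4.

**Ocular loop.**  Eye: damped spring (`τ_e` = 100 ms, friction 50 ms) around
a resting position `x0` that decays with 150 ms and jumps ±0.02 per
motoneuron spike.  Object: OU process (τ = 1 s, σ = 0.6 s^−1/2 → stationary
std ≈ 0.42).  100 retinal neurons with Gaussian tuning (width 0.15) to
object-minus-eye position read both positions through linked variables and
spike with probability rate·dt per step; they project to the motoneuron
pulling the eye toward their preferred side with weight ∝ eccentricity.
The model is illustrative: the test compares closed-loop tracking error
against a gain-0 control with the identical object path (same seed), not
against behavioural data.

**Threshold finding.**  Traub–Miles-type Hodgkin–Huxley kinetics per
membrane area (C_m = 1 µF/cm², leak 0.05 mS/cm² at −65 mV, K 30 mS/cm²,
VT = −63 mV), sodium density spanning 15–100 mS/cm² across 100 unconnected
neurons; exponential Euler at dt = 0.05 ms.  The bisection protocol stores
the resting state once and per iteration restores, sets v to the estimate,
runs 20 ms, and moves each instance's estimate by ±step (spike/no spike),
halving the step; 20 iterations from −50 mV with step 15 mV.  The oracle in
the acceptance test is a staged grid scan (0.5 → 0.05 → 0.01 mV) of the
same trial procedure, valid because spiking is monotone in the initial
voltage — the same assumption bisection itself rests on (verified
separately at coarse resolution).

**CUBA benchmark.**  The classical current-based network: N = 4000 LIF
neurons (80% excitatory), `τ_m, τ_e, τ_i` = 20, 5, 10 ms, threshold −50 mV,
reset −60 mV, suprathreshold leak reversal −49 mV, weights 1.62 mV and
−9 mV, 5 ms refractory, independent Bernoulli connectivity p = 0.02 over
all ordered pairs (mean in-degree 80), dt = 0.1 ms.  Homogeneous time
constants give one shared exact-update matrix; the heterogeneous variant
draws all three per neuron uniformly in [0.9, 1.1]× base, giving one matrix
per neuron.

**Pitch detection.**  The waveform generator produces tone *bursts* (pulse
trains of the requested period, 80 ms long, 25 ms silent gaps) rather than
one continuous train: a strictly periodic train has near-identical
autocorrelation at every multiple of its period, so the detector at k·T
would trail the one at T by only k coincidences; burst boundaries reset the
count, making the margin grow with the number of bursts.  The input cell
(τ = 0.5 ms, adaptive threshold: rest 0.4, jump 0.01 per spike, decay
30 ms, 1.2 ms refractory) fires once per pulse with a latency set by the
adapted threshold; because that latency can straddle a grid step, the
detectors (τ = 0.3 ms, threshold 0.95, EPSP 0.8) are tuned so that two
arrivals within ±1 step fire but arrivals ≥ 0.5 ms apart never do.
Detector k's two pathways differ by (k+1)·0.5 ms.

## What the fixtures do and do not show

The fixtures are synthetic throughout: waveforms are generated pulse
trains, not audio; the object motion is an OU process; the pyloric and
ocular constants are reconstructions chosen for qualitative behaviour.
Passing tests therefore demonstrates the *simulator's* contracts —
dimensional validation, exact integration, delivery timing, snapshot
fidelity, protocol correctness, and the stated qualitative behaviours of
the circuits — not quantitative agreement of any fixture with physiological
recordings.

## Numerical and design choices

- Durations are rounded to whole steps, warning if the rounding error
  exceeds 1e-9·dt.  A single global clock drives all objects; per-object
  clocks are out of scope.
- Thresholds are evaluated on the post-integration state of the same step;
  monitors sample after resets (the alternative — before resets — would
  show the pre-reset peak; the choice is visible only on spike steps).
- Delay rounding ties go up; `round(d/dt)` in the tests means
  `floor(d/dt + 0.5)`.
- Synaptic `+=` on postsynaptic variables accumulates correctly when several
  due synapses share a target (unbuffered scatter-add); plain `=` with
  duplicate targets keeps the last write.
- Bisection estimates live on a dyadic grid around the initial estimate and
  stay within ±2·step₀ of it; the initial estimate and step must bracket
  the true thresholds (checked in the sweep by requiring interior scan
  brackets).
- Problem sizes in the test suite (e.g. store/restore at N = 1000 for 1 s,
  stochastic moments over 10⁴ paths, the 50 s pyloric run at dt = 0.2 ms)
  are the package's chosen desk-scale defaults; all scale up linearly.

## Known limitations

No standalone/native code generation, no multithreading or GPU backends, no
multi-compartment neurons, no real-time audio input, no event types beyond
the spike, no per-instance refractory expressions, no offset or logarithmic
units, and no implicit/stiff or adaptive integrators.  Exact integration
does not apply to time-dependent drives (they fall back to exponential
Euler).  `Synapses.connect` materializes the full candidate cross product,
which is memory-bound around N·M ≈ 10⁸ pairs.
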