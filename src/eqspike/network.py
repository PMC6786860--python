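"""Clock, schedule, run loop, seeding and snapshots.

Each timestep executes a fixed slot order:

  1. summed/graded updates and synaptic-pathway integration
  2. group state updates (numerical integration)
  3. threshold tests
  4. spike delivery (queue push for this step's spikes, then pop + events)
  5. resets
  6. monitors

so within one timestep resets never precede deliveries and deliveries never
precede thresholds.  One global clock drives everything; durations are
rounded to a whole number of steps (with a warning if the rounding error
exceeds 1e-9 dt).  All randomness -- rand()/randn() in expressions,
connection sampling, Euler-Maruyama noise -- derives from a single
per-network numpy Generator, so (seed, model, dt, duration) fully determine
every output.  :meth:`Network.store`/:meth:`Network.restore` snapshot and
reinstate the complete simulation state (clock, state arrays, spike queues,
monitor buffers, RNG state) bit-exactly.
"""

from __future__ import annotations

import json
import warnings

import numpy as np

from .errors import EqspikeError, RestoreWithoutStore
from .groups import NeuronGroup
from .monitors import _Monitor
from .synapses import Synapses, check_summed_collisions
from .units import TIME, Quantity, get_dimension

__all__ = ["Clock", "Network"]


class Clock:
    """Integer timestep counter with fixed dt; t advances only by whole steps."""

    def __init__(self, dt):
        if get_dimension(dt) != TIME:
            raise EqspikeError("dt must be a time quantity")
        self.dt = float(dt.value if isinstance(dt, Quantity) else dt)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.timestep = 0

    @property
    def t(self):
        return self.timestep * self.dt

    def steps_for(self, duration):
        if get_dimension(duration) != TIME:
            raise EqspikeError("duration must be a time quantity")
        dur = float(duration.value if isinstance(duration, Quantity) else duration)
        if dur < 0:
            raise ValueError("duration must be nonnegative")
        steps = int(round(dur / self.dt))
        if abs(steps * self.dt - dur) > 1e-9 * self.dt:
            warnings.warn(
                f"duration {dur} s is not a multiple of dt={self.dt} s; "
                f"running {steps} steps", stacklevel=3)
        return steps


class Network:
    """A set of groups, synapse populations and monitors sharing one clock."""

    def __init__(self, *objects, dt, seed=None):
        self.clock = Clock(dt)
        self.groups: list[NeuronGroup] = []
        self.synapses: list[Synapses] = []
        self.monitors: list[_Monitor] = []
        self.rng = np.random.default_rng(seed)
        self._snapshots = {}
        self._built = False
        self.add(*objects)

    def add(self, *objects):
        for obj in objects:
            if isinstance(obj, NeuronGroup):
                self.groups.append(obj)
            elif isinstance(obj, Synapses):
                self.synapses.append(obj)
            elif isinstance(obj, _Monitor):
                self.monitors.append(obj)
            elif isinstance(obj, (list, tuple)):
                self.add(*obj)
            else:
                raise TypeError(f"cannot add {obj!r} to a network")
        self._built = False
        return self

    def set_seed(self, seed):
        """Reseed the single RNG stream; affects only subsequent draws."""
        self.rng = np.random.default_rng(seed)
        for obj in self.groups + self.synapses:
            obj.rng = self.rng
        return self

    # ------------------------------------------------------------------ build -
    def _build(self):
        if self._built:
            return
        check_summed_collisions(self.synapses)
        dt = self.clock.dt
        for g in self.groups:
            g.prepare(dt, self.rng)
        for s in self.synapses:
            s.prepare(dt, self.rng)
        for m in self.monitors:
            m.prepare(dt)
        self._built = True

    # ------------------------------------------------------------------ run ---
    def run(self, duration, callback=None, callback_every=0):
        """Advance the network by ``duration``; repeated calls continue.

        ``callback(network)`` is invoked every ``callback_every`` steps if
        given (plain host-language control flow between runs stays ordinary
        Python -- experiment protocols are procedural by design).
        """
        self._build()
        steps = self.clock.steps_for(duration)
        dt = self.clock.dt
        groups, synapses, monitors = self.groups, self.synapses, self.monitors
        for _ in range(steps):
            step = self.clock.timestep
            t = step * dt
            stamp = step + 1
            # (1) graded/summed interactions and pathway integration, so this
            #     step's integration sees this step's synaptic drive
            for s in synapses:
                s.state_update(t, dt)
                s.update_summed(t, dt)
            # (2) numerical integration
            for g in groups:
                g.state_update(t, dt, stamp)
            # (3) thresholds
            spikes = {}
            for g in groups:
                if g.threshold_expr is not None:
                    sp = g.apply_threshold(t, dt, stamp)
                    if sp.size:
                        spikes[g] = sp
            # (4) synaptic propagation: push this step's spikes, pop due ones
            for s in synapses:
                s.enqueue(spikes, step)
            for s in synapses:
                s.deliver(step, t, dt)
            # (5) resets
            for g in groups:
                sp = spikes.get(g)
                if sp is not None:
                    g.apply_reset(sp, t, dt)
            # (6) monitors
            self.clock.timestep = stamp
            for m in monitors:
                m.record(stamp, spikes)
            if callback is not None and callback_every and \
                    stamp % callback_every == 0:
                callback(self)
        return self

    @property
    def t(self):
        return Quantity(self.clock.t, TIME)

    # ------------------------------------------------------------- snapshots --
    def store(self, name="default"):
        """Save a complete named snapshot of the simulation state."""
        self._build()
        self._snapshots[name] = {
            "timestep": self.clock.timestep,
            "groups": [g.snapshot() for g in self.groups],
            "synapses": [s.snapshot() for s in self.synapses],
            "monitors": [m.snapshot() for m in self.monitors],
            "rng": json.loads(json.dumps(self.rng.bit_generator.state)),
        }
        return self

    def restore(self, name="default"):
        """Reinstate a stored snapshot bit-exactly (clock, state, queues,
        monitors, RNG)."""
        if name not in self._snapshots:
            raise RestoreWithoutStore(f"no snapshot named {name!r}")
        snap = self._snapshots[name]
        self.clock.timestep = snap["timestep"]
        for g, gs in zip(self.groups, snap["groups"]):
            g.restore(gs)
        for s, ss in zip(self.synapses, snap["synapses"]):
            s.restore(ss)
        for m, ms in zip(self.monitors, snap["monitors"]):
            m.restore(ms)
        self.rng.bit_generator.state = json.loads(json.dumps(snap["rng"]))
        return self

    def write_manifest(self, path, **extra):
        """JSON run manifest: dt, t, seed-relevant info plus caller extras."""
        import eqspike
        manifest = {"dt_seconds": self.clock.dt, "t_seconds": self.clock.t,
                    "version": eqspike.__version__}
        manifest.update(extra)
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
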