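"""Recording devices: state trajectories, spikes and population rates.

Monitors sample in the last schedule slot of each timestep, after resets, so
a recorded membrane potential shows the post-reset value on spike steps.
Monitors participate in snapshots: store/restore truncates recorded data back
to the snapshot time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EqspikeError
from .units import DIMENSIONLESS, TIME, Quantity

__all__ = ["StateMonitor", "SpikeMonitor", "PopulationRateMonitor"]


class _Monitor:
    def prepare(self, dt):
        self._dt = dt

    def record(self, stamp, spikes):
        raise NotImplementedError

    def snapshot(self):
        raise NotImplementedError

    def restore(self, snap):
        raise NotImplementedError


class StateMonitor(_Monitor):
    """Record one or more variables of a group every ``interval`` timesteps.

    ``record`` selects instances: True (all) or an index list.  Values are
    bit-equal to the group state at sampling time.
    """

    def __init__(self, group, variables, record=True, interval=1):
        self.group = group
        self.variables = [variables] if isinstance(variables, str) else list(variables)
        for var in self.variables:
            if var not in group.state_arrays and var not in group.linked and \
                    var not in getattr(group.eqs, "entries", {}):
                raise EqspikeError(f"unknown variable {var!r} on {group.name}")
        self.indices = np.arange(group.n) if record is True \
            else np.asarray(record, dtype=np.int64)
        self.interval = int(interval)
        self._times = []
        self._values = {var: [] for var in self.variables}

    def record(self, stamp, spikes):
        if stamp % self.interval:
            return
        self._times.append(stamp * self._dt)
        for var in self.variables:
            if var in self.group.state_arrays:
                vals = self.group.state_arrays[var][self.indices]
            elif var in self.group.linked:
                vals = self.group.linked[var].read()[self.indices]
            else:   # subexpression
                vals = self.group.evaluate(var, stamp * self._dt,
                                           self._dt)[self.indices]
            self._values[var].append(np.array(vals, dtype=float))

    @property
    def t(self):
        return Quantity(np.asarray(self._times, dtype=float), TIME)

    def values(self, variable):
        """(timesteps x recorded instances) Quantity."""
        dim = self.group.eqs[variable].dim if variable in self.group.eqs \
            else DIMENSIONLESS
        stack = np.asarray(self._values[variable], dtype=float) \
            if self._times else np.empty((0, self.indices.size))
        return Quantity(stack, dim)

    def __getitem__(self, variable):
        return self.values(variable)

    def to_dataframe(self):
        data = {"t_seconds": np.asarray(self._times, dtype=float)}
        for var in self.variables:
            arr = np.asarray(self._values[var], dtype=float)
            for col, idx in enumerate(self.indices):
                data[f"{var}_{idx}"] = arr[:, col] if arr.size else np.empty(0)
        return pd.DataFrame(data)

    def write_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def snapshot(self):
        return (len(self._times),)

    def restore(self, snap):
        (n,) = snap
        del self._times[n:]
        for var in self.variables:
            del self._values[var][n:]


class SpikeMonitor(_Monitor):
    """Spike times and emitting indices of one group (times nondecreasing)."""

    def __init__(self, group):
        self.group = group
        self._times = []
        self._indices = []

    def record(self, stamp, spikes):
        sp = spikes.get(self.group)
        if sp is None or sp.size == 0:
            return
        self._times.append(np.full(sp.size, stamp * self._dt))
        self._indices.append(sp.copy())

    @property
    def t(self):
        vals = np.concatenate(self._times) if self._times else np.empty(0)
        return Quantity(vals, TIME)

    @property
    def i(self):
        return np.concatenate(self._indices) if self._indices \
            else np.empty(0, dtype=np.int64)

    @property
    def num_spikes(self):
        return sum(ix.size for ix in self._indices)

    def count(self):
        """Spike count per instance."""
        return np.bincount(self.i, minlength=self.group.n)

    def to_dataframe(self):
        return pd.DataFrame({"t_seconds": self.t.value, "neuron": self.i})

    def write_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def snapshot(self):
        return (len(self._times),)

    def restore(self, snap):
        (n,) = snap
        del self._times[n:]
        del self._indices[n:]


class PopulationRateMonitor(_Monitor):
    """Instantaneous population rate: spikes_in_step / (N * dt), in hertz.

    The integral rate * dt * N over a run equals the total spike count.
    """

    def __init__(self, group):
        self.group = group
        self._times = []
        self._rates = []

    def record(self, stamp, spikes):
        sp = spikes.get(self.group)
        n_sp = 0 if sp is None else sp.size
        self._times.append(stamp * self._dt)
        self._rates.append(n_sp / (self.group.n * self._dt))

    @property
    def t(self):
        return Quantity(np.asarray(self._times, dtype=float), TIME)

    @property
    def rate(self):
        return Quantity(np.asarray(self._rates, dtype=float),
                        DIMENSIONLESS / TIME)

    def snapshot(self):
        return (len(self._times),)

    def restore(self, snap):
        (n,) = snap
        del self._times[n:]
        del self._rates[n:]
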