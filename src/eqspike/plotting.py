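"""Small matplotlib helpers for the standard figures: a raster of spikes and
membrane-potential traces stacked above it."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["raster_plot", "trace_and_raster"]


def raster_plot(spike_monitor, ax=None, **kwargs):
    """Spike raster: time on x, neuron index on y."""
    if ax is None:
        _, ax = plt.subplots()
    kwargs.setdefault("s", 4)
    ax.scatter(spike_monitor.t.value, spike_monitor.i, marker="|", **kwargs)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron")
    return ax


def trace_and_raster(state_monitor, spike_monitor, variable="v", path=None,
                     scale=1.0, ylabel=None):
    """Membrane potential over time per recorded instance, raster below."""
    n = state_monitor.indices.size
    fig, axes = plt.subplots(n + 1, 1, sharex=True,
                             figsize=(8, 1.2 * (n + 1)))
    t = state_monitor.t.value
    vals = state_monitor.values(variable).value
    for k in range(n):
        axes[k].plot(t, vals[:, k] * scale, lw=0.5)
        axes[k].set_ylabel(ylabel or variable)
    raster_plot(spike_monitor, ax=axes[-1])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _finite(x):
    return np.asarray(x)[np.isfinite(x)]
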