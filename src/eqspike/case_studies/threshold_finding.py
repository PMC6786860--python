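"""Voltage-threshold estimation by bisection.

A neuron's firing threshold -- the lowest membrane potential from which it
fires an action potential within a short trial -- is found by a procedural
experiment: store the network state once, then repeatedly restore it, set
the membrane potential to the current estimate, simulate for a 20 ms trial,
and move the estimate down if the neuron spiked and up if it did not,
halving the step width each iteration.  After n iterations the estimate is
within step0 * 2**(1-n) of the threshold the trial procedure defines.  The
loop is ordinary host-language control flow around ``run()`` -- the outcome
of each trial determines the parameters of the next, which a purely
declarative description could not express.

The population fixture is a single-compartment conductance-based model with
a passive leak and voltage-gated sodium and potassium conductances
(Traub-Miles-type kinetics, written per membrane area), 100 unconnected
neurons whose sodium densities span 15 to 100 mS/cm2.  Running the bisection
vectorized over the whole population yields the threshold-vs-density curve.
"""

from __future__ import annotations

import numpy as np

from ..groups import NeuronGroup
from ..monitors import SpikeMonitor
from ..network import Network
from ..units import Quantity, ms, mV, parse_unit_expression

CONSTANTS = {
    "Cm": parse_unit_expression("1*uF/cm2"),
    "gl": parse_unit_expression("0.05*mS/cm2"),
    "gk": parse_unit_expression("30*mS/cm2"),
    "El": -65 * mV,
    "ENa": 50 * mV,
    "EK": -90 * mV,
    "VT": -63 * mV,
    "gna_min": parse_unit_expression("15*mS/cm2"),
    "gna_max": parse_unit_expression("100*mS/cm2"),
    "dt": 0.05 * ms,
    "spike_threshold": -20 * mV,
}

HH_MODEL = """
alpham = 1.28 / exprel((13*mV - v + VT)/(4*mV)) / ms : second**-1
betam = 1.4 / exprel((v - VT - 40*mV)/(5*mV)) / ms : second**-1
alphah = 0.128 * exp((17*mV - v + VT)/(18*mV)) / ms : second**-1
betah = 4 / (1 + exp((40*mV - v + VT)/(5*mV))) / ms : second**-1
alphan = 0.16 / exprel((15*mV - v + VT)/(5*mV)) / ms : second**-1
betan = 0.5 * exp((10*mV - v + VT)/(40*mV)) / ms : second**-1
dv/dt = (gl*(El - v) + gna*m**3*h*(ENa - v) + gk*n**4*(EK - v)) / Cm : volt
dm/dt = alpham*(1 - m) - betam*m : 1
dh/dt = alphah*(1 - h) - betah*h : 1
dn/dt = alphan*(1 - n) - betan*n : 1
gna : siemens/metre**2 (constant)
"""


def build_hh_population(n=100, gna_min=None, gna_max=None, dt=None):
    """100 unconnected conductance-based neurons with evenly spaced sodium
    densities; returns (network, info)."""
    c = CONSTANTS
    gna_min = c["gna_min"] if gna_min is None else gna_min
    gna_max = c["gna_max"] if gna_max is None else gna_max
    ns = {k: c[k] for k in ("Cm", "gl", "gk", "El", "ENa", "EK", "VT")}
    group = NeuronGroup(n, HH_MODEL, threshold="v > spike_threshold",
                        refractory=2 * ms, method="exponential_euler",
                        namespace={**ns, "spike_threshold": c["spike_threshold"]},
                        name="hh")
    lo, hi = float(gna_min.value), float(gna_max.value)
    if n > 1:
        group.set_state("gna", Quantity(np.linspace(lo, hi, n), gna_min.dim))
    else:
        group.set_state("gna", gna_min)
    # rest: v at leak reversal, gates at their steady state there
    group.set_state("v", c["El"])
    for gate, a, b in (("m", "alpham", "betam"), ("h", "alphah", "betah"),
                       ("n", "alphan", "betan")):
        group.set_state(gate, f"{a} / ({a} + {b})")
    spikes = SpikeMonitor(group)
    net = Network(group, spikes, dt=dt if dt is not None else c["dt"])
    return net, {"group": group, "spikes": spikes, "net": net}


def find_threshold(net, group, spike_monitor, initial, step0, n_iter=20,
                   trial=20 * ms, variable="v"):
    """Vectorized bisection over all instances of ``group``.

    Per iteration: restore the stored state, set ``variable`` to the current
    estimates, run one trial, then decrease the estimate where the instance
    spiked and increase it where it did not; halve the step.  Returns the
    per-instance estimates as a Quantity after ``n_iter`` iterations.
    """
    estimate = np.full(group.n, float(initial.value))
    step = float(step0.value)
    dim = initial.dim
    net.store("_bisection")
    try:
        for _ in range(n_iter):
            net.restore("_bisection")
            group.set_state(variable, Quantity(estimate.copy(), dim))
            before = spike_monitor.count()
            net.run(trial)
            spiked = (spike_monitor.count() - before) > 0
            estimate = np.where(spiked, estimate - step, estimate + step)
            step /= 2.0
    finally:
        net.restore("_bisection")
    return Quantity(estimate, dim)


def spikes_from_initial_voltages(v0, gna=None, trial=20 * ms, dt=None):
    """Whether a fresh neuron spikes within ``trial`` when started at ``v0``.

    ``v0`` (volt Quantity, length K) and ``gna`` (density Quantity, scalar or
    length K) are broadcast per instance; gates start at rest.  This is the
    primitive a brute-force threshold scan is built from.
    """
    v0_arr = np.atleast_1d(np.asarray(v0.value, dtype=float))
    k = v0_arr.size
    net, info = build_hh_population(n=k, dt=dt)
    group = info["group"]
    if gna is not None:
        gvals = np.broadcast_to(np.atleast_1d(np.asarray(gna.value)), (k,))
        group.set_state("gna", Quantity(gvals.copy(), gna.dim))
    group.set_state("v", Quantity(v0_arr, v0.dim))
    net.run(trial)
    return info["spikes"].count() > 0
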