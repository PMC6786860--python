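"""The CUBA benchmark: a sparsely connected network of leaky
integrate-and-fire neurons with synapses modelled as exponentially decaying
currents (here lumped into voltage-scale drive variables ge/gi, the classical
current-based formulation of the Vogels-Abbott network).

N neurons (80% excitatory), every ordered source->target pair connected
independently with probability 0.02, so each neuron receives on average
0.02*N synaptic inputs (80 at the standard N = 4000).  Weights are the
standard benchmark values, tuned to sustain ongoing asynchronous activity.
The membrane equation is linear with constant coefficients, so the
homogeneous variant is integrated *exactly* (the method policy selects the
matrix-exponential updater automatically); spikes remain aligned to the
0.1 ms simulation grid.  In the heterogeneous variant the three time
constants are redrawn per neuron, uniformly between 90% and 110% of the
homogeneous values, which forces one update matrix per neuron.
"""

from __future__ import annotations

import numpy as np

from ..groups import NeuronGroup
from ..monitors import PopulationRateMonitor, SpikeMonitor
from ..network import Network
from ..synapses import Synapses
from ..units import ms, mV

#: benchmark constants (SI-scaled quantities); time constants are the
#: classical values, weights the classical "60*0.27/10" / "-20*4.5/10" mV
CONSTANTS = {
    "taum": 20 * ms,          # membrane time constant
    "taue": 5 * ms,           # excitatory synaptic decay
    "taui": 10 * ms,          # inhibitory synaptic decay
    "Vt": -50 * mV,           # spike threshold
    "Vr": -60 * mV,           # reset potential
    "El": -49 * mV,           # leak reversal (suprathreshold: drives activity)
    "we": (60 * 0.27 / 10) * mV,    # excitatory weight
    "wi": (-20 * 4.5 / 10) * mV,    # inhibitory weight
    "refractory": 5 * ms,
    "p_connect": 0.02,
    "dt": 0.1 * ms,
}

_MODEL_HOMOGENEOUS = """
dv/dt  = (ge + gi - (v - El)) / taum : volt (unless_refractory)
dge/dt = -ge / taue : volt
dgi/dt = -gi / taui : volt
"""

_MODEL_HETEROGENEOUS = """
dv/dt  = (ge + gi - (v - El)) / taum_i : volt (unless_refractory)
dge/dt = -ge / taue_i : volt
dgi/dt = -gi / taui_i : volt
taum_i : second (constant)
taue_i : second (constant)
taui_i : second (constant)
"""


def build_cuba(N=4000, heterogeneous=False, seed=0, p=None, monitors=True):
    """Build the CUBA network; returns (network, info dict).

    info holds the group, both synapse populations, the monitors and the
    empirical mean in-degree.
    """
    if N < 10:
        raise ValueError("the benchmark needs at least 10 neurons")
    rng = np.random.default_rng(seed)
    p = CONSTANTS["p_connect"] if p is None else p
    n_exc = int(0.8 * N)

    model = _MODEL_HETEROGENEOUS if heterogeneous else _MODEL_HOMOGENEOUS
    ns = {k: CONSTANTS[k] for k in ("taum", "taue", "taui", "Vt", "Vr", "El",
                                    "we", "wi")}
    group = NeuronGroup(N, model, threshold="v > Vt", reset="v = Vr",
                        refractory=CONSTANTS["refractory"], namespace=ns,
                        name="cuba")
    group.rng = rng
    if heterogeneous:
        base = {"taum_i": CONSTANTS["taum"], "taue_i": CONSTANTS["taue"],
                "taui_i": CONSTANTS["taui"]}
        for var, tau in base.items():
            factors = rng.uniform(0.9, 1.1, size=N)
            group.state_arrays[var][...] = factors * float(tau.value)
    # membrane potentials start uniformly between reset and threshold
    group.set_state("v", "Vr + rand() * (Vt - Vr)")

    exc = Synapses(group, group, on_pre="ge_post += we", name="excitatory")
    inh = Synapses(group, group, on_pre="gi_post += wi", name="inhibitory")
    # excitatory sources are neurons [0, n_exc), inhibitory the rest; the
    # candidate set is the full ordered cross product, thinned by p
    exc.connect(condition=f"i < {n_exc}", p=p, rng=rng)
    inh.connect(condition=f"i >= {n_exc}", p=p, rng=rng)

    objs = [group, exc, inh]
    info = {"group": group, "exc": exc, "inh": inh, "n_exc": n_exc,
            "mean_in_degree": (exc.n + inh.n) / N}
    if monitors:
        info["spikes"] = SpikeMonitor(group)
        info["rate"] = PopulationRateMonitor(group)
        objs += [info["spikes"], info["rate"]]
    net = Network(*objs, dt=CONSTANTS["dt"])
    net.set_seed(int(rng.integers(2 ** 31)))
    info["net"] = net
    return net, info
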