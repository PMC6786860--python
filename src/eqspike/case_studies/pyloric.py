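"""The pyloric network of the crustacean stomatogastric ganglion with
activity-dependent conductance regulation.

Three neurons -- the lumped pacemaker AB/PD, LP and PY -- each modelled with
a three-variable bursting neuron (a Hindmarsh-Rose-type model rescaled to
physical voltage), a calcium trace that jumps by 0.1 at every spike and
decays exponentially, and a slow regulation variable z that integrates the
difference between the calcium trace and a neuron-type-specific target.
z in turn sets two regulated conductances, s and g, whose depolarizing
current controls excitability: too much activity raises Ca above target,
z grows, s and g shrink, and the cell calms down (an integral feedback that
drives each cell's average Ca to its target).

The cells interact through two kinds of *graded* synapses -- continuous
interactions, not spike-triggered events:

- fast glutamatergic: instantaneous sigmoid of the presynaptic potential,
  connecting every ordered pair except PY->AB/PD
  (condition ``label_pre != label_post and not (label_pre == PY and
  label_post == ABPD)``, i.e. exactly 5 synapses);
- slow cholinergic: a per-synapse activation variable m_slow relaxing toward
  the same sigmoid with a slow time constant, from the pacemaker onto LP and
  PY (2 synapses).

Both inject current through summed variables (I_fast, I_slow) that are set
each timestep to the sum over incoming synapses.

Numeric constants below are this package's reconstruction, chosen to produce
slow bursting, spikes crossing -20 mV, and calcium convergence to the
per-label targets; they are not measurements.
"""

from __future__ import annotations

import numpy as np

from ..groups import NeuronGroup
from ..monitors import SpikeMonitor, StateMonitor
from ..network import Network
from ..synapses import Synapses
from ..units import Quantity, ms, mV, nA, nS, second

#: label values injected into every namespace (plain dimensionless integers)
LABELS = {"ABPD": 0, "LP": 1, "PY": 2}

CONSTANTS = {
    # voltage mapping of the dimensionless bursting model: x = (v - v_mid)/vs
    "vs": 20 * mV,
    "v_mid": -40 * mV,
    # fast/slow time scales of the bursting dynamics
    "tau": 4 * ms,
    "tau_slow": 1000 * ms,
    "b_hr": 4.0,            # slow-variable coupling
    "x_rest": -1.6,         # resting point of the slow variable
    "I_base": 0.8,          # baseline drive (dimensionless, in model units)
    # calcium trace and regulation
    "tau_Ca": 200 * ms,
    "tau_reg": 1 * second,
    "c_reg": 2.0,           # steepness of the conductance sigmoid
    "s_max": 24 * nS,
    "g_max": 24 * nS,
    "V_drive": 60 * mV,     # fixed driving force of the regulated current
    "i_unit": 1 * nA,       # current scale of the dimensionless drive
    # per-label calcium targets (attainable within the cell's rate range)
    "Ca_targets": {"ABPD": 0.12, "LP": 0.08, "PY": 0.05},
    # graded synapses
    "g_fast": 6 * nS,
    "E_fast": -70 * mV,
    "g_slow": 4 * nS,
    "E_slow": -70 * mV,
    "V_mid_syn": -35 * mV,
    "V_slope": 5 * mV,
    "tau_m_slow": 200 * ms,
    # spike detection
    "v_spike": -20 * mV,
    "refractory": 8 * ms,
    "dt": 0.2 * ms,
}

NEURON_MODEL = """
x = (v - v_mid) / vs : 1
dv/dt = (y - x**3 + 3*x**2 + I_drive - z_hr) * vs / tau : volt
dy/dt = (1 - 5*x**2 - y) / tau : 1
dz_hr/dt = (b_hr*(x - x_rest) - z_hr) / tau_slow : 1
dCa/dt = -Ca / tau_Ca : 1
dz/dt = (Ca - Ca_target) / tau_reg : 1
s = s_max / (1 + exp(c_reg * z)) : siemens
g = g_max / (1 + exp(c_reg * z)) : siemens
I_drive = I_base + ((s + g) * V_drive + I_fast + I_slow) / i_unit : 1
I_fast : amp
I_slow : amp
Ca_target : 1 (constant)
label : integer (constant)
"""

FAST_SYNAPSE_MODEL = """
I_fast_post = g_fast * (E_fast - v_post) / (1 + exp((V_mid_syn - v_pre)/V_slope)) : amp (summed)
"""

SLOW_SYNAPSE_MODEL = """
dm_slow/dt = (1/(1 + exp((V_mid_syn - v_pre)/V_slope)) - m_slow) / tau_m_slow : 1
I_slow_post = g_slow * m_slow * (E_slow - v_post) : amp (summed)
"""

#: fast connectivity condition over the three labelled cells
FAST_CONDITION = ("label_pre != label_post and "
                  "not (label_pre == PY and label_post == ABPD)")
#: the slow cholinergic pathway runs from the pacemaker onto LP and PY
SLOW_CONDITION = ("label_pre == ABPD and "
                  "(label_post == LP or label_post == PY)")


def _namespace():
    keys = ("vs", "v_mid", "tau", "tau_slow", "b_hr", "x_rest", "I_base",
            "tau_Ca", "tau_reg", "c_reg", "s_max", "g_max", "V_drive", "i_unit",
            "g_fast", "E_fast", "g_slow", "E_slow", "V_mid_syn", "V_slope",
            "tau_m_slow")
    ns = {k: CONSTANTS[k] for k in keys}
    ns.update(LABELS)
    return ns


def build_pyloric(seed=0, record_states=True, record_interval=5):
    """Assemble the three-cell circuit; returns (network, info dict)."""
    rng = np.random.default_rng(seed)
    ns = _namespace()
    cells = NeuronGroup(3, NEURON_MODEL,
                        threshold="v > v_spike", reset="Ca += 0.1",
                        refractory=CONSTANTS["refractory"],
                        method="rk4",
                        namespace={**ns, "v_spike": CONSTANTS["v_spike"]},
                        name="pyloric")
    cells.rng = rng
    cells.set_state("label", np.array([LABELS["ABPD"], LABELS["LP"],
                                       LABELS["PY"]]))
    for lab, target in CONSTANTS["Ca_targets"].items():
        cells.set_state("Ca_target", target, subset=f"label == {LABELS[lab]}")
    # start from rest with per-cell offsets so the three cells desynchronize
    cells.set_state("v", Quantity(np.array([-72e-3, -66e-3, -60e-3]), mV.dim))
    cells.set_state("y", -8.0)
    cells.set_state("z_hr", 1.0)
    cells.set_state("z", 2.0)    # start far under-excitable: cells quiescent

    fast = Synapses(cells, cells, model=FAST_SYNAPSE_MODEL, namespace=ns,
                    name="fast_glutamatergic")
    fast.connect(condition=FAST_CONDITION)
    slow = Synapses(cells, cells, model=SLOW_SYNAPSE_MODEL, namespace=ns,
                    method="exponential_euler", name="slow_cholinergic")
    slow.connect(condition=SLOW_CONDITION)

    spikes = SpikeMonitor(cells)
    objs = [cells, fast, slow, spikes]
    info = {"cells": cells, "fast": fast, "slow": slow, "spikes": spikes,
            "labels": LABELS}
    if record_states:
        states = StateMonitor(cells, ["v", "Ca"], interval=record_interval)
        objs.append(states)
        info["states"] = states
    net = Network(*objs, dt=CONSTANTS["dt"])
    net.set_seed(int(rng.integers(2 ** 31)))
    info["net"] = net
    return net, info


def calcium_window_means(states, t_lo, t_hi):
    """Mean Ca per cell over the time window [t_lo, t_hi) (Quantities in s)."""
    t = states.t.value
    lo = float(t_lo.value) if isinstance(t_lo, Quantity) else t_lo
    hi = float(t_hi.value) if isinstance(t_hi, Quantity) else t_hi
    mask = (t >= lo) & (t < hi)
    ca = states.values("Ca").value
    return ca[mask].mean(axis=0)
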