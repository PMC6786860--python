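"""Closed-loop sensorimotor model: an eye tracking a drifting object.

The eye is moved laterally by two antagonistic muscles, modelled together as
a damped spring whose resting position x0 is shifted transiently -- a
muscular 'twitch' -- by every spike of the corresponding motoneuron, and
then decays back.  The stimulus is an object drifting in front of the eye
according to a stochastic (Ornstein-Uhlenbeck) process.  A retina of N
neurons with Gaussian tuning to the object's position *in eye coordinates*
(object minus gaze, i.e. eccentricity) spikes stochastically and projects
onto the motoneuron that pulls the eye toward that side, with synaptic
strength proportional to eccentricity: an object at the edge of the retina
pulls strongly, an object in the centre not at all.  Retinal neurons read
the eye and object positions through *linked variables* -- the groups are
coupled continuously, not through spikes.

Positions are dimensionless (retina spans roughly [-1, 1]).  All constants
are this package's choices, tuned for visible tracking within seconds.
"""

from __future__ import annotations

import numpy as np

from ..groups import NeuronGroup, link_variable
from ..monitors import SpikeMonitor, StateMonitor
from ..network import Network
from ..synapses import Synapses
from ..units import ms, second

CONSTANTS = {
    "tau_e": 100 * ms,        # spring time constant of the eye plant
    "tau_f": 50 * ms,         # friction time constant
    "tau_twitch": 150 * ms,   # decay of the twitch displacement x0
    "twitch_size": 0.02,      # x0 displacement per motoneuron spike
    "tau_obj": 1 * second,    # OU time constant of the object drift
    "sigma_obj": 0.6 * second ** -0.5,   # OU noise strength
    "n_retina": 100,
    "rate_max": 150,          # peak retinal rate, Hz
    "tuning_width": 0.15,     # Gaussian tuning width (position units)
    "tau_moto": 20 * ms,      # motoneuron membrane time constant
    "w_moto": 0.15,           # synaptic weight scale (x eccentricity)
    "dt": 0.5 * ms,
}

EYE_MODEL = """
dx_eye/dt = xv : 1
dxv/dt = (x0 - x_eye) / tau_e**2 - xv / tau_f : second**-1
dx0/dt = -x0 / tau_twitch : 1
"""

OBJECT_MODEL = """
dx_obj/dt = -x_obj / tau_obj + sigma_obj * xi : 1
"""

RETINA_MODEL = """
x_eye_lnk : 1 (linked)
x_obj_lnk : 1 (linked)
x_pref : 1 (constant)
rate = rate_max * exp(-((x_obj_lnk - x_eye_lnk) - x_pref)**2 / (2 * width**2)) / second : second**-1
"""

MOTO_MODEL = """
dvm/dt = -vm / tau_moto : 1
"""


def build_ocular(seed=0, gain=1.0):
    """Assemble the loop; ``gain`` scales the retina->motoneuron weights
    (gain=0 is the open-loop control with identical object path under the
    same seed).  Returns (network, info)."""
    c = CONSTANTS
    rng = np.random.default_rng(seed)
    eye = NeuronGroup(1, EYE_MODEL, namespace={"tau_e": c["tau_e"],
                                               "tau_f": c["tau_f"],
                                               "tau_twitch": c["tau_twitch"]},
                      name="eye")
    obj = NeuronGroup(1, OBJECT_MODEL,
                      namespace={"tau_obj": c["tau_obj"],
                                 "sigma_obj": c["sigma_obj"]},
                      name="object")
    retina = NeuronGroup(c["n_retina"], RETINA_MODEL,
                         threshold="rand() < rate * dt",
                         namespace={"rate_max": float(c["rate_max"]),
                                    "width": c["tuning_width"]},
                         name="retina")
    retina.set_state("x_pref", "-1 + 2 * i / (N - 1)")
    link_variable(retina, "x_eye_lnk", eye, "x_eye")
    link_variable(retina, "x_obj_lnk", obj, "x_obj")

    moto = NeuronGroup(2, MOTO_MODEL, threshold="vm > 1", reset="vm = 0",
                       namespace={"tau_moto": c["tau_moto"]}, name="motoneurons")

    # retinal neurons drive the motoneuron pulling the eye toward their side:
    # motoneuron 0 pulls in the positive direction, motoneuron 1 negative
    proj = Synapses(retina, moto, model="w : 1 (constant)",
                    on_pre="vm_post += w", name="retina_to_moto")
    proj.connect(condition="(x_pref_pre >= 0 and j == 0) or "
                           "(x_pref_pre < 0 and j == 1)")
    proj.set_state("w", f"{gain * c['w_moto']} * abs(x_pref_pre)")

    # each motoneuron spike produces a twitch of the eye's resting position
    twitch = Synapses(moto, eye, model="w_tw : 1 (constant)",
                      on_pre="x0_post += w_tw", name="twitches")
    twitch.connect(i=[0, 1], j=[0, 0])
    twitch.set_state("w_tw", f"{c['twitch_size']} * (1 - 2*i)")

    eye_mon = StateMonitor(eye, ["x_eye", "x0"], interval=20)
    obj_mon = StateMonitor(obj, "x_obj", interval=20)
    moto_spk = SpikeMonitor(moto)
    net = Network(eye, obj, retina, moto, proj, twitch,
                  eye_mon, obj_mon, moto_spk, dt=c["dt"])
    net.set_seed(int(rng.integers(2 ** 31)))
    info = {"eye": eye, "object": obj, "retina": retina, "moto": moto,
            "proj": proj, "twitch": twitch, "eye_mon": eye_mon,
            "obj_mon": obj_mon, "moto_spikes": moto_spk, "net": net}
    return net, info


def run_ocular(duration, seed=0, gain=1.0):
    """Run the loop; returns (times, eye trajectory, object trajectory, info).

    ``duration`` may be a time Quantity or plain seconds."""
    from ..units import Quantity, TIME
    if not isinstance(duration, Quantity):
        duration = Quantity(float(duration), TIME)
    net, info = build_ocular(seed=seed, gain=gain)
    net.run(duration)
    t = info["eye_mon"].t.value
    eye = info["eye_mon"].values("x_eye").value[:, 0]
    objp = info["obj_mon"].values("x_obj").value[:, 0]
    return t, eye, objp, info


def tracking_error(duration, seed=0, gain=1.0, discard=1.0):
    """Time-averaged |eye - object| after a settling period (seconds)."""
    t, eye, objp, _ = run_ocular(duration, seed=seed, gain=gain)
    mask = t >= discard
    return float(np.mean(np.abs(eye[mask] - objp[mask])))
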