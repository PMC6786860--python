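"""Pitch detection by delay-line coincidence, driven by a stored waveform.

An input cell -- an integrate-and-fire neuron with an adaptive threshold --
converts a sound waveform into a spike train.  The model code reads the
waveform through ``sound(t)``, a user-registered function sampling a stored
array at index floor(t / sample_period) (the package generates the waveform;
real-time audio capture is out of scope).  The spike train is then fed to an
array of coincidence-detector neurons through two pathways: one
instantaneous (no delay) and one with incremental delays, detector k's
delayed pathway lagging by (k+1) * delay_step.  Each detector therefore
receives the input twice with a fixed temporal shift; a periodic input whose
period matches the shift produces synchronous pairs that cross the
coincidence threshold, so the most active detector indicates the stimulus
period -- a crude autocorrelation measure of pitch.

The default stimulus is a sequence of tone bursts (pulse trains) separated
by silence; burst boundaries break coincidences at integer multiples of the
period, so the detector at the period itself wins by a margin that grows
with the number of bursts.
"""

from __future__ import annotations

import numpy as np

from ..groups import NeuronGroup, register_function
from ..monitors import SpikeMonitor
from ..network import Network
from ..synapses import Synapses
from ..units import DIMENSIONLESS, TIME, Quantity, ms, second

CONSTANTS = {
    "sample_rate": 10_000.0,     # Hz; >= 2x the highest tone frequency used
    "dt": 0.1 * ms,
    # input cell (adaptive-threshold integrate-and-fire)
    "tau_r": 0.5 * ms,           # membrane time constant of the input cell
    "gain": 2.0,                 # drive scale of sound(t)
    "vt_rest": 0.4,              # resting threshold
    "vt_jump": 0.01,             # threshold increment per spike
    "tau_vt": 30 * ms,           # threshold decay
    "input_refractory": 1.2 * ms,
    # coincidence detectors
    "n_detectors": 20,
    "delay_step": 0.5 * ms,      # detector k delay difference: (k+1)*step
    "tau_d": 0.3 * ms,           # detector membrane time constant
    "w_c": 0.8,                  # EPSP size; one is subthreshold, two are not
    "theta_d": 0.95,             # detector threshold (pairs within +-1 step fire)
    # default tone-burst stimulus
    "pulse_width": 0.3 * ms,
    "burst_duration": 80 * ms,
    "gap_duration": 25 * ms,
}

INPUT_MODEL = """
dv/dt = (gain * sound(t) - v) / tau_r : 1
dvt/dt = (vt_rest - vt) / tau_vt : 1
"""

DETECTOR_MODEL = """
dv/dt = -v / tau_d : 1
"""


def tone_burst_train(periods, n_bursts_per_tone=1, burst_duration=None,
                     gap_duration=None, pulse_width=None, sample_rate=None):
    """Waveform of pulse-train tone bursts, one burst block per entry of
    ``periods`` (time Quantities), repeated ``n_bursts_per_tone`` times each,
    separated by silent gaps.  Returns (samples array, sample_rate in Hz)."""
    c = CONSTANTS
    fs = float(sample_rate or c["sample_rate"])
    burst = float((burst_duration or c["burst_duration"]).value)
    gap = float((gap_duration or c["gap_duration"]).value)
    width = float((pulse_width or c["pulse_width"]).value)
    chunks = []
    for period in periods:
        p = float(period.value if isinstance(period, Quantity) else period)
        if 1.0 / p > fs / 2:
            raise ValueError("sample rate below twice the tone frequency")
        n_b = int(round(burst * fs))
        t = np.arange(n_b) / fs
        pulse = (t % p) < width
        for _ in range(n_bursts_per_tone):
            chunks.append(pulse.astype(float))
            chunks.append(np.zeros(int(round(gap * fs))))
    return np.concatenate(chunks), fs


def make_sound_function(waveform, sample_rate):
    """Register ``sound(t)``: sample the stored waveform at floor(t * fs)."""
    wave = np.asarray(waveform, dtype=float)
    fs = float(sample_rate)

    def _sound(t):
        idx = np.minimum((np.asarray(t) * fs).astype(np.int64), wave.size - 1)
        return wave[idx]

    return register_function("sound", _sound, arg_dims=(TIME,),
                             return_dim=DIMENSIONLESS)


def build_pitch(waveform, sample_rate=None, n_detectors=None):
    """Input cell + detector array wired through the two pathways."""
    c = CONSTANTS
    fs = float(sample_rate or c["sample_rate"])
    n_det = int(n_detectors or c["n_detectors"])
    if not np.all(np.isfinite(waveform)):
        raise ValueError("waveform must be finite")
    sound = make_sound_function(waveform, fs)

    receptor = NeuronGroup(
        1, INPUT_MODEL, threshold="v > vt", reset="v = 0; vt += vt_jump",
        refractory=c["input_refractory"],
        namespace={"gain": c["gain"], "tau_r": c["tau_r"],
                   "vt_rest": c["vt_rest"], "vt_jump": c["vt_jump"],
                   "tau_vt": c["tau_vt"], "sound": sound},
        name="input_cell")
    receptor.set_state("vt", c["vt_rest"])

    detectors = NeuronGroup(n_det, DETECTOR_MODEL, threshold="v > theta_d",
                            reset="v = 0",
                            namespace={"tau_d": c["tau_d"],
                                       "theta_d": c["theta_d"]},
                            name="detectors")

    paths = Synapses(receptor, detectors,
                     on_pre={"instantaneous": "v_post += w_c",
                             "delayed": "v_post += w_c"},
                     namespace={"w_c": c["w_c"]}, name="delay_lines")
    paths.connect(condition=None, p=None)   # full 1 x n_det cross product
    step_s = float(c["delay_step"].value)
    paths.set_state("delay", 0 * ms, pathway="instantaneous")
    paths.set_state("delay", f"(j + 1) * {step_s} * second", pathway="delayed")

    in_spikes = SpikeMonitor(receptor)
    det_spikes = SpikeMonitor(detectors)
    net = Network(receptor, detectors, paths, in_spikes, det_spikes,
                  dt=c["dt"])
    info = {"receptor": receptor, "detectors": detectors, "paths": paths,
            "input_spikes": in_spikes, "detector_spikes": det_spikes,
            "net": net, "delay_step": c["delay_step"], "n_detectors": n_det}
    return net, info


def preferred_delays(info):
    """Delay difference of each detector (Quantity, seconds)."""
    step = float(info["delay_step"].value)
    return Quantity((np.arange(info["n_detectors"]) + 1) * step, TIME)


def run_pitch(periods, n_bursts_per_tone=8, n_detectors=None):
    """Play a tone sequence; returns (detector spike counts, info)."""
    wave, fs = tone_burst_train(periods, n_bursts_per_tone=n_bursts_per_tone)
    net, info = build_pitch(wave, fs, n_detectors=n_detectors)
    duration = Quantity(wave.size / fs, TIME)
    net.run(duration)
    return info["detector_spikes"].count(), info
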