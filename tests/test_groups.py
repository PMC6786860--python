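"""NeuronGroup behaviour: state init, thresholds, refractoriness, linked
variables, user functions, trace spike extraction."""

import numpy as np
import pytest

import eqspike as eq
from eqspike.errors import (DimensionMismatch, NameCollision,
                            UnresolvedIdentifier, WriteToLinked)
from eqspike.groups import extract_spikes_from_trace, link_variable, \
    register_function
from eqspike.units import DIMENSIONLESS, Quantity, TIME, metre, ms, mV, second, volt


class TestCreateGroup:
    def test_one_neuron_lif(self):
        g = eq.NeuronGroup(1, "dv/dt = -v/tau : volt", threshold="v > -50*mV",
                           reset="v = -60*mV", namespace={"tau": 20 * ms})
        assert g.n == 1
        assert np.all(g.state("v").value == 0)   # differential vars start at 0

    def test_labelled_group(self):
        labels = {"ABPD": 0, "LP": 1, "PY": 2}
        g = eq.NeuronGroup(3, "dv/dt = -v/tau : volt\nlabel : integer (constant)",
                           namespace={"tau": 20 * ms, **labels})
        g.set_state("label", "i")
        assert g.state_arrays["label"].dtype == np.int64

    def test_nonboolean_threshold_rejected(self):
        with pytest.raises(DimensionMismatch):
            eq.NeuronGroup(1, "dv/dt = -v/tau : volt", threshold="v",
                           namespace={"tau": 20 * ms})

    def test_unknown_name_rejected_at_creation(self):
        with pytest.raises(UnresolvedIdentifier):
            eq.NeuronGroup(1, "dv/dt = -v/tau : volt")


class TestSetState:
    def test_expression_linear_in_i(self):
        g = eq.NeuronGroup(100, "gna : 1 (constant)")
        g.set_state("gna", "15 + (100 - 15) * i / (N - 1)")
        vals = g.state("gna").value
        assert vals[0] == pytest.approx(15) and vals[-1] == pytest.approx(100)
        assert np.allclose(np.diff(vals), vals[1] - vals[0])

    def test_rand_range(self):
        g = eq.NeuronGroup(1000, "dv/dt = -v/tau : volt",
                           namespace={"tau": 20 * ms})
        g.set_state("v", "-65*mV + 10*mV*rand()")
        v = g.state("v").value
        assert v.min() >= -0.065 and v.max() < -0.055

    def test_condition_subset(self):
        labels = {"LP": 1}
        g = eq.NeuronGroup(4, "x : 1\nlabel : integer (constant)",
                           namespace=labels)
        g.set_state("label", np.array([0, 1, 1, 0]))
        g.set_state("x", 7.0, subset="label == LP")
        assert np.allclose(g.state("x").value, [0, 7, 7, 0])

    def test_quantity_equals_equivalent_expression(self):
        g1 = eq.NeuronGroup(5, "dv/dt = -v/tau : volt",
                            namespace={"tau": 20 * ms})
        g2 = eq.NeuronGroup(5, "dv/dt = -v/tau : volt",
                            namespace={"tau": 20 * ms})
        g1.set_state("v", -52 * mV)
        g2.set_state("v", "-52*mV")
        assert np.array_equal(g1.state("v").value, g2.state("v").value)

    def test_wrong_dimension_rejected(self):
        g = eq.NeuronGroup(1, "dv/dt = -v/tau : volt",
                           namespace={"tau": 20 * ms})
        with pytest.raises(DimensionMismatch):
            g.set_state("v", 5 * ms)


class TestThresholdAndRefractory:
    def test_threshold_indices(self):
        g = eq.NeuronGroup(2, "dv/dt = 0*mV/ms : volt", threshold="v > -50*mV")
        g.set_state("v", Quantity(np.array([-0.07, -0.04]), volt.dim))
        g.prepare(1e-4, np.random.default_rng())
        assert g.apply_threshold(0.0, 1e-4, stamp=1).tolist() == [1]

    def test_refractory_suppresses(self):
        g = eq.NeuronGroup(1, "dv/dt = 0*mV/ms : volt", threshold="v > -50*mV",
                           refractory=5 * ms)
        g.set_state("v", -40 * mV)
        g.prepare(1e-4, np.random.default_rng())
        assert g.apply_threshold(0.0, 1e-4, stamp=1).size == 1
        # 1 ms later: still refractory
        assert g.apply_threshold(1e-3, 1e-4, stamp=11).size == 0
        # 5 ms later: allowed again
        assert g.apply_threshold(5e-3, 1e-4, stamp=51).size == 1

    def test_successive_spikes_at_least_refractory_apart(self):
        g = eq.NeuronGroup(1, "dv/dt = (v0 - v)/tau : volt",
                           threshold="v > -50*mV", reset="v = -70*mV",
                           refractory=3 * ms,
                           namespace={"tau": 5 * ms, "v0": -30 * mV})
        sm = eq.SpikeMonitor(g)
        net = eq.Network(g, sm, dt=0.1 * ms)
        net.run(100 * ms)
        assert sm.num_spikes > 3
        assert np.all(np.diff(sm.t.value) >= 3e-3 - 1e-12)

    def test_unless_refractory_freezes_variable(self):
        g = eq.NeuronGroup(1, "dv/dt = drive : volt (unless_refractory)",
                           threshold="v > 1*mV", reset="v = 0*mV",
                           refractory=5 * ms,
                           namespace={"drive": 1 * volt / second})
        sm = eq.SpikeMonitor(g)
        net = eq.Network(g, sm, dt=0.1 * ms)
        net.run(2 * ms)     # spikes at 1 ms, then frozen at reset value
        assert g.state("v").value[0] == pytest.approx(0.0)


class TestLinkedVariables:
    def _pair(self):
        src = eq.NeuronGroup(1, "dx/dt = 1/second : 1", name="eye")
        tgt = eq.NeuronGroup(100, "x_lnk : 1 (linked)\ny : 1", name="retina")
        link_variable(tgt, "x_lnk", src, "x")
        return src, tgt

    def test_all_instances_read_the_source(self):
        src, tgt = self._pair()
        src.state_arrays["x"][:] = 0.25
        assert np.all(tgt.state("x_lnk").value == 0.25)

    def test_update_visible_immediately(self):
        src, tgt = self._pair()
        net = eq.Network(src, tgt, dt=1 * ms)
        net.run(10 * ms)
        assert np.all(tgt.state("x_lnk").value ==
                      pytest.approx(src.state("x").value[0]))

    def test_linked_reads_equal_source_through_index_map(self, rng):
        src = eq.NeuronGroup(10, "q : 1")
        src.set_state("q", Quantity(rng.standard_normal(10)))
        tgt = eq.NeuronGroup(30, "q_lnk : 1 (linked)")
        idx = rng.integers(0, 10, 30)
        link_variable(tgt, "q_lnk", src, "q", index_map=idx)
        assert np.array_equal(tgt.state("q_lnk").value,
                              src.state("q").value[idx])

    def test_dimension_mismatch(self):
        src = eq.NeuronGroup(1, "x : metre")
        tgt = eq.NeuronGroup(1, "y : volt (linked)")
        with pytest.raises(DimensionMismatch):
            link_variable(tgt, "y", src, "x")

    def test_write_forbidden(self):
        _, tgt = self._pair()
        with pytest.raises(WriteToLinked):
            tgt.set_state("x_lnk", 1.0)


class TestRegisteredFunctions:
    def test_function_usable_in_model(self):
        wave = np.sin(np.linspace(0, 2 * np.pi, 1000))

        def sound(t):
            return wave[np.minimum((np.asarray(t) * 1e4).astype(int),
                                   wave.size - 1)]

        f = register_function("sound_t", sound, (TIME,), DIMENSIONLESS)
        g = eq.NeuronGroup(1, "dv/dt = (sound_t(t) - v)/tau : 1",
                           namespace={"tau": 10 * ms, "sound_t": f})
        net = eq.Network(g, dt=0.1 * ms)
        net.run(5 * ms)
        assert np.isfinite(g.state("v").value).all()

    def test_name_collision(self):
        with pytest.raises(NameCollision):
            register_function("exp", lambda x: x, (DIMENSIONLESS,),
                              DIMENSIONLESS)
        with pytest.raises(NameCollision):
            register_function("mV", lambda x: x, (DIMENSIONLESS,),
                              DIMENSIONLESS)

    def test_unregistered_function_raises_at_validation(self):
        with pytest.raises(UnresolvedIdentifier):
            eq.NeuronGroup(1, "dv/dt = mystery(t) * volt/second : volt")

    def test_builtins_available(self):
        g = eq.NeuronGroup(1, "x = clip(abs(-2.0), 0.0, 1.0) + int(exp(0)) : 1\n"
                              "y : 1")
        assert g.evaluate("x")[0] == pytest.approx(2.0)


class TestExtractSpikes:
    def test_sine_three_periods(self):
        t = np.linspace(0, 3.0, 30000)
        trace = -0.05 + 0.04 * np.sin(2 * np.pi * t)   # -50 +- 40 mV, 1 Hz
        out = extract_spikes_from_trace(Quantity(trace, volt.dim),
                                        Quantity(t, TIME), -20 * mV)
        assert len(out.value) == 3

    def test_constant_suprathreshold_trace_never_spikes(self):
        t = np.linspace(0, 1, 100)
        trace = np.full(100, -0.01)
        out = extract_spikes_from_trace(Quantity(trace, volt.dim),
                                        Quantity(t, TIME), -20 * mV)
        assert len(out.value) == 0

    def test_matches_scan_loop_oracle(self, rng):
        t = np.arange(5000) * 1e-4
        trace = rng.standard_normal(5000).cumsum() * 1e-3 - 0.05
        th = -0.045
        out = extract_spikes_from_trace(Quantity(trace, volt.dim),
                                        Quantity(t, TIME),
                                        Quantity(th, volt.dim))
        expected = [t[k] for k in range(1, 5000)
                    if trace[k] >= th and trace[k - 1] < th]
        assert np.array_equal(out.value, expected)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatch):
            extract_spikes_from_trace(Quantity(np.zeros(3), volt.dim),
                                      Quantity(np.zeros(3), TIME),
                                      5 * ms)


def test_group_loadable_from_yaml_config(tmp_path):
    cfg = tmp_path / "lif.yaml"
    cfg.write_text("""
N: 4
model: |
  dv/dt = (v0 - v)/tau : volt
threshold: v > -50*mV
reset: v = -60*mV
refractory: 5*ms
namespace:
  tau: 20*ms
  v0: -40*mV
""")
    from eqspike.config import load_group
    g = load_group(cfg)
    net = eq.Network(g, eq.SpikeMonitor(g), dt=0.1 * ms)
    net.run(30 * ms)
    assert net.monitors[0].num_spikes > 0
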