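"""State-update methods: linearity detection, exact integration, explicit
methods, stochastic integration."""

import numpy as np
import pytest
import sympy

import eqspike as eq
from eqspike.equations import parse_equations
from eqspike.integrators import detect_linear, exact_affine, make_updater
from eqspike.units import ms, mV, second
from conftest import series_affine

CUBA_EQS = """
dv/dt = (ge + gi - (v - El))/taum : volt
dge/dt = -ge/taue : volt
dgi/dt = -gi/taui : volt
"""

CUBA_CONSTS = {"taum": 0.02, "taue": 0.005, "taui": 0.01, "El": -0.049}


class TestDetectLinear:
    def test_single_decay(self):
        eqs = parse_equations("dv/dt = -v/tau : volt")
        sys_ = detect_linear(eqs, {"tau": 0.02})
        A, b = sys_.numeric({})
        assert A[0, 0] == pytest.approx(-50.0)
        assert b == pytest.approx([0.0])

    def test_cuba_matrix_matches_symbolic_differentiation(self):
        """Oracle: A[i][j] = d rhs_i / d x_j via sympy on the raw strings,
        with a constant remainder."""
        eqs = parse_equations(CUBA_EQS)
        sys_ = detect_linear(eqs, CUBA_CONSTS)
        A, b = sys_.numeric({})
        names = sys_.variables
        syms = {n: sympy.Symbol(n) for n in names}
        consts = {k: sympy.Float(v) for k, v in CUBA_CONSTS.items()}
        rhs = {
            "v": (syms["ge"] + syms["gi"] - (syms["v"] - consts["El"]))
            / consts["taum"],
            "ge": -syms["ge"] / consts["taue"],
            "gi": -syms["gi"] / consts["taui"],
        }
        for r, ni in enumerate(names):
            rest = rhs[ni]
            for c, nj in enumerate(names):
                coeff = sympy.diff(rhs[ni], syms[nj])
                assert float(coeff) == pytest.approx(A[r, c])
                rest = rest - coeff * syms[nj]
            assert float(sympy.simplify(rest)) == pytest.approx(b[r])
        # upper-triangular structure: v driven by ge/gi, not vice versa
        assert A[1, 0] == 0 and A[2, 0] == 0 and A[1, 2] == 0

    def test_nonlinear_fails_gracefully(self):
        eqs = parse_equations("dv/dt = -v**2/tau/volt : volt")
        assert detect_linear(eqs, {"tau": 0.02, "volt": 1.0}) is None

    def test_time_dependent_drive_fails(self):
        eqs = parse_equations("dv/dt = (sin(t/second)*volt - v)/tau : volt")
        assert detect_linear(eqs, {"tau": 0.02, "volt": 1.0, "second": 1.0}) \
            is None

    def test_stochastic_fails(self):
        eqs = parse_equations("dv/dt = -v/tau + sigma*xi : 1")
        assert detect_linear(eqs, {"tau": 0.02, "sigma": 1.0}) is None

    def test_per_instance_coefficients_flagged(self):
        eqs = parse_equations(
            "dv/dt = -v/taum_i : volt\ntaum_i : second (constant)")
        sys_ = detect_linear(eqs, {}, per_instance_params={"taum_i"})
        assert sys_.per_instance
        A, b = sys_.numeric({"taum_i": np.array([0.01, 0.02])}, 2)
        assert A[:, 0, 0] == pytest.approx([-100.0, -50.0])


class TestExactStep:
    def test_decay_closed_form(self):
        A, b = np.array([[-1 / 0.02]]), np.array([0.0])
        M, k = exact_affine(A, b, 0.02)
        v = M @ np.array([0.01]) + k
        assert v[0] == pytest.approx(0.01 * np.exp(-1), rel=1e-12)

    def test_cuba_matches_series_oracle(self):
        eqs = parse_equations(CUBA_EQS)
        sys_ = detect_linear(eqs, CUBA_CONSTS)
        A, b = sys_.numeric({})
        M, k = exact_affine(A, b, 1e-4)
        Ms, ks = series_affine(A, b, 1e-4)
        assert np.allclose(M, Ms, rtol=1e-13, atol=1e-16)
        assert np.allclose(k, ks, rtol=1e-12, atol=1e-18)

    def test_fixed_point_reproduced(self):
        tau = 0.02
        A, b = np.array([[-1 / tau]]), np.array([3.0])
        M, k = exact_affine(A, b, 10.0)     # many time constants
        v_inf = M @ np.array([0.0]) + k
        assert v_inf[0] == pytest.approx(3.0 * tau, rel=1e-9)

    def test_singular_matrix_uses_series_limit(self):
        # pure drift: dv/dt = c, A = 0 -> v' = v + c dt
        M, k = exact_affine(np.array([[0.0]]), np.array([2.0]), 0.5)
        assert M[0, 0] == pytest.approx(1.0) and k[0] == pytest.approx(1.0)


class _Host:
    """Minimal updater host over an equation set."""

    is_synapse = False

    def __init__(self, eqs_text, consts, n=1, seed=0):
        self.eqs = parse_equations(eqs_text)
        self.n = n
        self.consts = consts
        self.rng = np.random.default_rng(seed)
        self.state_arrays = {v: np.zeros(n) for v in self.eqs.diff_names}

    def constant_values(self):
        return dict(self.consts)

    def per_instance_params(self):
        return set()

    def function_impls(self):
        return {}

    def ns(self, t=0.0):
        from eqspike.codegen import RUNTIME_FUNCTIONS
        ns = dict(RUNTIME_FUNCTIONS)
        ns.update(self.consts)
        ns.update(self.state_arrays)
        ns["t"] = t
        return ns


class TestExplicitMethods:
    def test_euler_step_formula(self):
        host = _Host("dv/dt = -v/tau : 1", {"tau": 0.02})
        host.state_arrays["v"][:] = 1.0
        up = make_updater(host, "euler")
        up.step(host.ns(), 0.001)
        assert host.state_arrays["v"][0] == pytest.approx(1 - 0.001 / 0.02)

    def test_rk4_fourth_order_convergence(self):
        tau = 0.02

        def err(dt):
            host = _Host("dv/dt = -v/tau : 1", {"tau": tau})
            host.state_arrays["v"][:] = 1.0
            up = make_updater(host, "rk4")
            up.step(host.ns(), dt)
            return abs(host.state_arrays["v"][0] - np.exp(-dt / tau))

        e1, e2 = err(2e-3), err(1e-3)
        assert 10 < e1 / e2 < 40      # halving dt cuts error ~16x

    def test_exponential_euler_exact_on_linear(self):
        host = _Host("dv/dt = (v0 - v)/tau : 1", {"tau": 0.02, "v0": 2.0})
        up = make_updater(host, "exponential_euler")
        up.step(host.ns(), 0.01)
        expected = 2.0 * (1 - np.exp(-0.5))
        assert host.state_arrays["v"][0] == pytest.approx(expected, rel=1e-12)

    def test_exponential_euler_stable_where_euler_diverges(self):
        # stiff decay: tau = 0.1 ms, dt = 1 ms
        for method, ok in (("euler", False), ("exponential_euler", True)):
            host = _Host("dv/dt = -v/tau : 1", {"tau": 1e-4})
            host.state_arrays["v"][:] = 1.0
            up = make_updater(host, method)
            for _ in range(50):
                up.step(host.ns(), 1e-3)
            stable = abs(host.state_arrays["v"][0]) < 1.0
            assert stable == ok

    def test_dimensions_preserved_through_updates(self):
        g = eq.NeuronGroup(3, "dv/dt = -v/tau : volt",
                           namespace={"tau": 20 * ms})
        g.set_state("v", -60 * mV)
        net = eq.Network(g, dt=0.1 * ms)
        net.run(1 * ms)
        assert g.state("v").dim == mV.dim


class TestEulerMaruyama:
    def test_zero_noise_equals_euler(self):
        h1 = _Host("dv/dt = -v/tau + 0.0*xi : 1", {"tau": 0.02})
        h2 = _Host("dv/dt = -v/tau : 1", {"tau": 0.02})
        for h in (h1, h2):
            h.state_arrays["v"][:] = 1.0
        make_updater(h1, "euler_maruyama").step(dict(h1.ns(), xi=0.0), 1e-3)
        make_updater(h2, "euler").step(h2.ns(), 1e-3)
        assert h1.state_arrays["v"][0] == pytest.approx(h2.state_arrays["v"][0])

    def test_pure_noise_variance(self, rng):
        # dx/dt = sigma*xi: Var(x(t)) = sigma^2 t
        n, sigma, dt, steps = 4000, 0.7, 1e-3, 200
        host = _Host("dx/dt = sigma*xi : 1", {"sigma": sigma}, n=n)
        host.rng = rng
        up = make_updater(host, None)
        assert type(up).__name__ == "EulerMaruyamaUpdater"
        for _ in range(steps):
            up.step(host.ns(), dt)
        var = host.state_arrays["x"].var()
        assert var == pytest.approx(sigma ** 2 * steps * dt, rel=0.1)

    def test_ou_stationary_std(self, rng):
        # dx/dt = -x/tau + sigma*xi: stationary std = sigma*sqrt(tau/2)
        n, tau, sigma, dt = 4000, 0.01, 1.5, 1e-4
        host = _Host("dx/dt = -x/tau + sigma*xi : 1",
                     {"tau": tau, "sigma": sigma}, n=n)
        host.rng = rng
        up = make_updater(host, None)
        for _ in range(int(8 * tau / dt)):
            up.step(host.ns(), dt)
        expected = sigma * np.sqrt(tau / 2)
        assert host.state_arrays["x"].std() == pytest.approx(expected, rel=0.08)


def test_per_instance_exact_equals_scalar_loop(rng):
    """Heterogeneous linear update == instance-by-instance scalar update."""
    n = 17
    taus = rng.uniform(0.01, 0.04, n)
    g = eq.NeuronGroup(n, "dv/dt = (El - v)/taum_i : volt\n"
                          "taum_i : second (constant)",
                       namespace={"El": -49 * mV})
    g.state_arrays["taum_i"][:] = taus
    v0 = rng.uniform(-0.07, -0.05, n)
    g.state_arrays["v"][:] = v0
    net = eq.Network(g, dt=0.1 * ms)
    net.run(5 * ms)
    assert type(g.updater).__name__ == "ExactUpdater"
    assert g.updater.system.per_instance
    expected = np.empty(n)
    for k in range(n):      # scalar oracle, one instance at a time
        M, kk = exact_affine(np.array([[-1 / taus[k]]]),
                             np.array([-0.049 / taus[k]]), 1e-4)
        x = v0[k]
        for _ in range(50):
            x = M[0, 0] * x + kk[0]
        expected[k] = x
    assert np.allclose(g.state("v").value, expected, rtol=1e-12)
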