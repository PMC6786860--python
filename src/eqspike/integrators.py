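"""State-update methods.

The default policy mirrors how a clock-driven simulator should treat each
model: linear constant-coefficient deterministic systems get *exact
integration* (a per-timestep affine update ``x' = M x + k`` with
``M = exp(A dt)``, error-free per step); other deterministic systems get
exponential Euler; anything containing the noise symbol ``xi`` gets
Euler-Maruyama.  The user can override the method per group.

Linearity is detected symbolically: after inlining subexpressions, the
Jacobian of the right-hand sides with respect to the state variables must be
constant (it may reference per-instance parameters such as heterogeneous
time constants, in which case one update matrix is precomputed per instance)
and the remainder must be a constant drive vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy
from scipy.linalg import expm

from ._sympy_bridge import inline_subexpressions
from .codegen import RUNTIME_FUNCTIONS, compile_expression
from .equations import order_subexpressions
from .errors import IntegrationError

__all__ = [
    "LinearSystem", "detect_linear", "exact_affine", "choose_method",
    "ExactUpdater", "EulerUpdater", "RK4Updater", "ExponentialEulerUpdater",
    "EulerMaruyamaUpdater", "make_updater", "METHODS",
]


# ---------------------------------------------------------------------------
# Linearity detection and exact integration
# ---------------------------------------------------------------------------

@dataclass
class LinearSystem:
    """d/dt state = A state + b, established symbolically.

    ``A_sym``/``b_sym`` are sympy matrices whose free symbols are all in
    ``coefficient_names``; ``per_instance`` is True when any coefficient
    references a per-instance parameter.
    """

    variables: list[str]
    A_sym: sympy.Matrix
    b_sym: sympy.Matrix
    coefficient_names: set[str]
    per_instance: bool

    def numeric(self, values, n_instances=1):
        """Evaluate A and b with ``values`` (name -> float or length-N array).

        Returns (A, b) with shapes (n, n)/(n,) for shared coefficients or
        (N, n, n)/(N, n) when per-instance.
        """
        n = len(self.variables)
        syms = sorted(self.coefficient_names)
        args = [sympy.Symbol(s, real=True) for s in syms]
        fA = sympy.lambdify(args, self.A_sym, modules="numpy")
        fb = sympy.lambdify(args, self.b_sym, modules="numpy")
        vals = [values[s] for s in syms]
        if not self.per_instance:
            A = np.asarray(fA(*vals), dtype=float).reshape(n, n)
            b = np.asarray(fb(*vals), dtype=float).reshape(n)
            return A, b
        vals = [np.broadcast_to(np.asarray(v, dtype=float), (n_instances,))
                for v in vals]
        A = np.empty((n_instances, n, n))
        b = np.empty((n_instances, n))
        for idx in range(n_instances):
            vi = [v[idx] for v in vals]
            A[idx] = np.asarray(fA(*vi), dtype=float).reshape(n, n)
            b[idx] = np.asarray(fb(*vi), dtype=float).reshape(n)
        return A, b


def detect_linear(eqs, constants, per_instance_params=()):
    """Try to write the deterministic EquationSet as d/dt x = A x + b.

    ``constants`` maps scalar constant names to floats (units included);
    ``per_instance_params`` are names whose values vary across instances.
    Returns a LinearSystem, or None for nonlinear / time-dependent /
    stochastic systems (failure is a value, not an exception).
    """
    variables = eqs.diff_names
    if not variables:
        return None
    for v in variables:
        if "xi" in eqs[v].expr.identifiers:
            return None
    try:
        rhs, _ = inline_subexpressions(eqs)
    except Exception:
        return None
    state_syms = [sympy.Symbol(v, real=True) for v in variables]
    t_sym = sympy.Symbol("t", real=True)
    n = len(variables)
    A = sympy.zeros(n, n)
    b = sympy.zeros(n, 1)
    coeff_names = set()
    per_instance = False
    allowed = set(constants) | set(per_instance_params)
    for i, v in enumerate(variables):
        f = sympy.expand(rhs[v])
        if f.atoms(sympy.Function):
            return None        # opaque user functions => not constant-coefficient
        rest = f
        for j, x in enumerate(state_syms):
            coeff = sympy.diff(f, x)
            if any(coeff.has(s) for s in state_syms) or coeff.has(t_sym):
                return None
            A[i, j] = sympy.simplify(coeff)
            rest = rest - coeff * x
        rest = sympy.simplify(sympy.expand(rest))
        if any(rest.has(s) for s in state_syms) or rest.has(t_sym):
            return None
        b[i] = rest
        free = {str(s) for s in (A[i, :].free_symbols | rest.free_symbols)}
        if not free <= allowed:
            return None
        coeff_names |= free
        if free & set(per_instance_params):
            per_instance = True
    # substitute scalar constants now; keep per-instance parameters symbolic
    subs = [(sympy.Symbol(name, real=True), float(val))
            for name, val in constants.items() if name in coeff_names]
    A = A.subs(subs)
    b = b.subs(subs)
    remaining = {str(s) for s in (A.free_symbols | b.free_symbols)}
    return LinearSystem(variables, A, b, remaining, per_instance)


def exact_affine(A, b, dt):
    """Affine update (M, k) with state' = M state + k over one step of dt.

    M = exp(A dt); k = integral_0^dt exp(A s) b ds, computed for any A
    (invertible or not) through the augmented matrix exponential
    exp([[A, b], [0, 0]] dt) = [[M, k], [0, 1]].
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[-1]
    if A.ndim == 2:
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = A * dt
        aug[:n, n] = b * dt
        E = expm(aug)
        M, k = E[:n, :n], E[:n, n]
    else:
        M = np.empty_like(A)
        k = np.empty_like(b)
        for idx in range(A.shape[0]):
            M[idx], k[idx] = exact_affine(A[idx], b[idx], dt)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(k))):
        raise IntegrationError("matrix exponential produced non-finite entries")
    return M, k


# ---------------------------------------------------------------------------
# Updaters
# ---------------------------------------------------------------------------

class _Updater:
    """Base: holds the compiled rhs plan for one group/pathway."""

    needs_rhs_kernels = True

    def __init__(self, host):
        self.host = host
        eqs = host.eqs
        self.diff_vars = eqs.diff_names
        if self.needs_rhs_kernels:
            order = order_subexpressions(eqs)
            self.sub_kernels = [(name, compile_expression(eqs[name].expr))
                                for name in order
                                if eqs[name].kind == "subexpression"
                                and not eqs[name].is_summed]
            self.rhs_kernels = {v: compile_expression(eqs[v].expr)
                                for v in self.diff_vars}

    def prepare(self, dt):
        """Called at run start (and again if dt changes)."""

    def derivatives(self, ns, overrides=None):
        local = dict(ns)
        if overrides:
            local.update(overrides)
        for name, kern in self.sub_kernels:
            local[name] = kern.evaluate(local)
        return {v: np.asarray(kern.evaluate(local), dtype=float)
                for v, kern in self.rhs_kernels.items()}

    def step(self, ns, dt):
        raise NotImplementedError


class EulerUpdater(_Updater):
    """Explicit forward Euler: x' = x + f(x, t) dt."""

    def step(self, ns, dt):
        state = self.host.state_arrays
        derivs = self.derivatives(ns)
        for v in self.diff_vars:
            state[v] += dt * derivs[v]


class RK4Updater(_Updater):
    """Classical fourth-order Runge-Kutta."""

    def step(self, ns, dt):
        state = self.host.state_arrays
        t = ns["t"]
        y0 = {v: state[v].copy() for v in self.diff_vars}
        k1 = self.derivatives(ns)
        k2 = self.derivatives(ns, {**{v: y0[v] + 0.5 * dt * k1[v]
                                      for v in self.diff_vars}, "t": t + 0.5 * dt})
        k3 = self.derivatives(ns, {**{v: y0[v] + 0.5 * dt * k2[v]
                                      for v in self.diff_vars}, "t": t + 0.5 * dt})
        k4 = self.derivatives(ns, {**{v: y0[v] + dt * k3[v]
                                      for v in self.diff_vars}, "t": t + dt})
        for v in self.diff_vars:
            state[v][...] = y0[v] + (dt / 6.0) * (k1[v] + 2 * k2[v] + 2 * k3[v] + k4[v])


class ExponentialEulerUpdater(_Updater):
    """Per-variable exponentially-exact update of a local affine model.

    Each rhs f is decomposed symbolically as f = a + b x (b = df/dx, a = f - b x,
    both evaluated on the current state with the other variables frozen); x is
    then updated exactly under that frozen affine dynamics:
    x' = x e^{b dt} + (a/b)(e^{b dt} - 1), with the b -> 0 limit x + a dt.
    """

    needs_rhs_kernels = False

    def __init__(self, host):
        super().__init__(host)
        rhs, _ = inline_subexpressions(host.eqs)
        consts = host.constant_values()
        self._plan = []
        modules = [dict(RUNTIME_FUNCTIONS), dict(host.function_impls()), "numpy"]
        for v in self.diff_vars:
            x = sympy.Symbol(v, real=True)
            f = rhs[v]
            b = sympy.diff(f, x)
            a = sympy.expand(f - b * x)
            subs = [(sympy.Symbol(k, real=True), float(val))
                    for k, val in consts.items()]
            a, b = a.subs(subs), b.subs(subs)
            args = sorted({str(s) for s in (a.free_symbols | b.free_symbols)})
            arg_syms = [sympy.Symbol(s, real=True) for s in args]
            fa = sympy.lambdify(arg_syms, a, modules=modules)
            fb = sympy.lambdify(arg_syms, b, modules=modules)
            self._plan.append((v, args, fa, fb))

    def step(self, ns, dt):
        state = self.host.state_arrays
        new = {}
        for v, args, fa, fb in self._plan:
            vals = [ns[a] for a in args]
            a = np.asarray(fa(*vals), dtype=float)
            b = np.asarray(fb(*vals), dtype=float)
            x = state[v]
            bd = b * dt
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                exact = x * np.exp(bd) + (a / b) * np.expm1(bd)
            limit = x + (a + b * x) * dt
            new[v] = np.where(np.abs(bd) > 1e-12, exact, limit)
        for v in self.diff_vars:
            state[v][...] = new[v]


class EulerMaruyamaUpdater(_Updater):
    """Explicit first-order scheme for stochastic systems.

    The reserved symbol xi is bound to eta/sqrt(dt) with eta ~ N(0, 1) per
    instance per step (drawn from the network RNG); one Euler step of the full
    rhs then equals x + f dt + g sqrt(dt) eta for any rhs linear in xi, which
    :func:`detect_stochastic` guarantees.
    """

    def step(self, ns, dt):
        state = self.host.state_arrays
        n = self.host.n
        eta = self.host.rng.standard_normal(n)
        derivs = self.derivatives(ns, {"xi": eta / np.sqrt(dt)})
        for v in self.diff_vars:
            state[v] += dt * derivs[v]


class ExactUpdater(_Updater):
    """Precomputed affine update for linear constant-coefficient systems."""

    needs_rhs_kernels = False

    def __init__(self, host, system):
        super().__init__(host)
        self.system = system
        self._M = self._k = None
        self._dt = None

    def prepare(self, dt):
        if self._dt == dt:
            return
        values = dict(self.host.constant_values())
        for p in self.system.coefficient_names:
            if p not in values:
                values[p] = self.host.state_arrays[p]
        A, b = self.system.numeric(values, self.host.n)
        self._M, self._k = exact_affine(A, b, dt)
        self._dt = dt

    def step(self, ns, dt):
        state = self.host.state_arrays
        vars_ = self.system.variables
        if self.system.per_instance:
            X = np.stack([state[v] for v in vars_], axis=-1)          # (N, n)
            out = np.einsum("nij,nj->ni", self._M, X) + self._k
            for j, v in enumerate(vars_):
                state[v][...] = out[:, j]
        else:
            X = np.stack([state[v] for v in vars_], axis=0)           # (n, N)
            out = self._M @ X + self._k[:, None]
            for j, v in enumerate(vars_):
                state[v][...] = out[j]


METHODS = {
    "exact": ExactUpdater,
    "euler": EulerUpdater,
    "rk4": RK4Updater,
    "exponential_euler": ExponentialEulerUpdater,
    "euler_maruyama": EulerMaruyamaUpdater,
}


def choose_method(eqs, constants, per_instance_params=(), stochastic=None):
    """Default method policy: exact if linear and deterministic, otherwise
    exponential Euler; Euler-Maruyama is forced when xi is present."""
    from .equations import detect_stochastic

    if stochastic is None:
        stochastic = detect_stochastic(eqs)
    if stochastic:
        return "euler_maruyama", None
    system = detect_linear(eqs, constants, per_instance_params)
    if system is not None:
        return "exact", system
    return "exponential_euler", None


def make_updater(host, method=None):
    """Instantiate the updater for a group/pathway, honouring overrides."""
    from .equations import detect_stochastic

    eqs = host.eqs
    if not eqs.diff_names:
        return None
    stochastic = detect_stochastic(eqs)
    if method is None:
        method, system = choose_method(
            eqs, host.constant_values(), host.per_instance_params(), stochastic)
        if method == "exact":
            return ExactUpdater(host, system)
        return METHODS[method](host)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    if stochastic and method != "euler_maruyama":
        raise ValueError("stochastic equations require the euler_maruyama method")
    if method == "exact":
        system = detect_linear(eqs, host.constant_values(), host.per_instance_params())
        if system is None:
            raise ValueError("exact integration requires a linear "
                             "constant-coefficient system")
        return ExactUpdater(host, system)
    return METHODS[method](host)
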