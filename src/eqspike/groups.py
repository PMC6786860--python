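"""Populations of model instances.

A :class:`NeuronGroup` is N instances sharing one equation set, with
per-variable state arrays, an optional threshold condition, reset statements
and a refractory period.  State can be initialized from quantities or from
expression strings evaluated per instance (which may use ``i``, ``N``,
``rand()``/``randn()`` and other state variables).  Variables of other groups
can be read through *linked* parameter entries, and arbitrary user functions
can be registered and called from any expression.
"""

from __future__ import annotations

import numpy as np

from .codegen import (CodeBlock, RUNTIME_FUNCTIONS, compile_expression,
                      compile_statements)
from .equations import (RESERVED_DIMS, Expression, infer_dimension,
                        order_subexpressions, parse_equations,
                        parse_expression, validate_dimensions)
from .errors import (DimensionMismatch, EqspikeError, IntegrationError,
                     NameCollision, UnresolvedIdentifier, WriteToLinked)
from .units import DIMENSIONLESS, TIME, Quantity, UNIT_REGISTRY, get_dimension

__all__ = ["NeuronGroup", "RegisteredFunction", "register_function",
           "LinkedBinding", "link_variable", "extract_spikes_from_trace"]


class RegisteredFunction:
    """A user function callable from model code, with a dimension signature."""

    def __init__(self, name, implementation, arg_dims, return_dim):
        self.name = name
        self.implementation = implementation
        self.arg_dims = tuple(arg_dims)
        self.return_dim = return_dim

    def __call__(self, *args):
        return self.implementation(*args)


def register_function(name, implementation, arg_dims, return_dim):
    """Create a RegisteredFunction after checking the name is free."""
    from .codegen import RUNTIME_FUNCTIONS as builtins_

    if name in UNIT_REGISTRY or name in RESERVED_DIMS or name in builtins_:
        raise NameCollision(f"function name {name!r} is already bound")
    return RegisteredFunction(name, implementation, arg_dims, return_dim)


class LinkedBinding:
    """Read-only view of a source group's variable through an index map."""

    def __init__(self, target, target_var, source, source_var, index_map=None):
        self.target = target
        self.target_var = target_var
        self.source = source
        self.source_var = source_var
        if index_map is None:
            if source.n == 1:
                index_map = np.zeros(target.n, dtype=np.int64)
            elif source.n == target.n:
                index_map = np.arange(target.n, dtype=np.int64)
            else:
                raise EqspikeError(
                    "an explicit index_map is required when group sizes differ")
        elif callable(index_map):
            index_map = np.asarray([index_map(k) for k in range(target.n)],
                                   dtype=np.int64)
        else:
            index_map = np.asarray(index_map, dtype=np.int64)
        if index_map.shape != (target.n,) or index_map.min() < 0 \
                or index_map.max() >= source.n:
            raise EqspikeError("index_map must map every target index to a "
                               "valid source index")
        self.index_map = index_map

    def read(self):
        return self.source.state_arrays[self.source_var][self.index_map]


def link_variable(target, target_var, source, source_var, index_map=None):
    """Bind ``target.target_var`` (a parameter flagged ``linked``) to always
    reflect ``source.source_var`` through ``index_map``."""
    entry = target.eqs[target_var]
    if "linked" not in entry.flags:
        raise EqspikeError(f"{target_var!r} is not declared '(linked)'")
    src_dim = source.eqs[source_var].dim
    if entry.dim != src_dim:
        raise DimensionMismatch(
            f"cannot link {target_var} ({entry.dim}) to {source_var} ({src_dim})",
            entry.dim, src_dim)
    binding = LinkedBinding(target, target_var, source, source_var, index_map)
    target.linked[target_var] = binding
    return binding


_NO_SPIKE = np.int64(-(10 ** 15))


class NeuronGroup:
    """N model instances sharing an EquationSet.

    Parameters
    ----------
    N : int
        Number of instances.
    model : str
        Unit-annotated equation string (see :mod:`eqspike.equations`).
    threshold : str, optional
        Dimensionless boolean condition; instances where it holds (and that
        are not refractory) emit a spike.
    reset : str, optional
        Statements executed for each spiking instance after delivery.
    refractory : Quantity (seconds), optional
        Threshold is suppressed for this long after each spike; differential
        variables flagged ``unless_refractory`` are frozen during the window.
    method : str, optional
        Integration method override (see :mod:`eqspike.integrators`).
    namespace : dict, optional
        Constants (Quantity or number) and RegisteredFunctions for the model.
    """

    is_synapse = False

    def __init__(self, N, model, threshold=None, reset=None, refractory=None,
                 method=None, namespace=None, name=None):
        self.n = int(N)
        if self.n <= 0:
            raise ValueError("N must be positive")
        self.name = name or f"group_{id(self):x}"
        self.namespace = dict(namespace or {})
        self.eqs = parse_equations(model) if isinstance(model, str) else model
        self.method = method
        self.linked = {}
        self.rng = np.random.default_rng()   # replaced by the network at build

        self._functions = {k: v for k, v in self.namespace.items()
                           if isinstance(v, RegisteredFunction)}
        self._validate()

        # state arrays, always SI-scaled; differential variables start at 0
        self.state_arrays: dict[str, np.ndarray] = {}
        for e in self.eqs:
            if e.kind == "subexpression":
                continue
            if "linked" in e.flags:
                continue
            dtype = {"integer": np.int64, "boolean": bool}.get(e.var_type, float)
            self.state_arrays[e.name] = np.zeros(self.n, dtype=dtype)
        self.last_spike_step = np.full(self.n, _NO_SPIKE, dtype=np.int64)

        self._sub_order = [nm for nm in order_subexpressions(self.eqs)
                           if self.eqs[nm].kind == "subexpression"
                           and not self.eqs[nm].is_summed]
        self._sub_kernels = {nm: compile_expression(self.eqs[nm].expr)
                             for nm in self._sub_order}

        self.threshold_expr = None
        if threshold is not None:
            expr = parse_expression(threshold, f"threshold of {self.name}")
            info = infer_dimension(expr, self._dim_namespace(),
                                   self._function_signatures(),
                                   context=f"threshold of {self.name}")
            if not (info.boolean or
                    (info.dim.is_dimensionless and self._is_boolean_var(expr))):
                raise DimensionMismatch(
                    f"threshold of {self.name} must be a boolean expression, "
                    f"got dimension {info.dim}")
            self.threshold_expr = compile_expression(expr)

        self.reset_block = None
        if reset is not None:
            self.reset_block = self._compile_statements(reset, kind="reset")

        if refractory is not None:
            if get_dimension(refractory) != TIME:
                raise DimensionMismatch("refractory must be a time quantity")
            self.refractory = float(refractory.value)
        else:
            self.refractory = None
        self._ref_steps = 0
        self._frozen_vars = [e.name for e in self.eqs
                             if e.kind == "differential"
                             and "unless_refractory" in e.flags]

        self.updater = None
        self._base_ns = None

    # -- validation helpers ---------------------------------------------------
    def _dim_namespace(self):
        dims = {}
        for k, v in self.namespace.items():
            if isinstance(v, RegisteredFunction):
                continue
            dims[k] = get_dimension(v) if isinstance(v, Quantity) else DIMENSIONLESS
        for e in self.eqs:
            dims[e.name] = e.dim
        return dims

    def _function_signatures(self):
        return {f.name: (f.arg_dims, f.return_dim)
                for f in self._functions.values()}

    def _is_boolean_var(self, expr):
        import ast
        return isinstance(expr.node, ast.Name) and \
            expr.node.id in self.eqs and \
            self.eqs[expr.node.id].var_type == "boolean"

    def _validate(self):
        validate_dimensions(self.eqs, self._dim_namespace(),
                            self._function_signatures())
        from .equations import _BUILTIN_FUNCS
        known = set(self._dim_namespace()) | set(UNIT_REGISTRY) | \
            set(RESERVED_DIMS) | set(_BUILTIN_FUNCS) | set(self._functions)
        missing = self.eqs.identifiers - known
        # suffixed names are resolved by synapse populations, not here
        missing = {m for m in missing
                   if not (self.is_synapse and
                           (m.endswith("_pre") or m.endswith("_post")))}
        if missing:
            raise UnresolvedIdentifier(missing, self.name)

    # -- info used by the integrators -----------------------------------------
    def constant_values(self):
        """Scalar SI values of every constant name reachable from the model."""
        out = {}
        for k, v in self.namespace.items():
            if isinstance(v, RegisteredFunction):
                continue
            out[k] = float(v.value) if isinstance(v, Quantity) else float(v)
        for ident in self.eqs.identifiers:
            if ident in UNIT_REGISTRY and ident not in out:
                out[ident] = float(UNIT_REGISTRY[ident].value)
        return out

    def per_instance_params(self):
        """Parameters that may appear in exact-integration coefficients: only
        ``constant``-flagged ones (anything else -- e.g. a summed-variable
        target -- changes between steps, so linearity detection must fail
        and a step-wise method be used instead)."""
        return {e.name for e in self.eqs
                if e.kind == "parameter" and e.is_constant
                and "linked" not in e.flags}

    def function_impls(self):
        impls = {f.name: f.implementation for f in self._functions.values()}
        return impls

    # -- runtime namespace -----------------------------------------------------
    def _build_base_ns(self):
        ns = dict(RUNTIME_FUNCTIONS)
        for uname, uq in UNIT_REGISTRY.items():
            ns[uname] = float(uq.value)
        ns.update(self.constant_values())
        ns.update(self.function_impls())
        ns.update(self.state_arrays)       # arrays by reference, mutated in place
        ns["i"] = np.arange(self.n)
        ns["N"] = self.n
        self._base_ns = ns
        return ns

    def eval_namespace(self, t, dt):
        ns = self._base_ns if self._base_ns is not None else self._build_base_ns()
        ns["t"] = t
        ns["dt"] = dt
        ns["rand"] = lambda: self.rng.random(self.n)
        ns["randn"] = lambda: self.rng.standard_normal(self.n)
        for var, binding in self.linked.items():
            ns[var] = binding.read()
        return ns

    def evaluate(self, expression, t=0.0, dt=0.0, indices=None, extra=None):
        """Evaluate an expression string over the group's current state.

        Subexpressions of the model are made available; returns a bare array
        (SI scale)."""
        if isinstance(expression, str):
            expression = parse_expression(expression, f"evaluate in {self.name}")
        kern = compile_expression(expression)
        ns = dict(self.eval_namespace(t, dt))
        if extra:
            ns.update(extra)
        # only the subexpressions the target (transitively) needs
        needed = set(expression.identifiers)
        for nm in reversed(self._sub_order):
            if nm in needed:
                needed |= self.eqs[nm].expr.identifiers
        for nm in self._sub_order:
            if nm in needed:
                ns[nm] = self._sub_kernels[nm].evaluate(ns)
        out = kern.evaluate(ns)
        out = np.broadcast_to(out, (self.n,)).copy() if np.ndim(out) == 0 \
            else np.asarray(out)
        return out[indices] if indices is not None else out

    # -- state access ----------------------------------------------------------
    def state(self, variable):
        """Current values of ``variable`` as a Quantity (copy)."""
        if variable in self.linked:
            vals = self.linked[variable].read()
            return Quantity(vals, self.eqs[variable].dim)
        arr = self.state_arrays[variable]
        dim = self.eqs[variable].dim if variable in self.eqs else DIMENSIONLESS
        return Quantity(arr.astype(float).copy(), dim)

    def _resolve_subset(self, subset):
        if subset is None:
            return slice(None)
        if isinstance(subset, str):
            mask = self.evaluate(subset)
            if mask.dtype != bool:
                raise EqspikeError(f"subset condition {subset!r} is not boolean")
            return np.flatnonzero(mask)
        idx = np.asarray(subset)
        if idx.dtype == bool:
            return np.flatnonzero(idx)
        if idx.size and (idx.min() < -self.n or idx.max() >= self.n):
            raise IndexError("subset index out of range")
        return idx

    def set_state(self, variable, value, subset=None):
        """Assign ``variable`` over ``subset`` (indices, mask or condition string).

        ``value`` may be a Quantity/number or an expression string evaluated
        per instance (usable names: i, N, rand(), randn(), state variables).
        """
        if variable in self.linked or \
                (variable in self.eqs and "linked" in self.eqs[variable].flags):
            raise WriteToLinked(f"{variable!r} is linked and read-only")
        if variable not in self.state_arrays:
            raise EqspikeError(f"unknown state variable {variable!r} in {self.name}")
        entry = self.eqs[variable]
        idx = self._resolve_subset(subset)
        if isinstance(value, str):
            expr = parse_expression(value, f"set_state({variable})")
            info = infer_dimension(expr, self._dim_namespace(),
                                   self._function_signatures(),
                                   context=f"set_state({variable})")
            if info.dim != entry.dim and not info.boolean:
                raise DimensionMismatch(
                    f"set_state({variable}): expression has dimension {info.dim}, "
                    f"variable has {entry.dim}", info.dim, entry.dim)
            vals = self.evaluate(expr)
        else:
            dim = get_dimension(value)
            if dim != entry.dim:
                raise DimensionMismatch(
                    f"set_state({variable}): value has dimension {dim}, "
                    f"variable has {entry.dim}", dim, entry.dim)
            vals = value.value if isinstance(value, Quantity) else value
            vals = np.broadcast_to(np.asarray(vals), np.shape(self.state_arrays[variable][idx]))
        arr = self.state_arrays[variable]
        arr[idx] = vals if arr.dtype != np.int64 else np.asarray(vals).astype(np.int64)
        return self

    # -- statement execution ----------------------------------------------------
    def _compile_statements(self, text, kind):
        writable = set(self.state_arrays)
        constants = {e.name for e in self.eqs if e.is_constant} | \
            set(self.namespace) | set(self.linked) | \
            {e.name for e in self.eqs if "linked" in e.flags}
        block = compile_statements(text, writable, constants, kind=kind,
                                   context=f"{kind} of {self.name}")
        # dimension check per statement
        dims = self._dim_namespace()
        for st in block.statements:
            expr = parse_expression(st.expr.source)
            info = infer_dimension(expr, dims, self._function_signatures(),
                                   context=f"{kind} of {self.name}")
            target_dim = dims[st.target]
            if st.op in ("=", "+=", "-="):
                if info.dim != target_dim and not info.boolean:
                    raise DimensionMismatch(
                        f"{kind}: {st.target} {st.op} expression of dimension "
                        f"{info.dim}, variable has {target_dim}")
            elif not info.dim.is_dimensionless:
                raise DimensionMismatch(
                    f"{kind}: {st.target} {st.op} needs a dimensionless rhs")
        return block

    def _statement_namespace(self, names, indices):
        ns = dict(RUNTIME_FUNCTIONS)
        for nm in names:
            if nm in UNIT_REGISTRY:
                ns[nm] = float(UNIT_REGISTRY[nm].value)
        ns.update(self.constant_values())
        ns.update(self.function_impls())
        n_sel = len(np.atleast_1d(np.arange(self.n)[indices])) \
            if not isinstance(indices, np.ndarray) else len(indices)
        ns["rand"] = lambda: self.rng.random(n_sel)
        ns["randn"] = lambda: self.rng.standard_normal(n_sel)
        ns["N"] = self.n
        ns["i"] = np.arange(self.n)[indices]
        ns["t"] = self._current_t
        ns["dt"] = self._current_dt
        for var, binding in self.linked.items():
            if var in names:
                ns[var] = binding.read()[indices]
        for var, arr in self.state_arrays.items():
            if var in names:
                ns[var] = arr[indices]
        for nm in self._sub_order:
            if nm in names:
                ns[nm] = self.evaluate(self.eqs[nm].expr.code,
                                       self._current_t, self._current_dt)[indices]
        return ns

    def _write(self, target, op, indices, values, ns):
        arr = self.state_arrays[target]
        if op == "=":
            arr[indices] = values
        elif op == "+=":
            np.add.at(arr, indices, values)
        elif op == "-=":
            np.subtract.at(arr, indices, values)
        elif op == "*=":
            np.multiply.at(arr, indices, values)
        elif op == "/=":
            np.divide.at(arr, indices, values)
        ns[target] = arr[indices]

    _current_t = 0.0
    _current_dt = 0.0

    # -- per-timestep operations -------------------------------------------------
    def prepare(self, dt, rng):
        from .integrators import make_updater

        self.rng = rng
        for e in self.eqs:
            if "linked" in e.flags and e.name not in self.linked:
                raise EqspikeError(
                    f"linked variable {e.name!r} of {self.name} was never bound "
                    "with link_variable()")
        if self.updater is None:
            self.updater = make_updater(self, self.method)
        if self.updater is not None:
            self.updater.prepare(dt)
        if self.refractory is not None:
            self._ref_steps = int(np.ceil(self.refractory / dt - 1e-9))
        self._build_base_ns()

    def _refractory_mask(self, stamp):
        if self._ref_steps <= 0:
            return None
        return (stamp - self.last_spike_step) < self._ref_steps

    def state_update(self, t, dt, stamp):
        if self.updater is None:
            return
        self._current_t, self._current_dt = t, dt
        frozen = None
        if self._frozen_vars:
            mask = self._refractory_mask(stamp)
            if mask is not None and mask.any():
                frozen = {v: self.state_arrays[v][mask] for v in self._frozen_vars}
        ns = self.eval_namespace(t, dt)
        self.updater.step(ns, dt)
        if frozen is not None:
            for v, vals in frozen.items():
                self.state_arrays[v][mask] = vals
        for v in self.eqs.diff_names:
            arr = self.state_arrays[v]
            if not np.all(np.isfinite(arr)):
                raise IntegrationError(
                    f"variable {v!r} of {self.name} became non-finite at t={t}")

    def apply_threshold(self, t, dt, stamp):
        """Spike index vector at this timestep (refractory instances excluded)."""
        if self.threshold_expr is None:
            return np.empty(0, dtype=np.int64)
        self._current_t, self._current_dt = t, dt
        ns = self.eval_namespace(t, dt)
        for nm in self._sub_order:
            ns[nm] = self._sub_kernels[nm].evaluate(ns)
        cond = np.broadcast_to(np.asarray(self.threshold_expr.evaluate(ns)),
                               (self.n,))
        mask = self._refractory_mask(stamp)
        if mask is not None:
            cond = cond & ~mask
        spikes = np.flatnonzero(cond)
        if spikes.size:
            self.last_spike_step[spikes] = stamp
        return spikes

    def apply_reset(self, spikes, t, dt):
        if self.reset_block is None or spikes.size == 0:
            return
        self._current_t, self._current_dt = t, dt
        self.reset_block.execute(self, spikes)

    # -- snapshots ---------------------------------------------------------------
    def snapshot(self):
        return {"state": {k: v.copy() for k, v in self.state_arrays.items()},
                "last_spike_step": self.last_spike_step.copy()}

    def restore(self, snap):
        for k, v in snap["state"].items():
            self.state_arrays[k][...] = v
        self.last_spike_step[...] = snap["last_spike_step"]

    def __repr__(self):
        return f"<NeuronGroup {self.name!r}, N={self.n}>"


def extract_spikes_from_trace(trace, times, threshold):
    """Spike times from a membrane-potential trace: one spike per strict upward
    crossing (sample >= threshold and previous sample < threshold); the first
    sample never spikes."""
    tdim = get_dimension(trace)
    if tdim != get_dimension(threshold):
        raise DimensionMismatch("trace and threshold dimensions differ")
    v = np.asarray(trace.value if isinstance(trace, Quantity) else trace,
                   dtype=float)
    th = float(threshold.value) if isinstance(threshold, Quantity) else float(threshold)
    tvals = np.asarray(times.value if isinstance(times, Quantity) else times,
                       dtype=float)
    if v.shape != tvals.shape:
        raise ValueError("trace and times must have equal length")
    crossings = np.flatnonzero((v[1:] >= th) & (v[:-1] < th)) + 1
    out = tvals[crossings]
    return Quantity(out, TIME) if isinstance(times, Quantity) else out
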