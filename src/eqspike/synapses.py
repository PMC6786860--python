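"""Synapse populations.

A :class:`Synapses` object owns the synapses between a source and a target
group: per-synapse state (with dynamics defined by differential equations in
precisely the same way as neurons), expression-based connectivity, per-synapse
transmission delays, spike-triggered statement pathways, and continuous
*summed-variable* bindings for graded interactions.

Identifier suffixes ``_pre`` / ``_post`` inside synaptic model code and
statements resolve to variables of the source / target group, indexed by each
synapse's endpoints.  A subexpression entry named ``X_post`` carrying the
``summed`` flag sets target variable ``X`` each timestep to the sum of the
expression over all synapses converging on each target instance (instances
with no synapses get zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codegen import RUNTIME_FUNCTIONS, compile_expression, compile_statements
from .equations import (infer_dimension, order_subexpressions, parse_equations,
                        parse_expression)
from .errors import (DimensionMismatch, EqspikeError, IntegrationError,
                     SummedTargetCollision)
from .groups import NeuronGroup, RegisteredFunction
from .units import DIMENSIONLESS, TIME, Quantity, UNIT_REGISTRY, get_dimension

__all__ = ["Synapses", "SpikeQueue"]


class SpikeQueue:
    """Future synapse-index lists keyed by absolute due timestep.

    A spike inserted with delay d steps is delivered exactly d steps later,
    once; total inserted == total delivered + pending.  Arbitrarily long
    delays are accepted (storage grows transparently, nothing is dropped).
    """

    def __init__(self):
        self.buckets: dict[int, list[np.ndarray]] = {}
        self.inserted = 0
        self.delivered = 0

    def push(self, due_step, synapse_indices):
        if synapse_indices.size == 0:
            return
        self.buckets.setdefault(int(due_step), []).append(synapse_indices)
        self.inserted += int(synapse_indices.size)

    def pop(self, step):
        chunks = self.buckets.pop(int(step), None)
        if not chunks:
            return np.empty(0, dtype=np.int64)
        out = chunks[0] if len(chunks) == 1 else np.concatenate(chunks)
        self.delivered += int(out.size)
        return out

    @property
    def pending(self):
        return self.inserted - self.delivered

    def snapshot(self):
        return ({k: [c.copy() for c in v] for k, v in self.buckets.items()},
                self.inserted, self.delivered)

    def restore(self, snap):
        buckets, inserted, delivered = snap
        self.buckets = {k: [c.copy() for c in v] for k, v in buckets.items()}
        self.inserted, self.delivered = inserted, delivered


class _Pathway:
    """One named spike-triggered route with its own delays and statements."""

    def __init__(self, name, trigger, statements_text):
        self.name = name
        self.trigger = trigger                # 'source' or 'target'
        self.statements_text = statements_text
        self.block = None
        self.delay = None                     # per-synapse seconds
        self.delay_steps = None
        self.queue = SpikeQueue()


class Synapses:
    """Synapse population between ``source`` and ``target`` groups.

    ``on_pre`` (statements run when a presynaptic spike arrives, after its
    pathway delay) may be a string (single pathway named ``'pre'``) or a dict
    ``{pathway_name: statements}`` for multiple pathways with independent
    delays.  ``on_post`` behaves symmetrically for postsynaptic spikes.
    All synaptic effects are explicit statements -- nothing is implicit.
    """

    is_synapse = True

    def __init__(self, source, target, model="", on_pre=None, on_post=None,
                 method=None, namespace=None, name=None):
        self.source = source
        self.target = target
        self.name = name or f"synapses_{id(self):x}"
        self.namespace = dict(namespace or {})
        self.method = method
        self.eqs = parse_equations(model or "")
        self.rng = np.random.default_rng()
        self.linked = {}

        self._functions = {k: v for k, v in self.namespace.items()
                           if isinstance(v, RegisteredFunction)}

        self.pathways: dict[str, _Pathway] = {}
        if on_pre is not None:
            items = on_pre.items() if isinstance(on_pre, dict) else [("pre", on_pre)]
            for pname, text in items:
                self.pathways[pname] = _Pathway(pname, "source", text)
        if on_post is not None:
            items = on_post.items() if isinstance(on_post, dict) else [("post", on_post)]
            for pname, text in items:
                self.pathways[pname] = _Pathway(pname, "target", text)

        # summed entries: subexpressions named X_post / X_pre with flag summed
        self.summed_entries = []
        for e in self.eqs:
            if e.is_summed:
                base, grp = self._suffix_target(e.name)
                if grp is None:
                    raise EqspikeError(
                        f"summed entry {e.name!r} must end in _pre or _post")
                if base not in grp.state_arrays:
                    raise EqspikeError(
                        f"summed entry {e.name!r}: no variable {base!r} on the "
                        f"{'source' if grp is self.source else 'target'} group")
                if grp.eqs[base].dim != e.dim:
                    raise DimensionMismatch(
                        f"summed entry {e.name!r} has dimension {e.dim}, target "
                        f"variable has {grp.eqs[base].dim}")
                self.summed_entries.append(e)

        self._validate_dims()

        self.n = 0
        self.i_arr = np.empty(0, dtype=np.int64)
        self.j_arr = np.empty(0, dtype=np.int64)
        self.state_arrays: dict[str, np.ndarray] = {}
        self.updater = None
        self._prepared = False

    # ------------------------------------------------------------------ dims --
    def _suffix_target(self, name):
        if name.endswith("_pre"):
            return name[:-4], self.source
        if name.endswith("_post"):
            return name[:-5], self.target
        return name, None

    def _dim_namespace(self):
        dims = {}
        # constants of the connected groups are visible (their own namespaces
        # first, this population's overriding)
        for grp in (self.source, self.target):
            for k, v in grp.namespace.items():
                if isinstance(v, RegisteredFunction):
                    continue
                dims[k] = get_dimension(v) if isinstance(v, Quantity) \
                    else DIMENSIONLESS
        for k, v in self.namespace.items():
            if isinstance(v, RegisteredFunction):
                continue
            dims[k] = get_dimension(v) if isinstance(v, Quantity) else DIMENSIONLESS
        for grp, suffix in ((self.source, "_pre"), (self.target, "_post")):
            for e in grp.eqs:
                dims[e.name + suffix] = e.dim
            dims["i" + suffix] = DIMENSIONLESS
            dims["j" + suffix] = DIMENSIONLESS
        for e in self.eqs:
            dims[e.name] = e.dim
        dims["delay"] = TIME
        return dims

    def _function_signatures(self):
        sigs = {f.name: (f.arg_dims, f.return_dim)
                for f in self._functions.values()}
        for grp in (self.source, self.target):
            sigs.update(grp._function_signatures())
        return sigs

    def _validate_dims(self):
        from .equations import validate_dimensions
        validate_dimensions(self.eqs, self._dim_namespace(),
                            self._function_signatures())
        # summed entries validate against their declared dim like any
        # subexpression; structural checks happened in __init__

    # ------------------------------------------------------------- connect ----
    def connect(self, condition=None, p=None, i=None, j=None, rng=None):
        """Create synapses.

        Exactly one of: ``condition`` (optionally thinned by probability
        ``p``), ``p`` alone (all pairs, independent Bernoulli), or explicit
        index lists ``i``/``j``.  Candidate pairs are enumerated row-major in
        (i, j); creation order is deterministic given the RNG.
        """
        rng = rng or self.rng
        if p is not None and not (0 <= p <= 1):
            raise ValueError(f"invalid probability {p}")
        ns_, nt = self.source.n, self.target.n
        if i is not None or j is not None:
            if condition is not None or p is not None:
                raise ValueError("explicit pairs exclude condition/p")
            I = np.asarray(i, dtype=np.int64)
            J = np.asarray(j, dtype=np.int64)
            if I.shape != J.shape:
                raise ValueError("i and j must have equal length")
            if I.size and (I.min() < 0 or I.max() >= ns_ or J.min() < 0
                           or J.max() >= nt):
                raise IndexError("synapse index out of range")
        else:
            I = np.repeat(np.arange(ns_, dtype=np.int64), nt)
            J = np.tile(np.arange(nt, dtype=np.int64), ns_)
            keep = np.ones(I.size, dtype=bool)
            if condition is not None:
                expr = parse_expression(condition, f"connect of {self.name}")
                info = infer_dimension(expr, self._dim_namespace(),
                                       self._function_signatures(),
                                       context=f"connect of {self.name}")
                if not (info.boolean or info.dim.is_dimensionless):
                    raise DimensionMismatch(
                        f"connectivity condition has dimension {info.dim}")
                kern = compile_expression(expr)
                nsd = self._pair_namespace(I, J)
                keep &= np.broadcast_to(np.asarray(kern.evaluate(nsd), dtype=bool),
                                        I.shape)
            if p is not None:
                keep &= rng.random(I.size) < p
            I, J = I[keep], J[keep]

        self.i_arr = np.concatenate([self.i_arr, I])
        self.j_arr = np.concatenate([self.j_arr, J])
        self.n = self.i_arr.size
        self._allocate()
        return self

    def _pair_namespace(self, I, J):
        ns = dict(RUNTIME_FUNCTIONS)
        for k, v in self.namespace.items():
            if isinstance(v, RegisteredFunction):
                ns[k] = v.implementation
            else:
                ns[k] = float(v.value) if isinstance(v, Quantity) else v
        for uname, uq in UNIT_REGISTRY.items():
            ns.setdefault(uname, float(uq.value))
        for grp, idx, suffix in ((self.source, I, "_pre"),
                                 (self.target, J, "_post")):
            for var, arr in grp.state_arrays.items():
                ns[var + suffix] = arr[idx]
            for var, binding in grp.linked.items():
                ns[var + suffix] = binding.read()[idx]
        ns["i"] = I
        ns["j"] = J
        ns["N"] = max(self.n, 1)
        ns["rand"] = lambda: self.rng.random(I.size)
        ns["randn"] = lambda: self.rng.standard_normal(I.size)
        return ns

    def _allocate(self):
        for e in self.eqs:
            if e.kind == "subexpression":
                continue
            old = self.state_arrays.get(e.name)
            dtype = {"integer": np.int64, "boolean": bool}.get(e.var_type, float)
            arr = np.zeros(self.n, dtype=dtype)
            if old is not None:
                arr[:old.size] = old
            self.state_arrays[e.name] = arr
        for pw in self.pathways.values():
            old = pw.delay
            pw.delay = np.zeros(self.n)
            if old is not None:
                pw.delay[:old.size] = old

    # ------------------------------------------------------------- state ------
    def _runtime_unit_constants(self):
        out = {}
        for grp in (self.source, self.target):
            out.update(grp.constant_values())
        for k, v in self.namespace.items():
            if not isinstance(v, RegisteredFunction):
                out[k] = float(v.value) if isinstance(v, Quantity) else float(v)
        idents = set(self.eqs.identifiers)
        for pw in self.pathways.values():
            if pw.block is not None:
                for st in pw.block.statements:
                    idents |= st.expr.names
        for ident in idents:
            if ident in UNIT_REGISTRY and ident not in out:
                out[ident] = float(UNIT_REGISTRY[ident].value)
        return out

    # host API for integrators ------------------------------------------------
    def constant_values(self):
        return self._runtime_unit_constants()

    def per_instance_params(self):
        params = {e.name for e in self.eqs if e.kind == "parameter"}
        # pre/post references vary per synapse as well
        for e in self.eqs:
            if e.expr is None:
                continue
            for ident in e.expr.identifiers:
                if ident.endswith("_pre") or ident.endswith("_post"):
                    params.add(ident)
        return params

    def function_impls(self):
        impls = {f.name: f.implementation for f in self._functions.values()}
        for grp in (self.source, self.target):
            impls.update(grp.function_impls())
        return impls

    _base_ns = None

    def _build_base_ns(self):
        ns = dict(RUNTIME_FUNCTIONS)
        for uname, uq in UNIT_REGISTRY.items():
            ns[uname] = float(uq.value)
        ns.update(self.constant_values())
        ns.update(self.function_impls())
        self._base_ns = ns
        return ns

    def eval_namespace(self, t, dt):
        ns = dict(self._base_ns if self._base_ns is not None
                  else self._build_base_ns())
        ns.update(self.state_arrays)
        for grp, idx, suffix in ((self.source, self.i_arr, "_pre"),
                                 (self.target, self.j_arr, "_post")):
            for var, arr in grp.state_arrays.items():
                ns[var + suffix] = arr[idx]
            for var, binding in grp.linked.items():
                ns[var + suffix] = binding.read()[idx]
        ns["i"] = self.i_arr
        ns["j"] = self.j_arr
        ns["N"] = self.n
        ns["t"] = t
        ns["dt"] = dt
        ns["rand"] = lambda: self.rng.random(self.n)
        ns["randn"] = lambda: self.rng.standard_normal(self.n)
        return ns

    def evaluate(self, expression, t=0.0, dt=0.0):
        if isinstance(expression, str):
            expression = parse_expression(expression, f"evaluate in {self.name}")
        kern = compile_expression(expression)
        ns = self.eval_namespace(t, dt)
        order = [nm for nm in order_subexpressions(self.eqs)
                 if self.eqs[nm].kind == "subexpression"
                 and not self.eqs[nm].is_summed]
        for nm in order:
            ns[nm] = compile_expression(self.eqs[nm].expr).evaluate(ns)
        out = kern.evaluate(ns)
        return np.broadcast_to(out, (self.n,)).copy() if np.ndim(out) == 0 \
            else np.asarray(out)

    def set_state(self, variable, value, subset=None, pathway=None):
        """Per-synapse assignment; ``variable`` may be ``'delay'`` (optionally
        naming a pathway) or any per-synapse state variable.  Expression
        strings may use i, j and pre/post-suffixed group variables."""
        if variable == "delay":
            if pathway is None:
                if len(self.pathways) != 1:
                    raise EqspikeError("multiple pathways: name one with pathway=")
                pathway = next(iter(self.pathways))
            arr = self.pathways[pathway].delay
            dim = TIME
        else:
            if variable not in self.state_arrays:
                raise EqspikeError(f"unknown synaptic variable {variable!r}")
            arr = self.state_arrays[variable]
            dim = self.eqs[variable].dim
        idx = slice(None) if subset is None else np.asarray(subset)
        if isinstance(value, str):
            expr = parse_expression(value, f"set_state({variable})")
            info = infer_dimension(expr, self._dim_namespace(),
                                   self._function_signatures(),
                                   context=f"set_state({variable})")
            if info.dim != dim and not info.boolean:
                raise DimensionMismatch(
                    f"set_state({variable}): expression has dimension "
                    f"{info.dim}, variable has {dim}", info.dim, dim)
            vals = self.evaluate(expr)[idx]
        else:
            vdim = get_dimension(value)
            if vdim != dim:
                raise DimensionMismatch(
                    f"set_state({variable}): value has dimension {vdim}, "
                    f"variable has {dim}", vdim, dim)
            vals = value.value if isinstance(value, Quantity) else value
        arr[idx] = vals
        return self

    def state(self, variable, pathway=None):
        if variable == "delay":
            pathway = pathway or next(iter(self.pathways))
            return Quantity(self.pathways[pathway].delay.copy(), TIME)
        return Quantity(self.state_arrays[variable].copy(),
                        self.eqs[variable].dim)

    # ------------------------------------------------------------- run-time ---
    def prepare(self, dt, rng):
        from .integrators import make_updater

        self.rng = rng
        self._dt = dt
        # statement blocks (compiled lazily so connectivity/weights can be set
        # in any order before the run)
        writable = set(self.state_arrays)
        for grp, suffix in ((self.source, "_pre"), (self.target, "_post")):
            for var in grp.state_arrays:
                if var not in grp.linked:
                    writable.add(var + suffix)
        constants = set(self.namespace) | \
            {e.name for e in self.eqs if e.is_constant}
        for pw in self.pathways.values():
            if pw.block is None:
                pw.block = compile_statements(
                    pw.statements_text, writable, constants,
                    kind="synapse_event", context=f"{pw.name} of {self.name}")
                dims = self._dim_namespace()
                for st in pw.block.statements:
                    expr = parse_expression(st.expr.source)
                    info = infer_dimension(expr, dims,
                                           self._function_signatures(),
                                           context=f"{pw.name} of {self.name}")
                    if st.op in ("=", "+=", "-=") and info.dim != dims[st.target] \
                            and not info.boolean:
                        raise DimensionMismatch(
                            f"{pw.name}: {st.target} {st.op} expression of "
                            f"dimension {info.dim}, variable has {dims[st.target]}")
            # delays rounded to the nearest grid step, ties away from zero
            pw.delay_steps = np.floor(pw.delay / dt + 0.5).astype(np.int64)

        if self.updater is None and self.eqs.diff_names:
            self.updater = make_updater(self, self.method)
        if self.updater is not None:
            self.updater.prepare(dt)

        self.summed_kernels = []
        for e in self.summed_entries:
            base, grp = self._suffix_target(e.name)
            self.summed_kernels.append(
                (base, grp, compile_expression(e.expr)))

        # CSR of synapse indices by source (resp. target) for fast fan-out
        self._fanout = {}
        for trigger, endpoint, count in (("source", self.i_arr, self.source.n),
                                         ("target", self.j_arr, self.target.n)):
            order = np.argsort(endpoint, kind="stable")
            starts = np.searchsorted(endpoint[order], np.arange(count + 1))
            self._fanout[trigger] = (order, starts)
        self._prepared = True

    def _synapses_of(self, trigger, cells):
        order, starts = self._fanout[trigger]
        cnt = starts[cells + 1] - starts[cells]
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        base = np.repeat(starts[cells], cnt)
        offs = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        return order[base + offs]

    def enqueue(self, spikes_by_group, step):
        """Insert this step's spikes into every pathway's queue."""
        for pw in self.pathways.values():
            cells = spikes_by_group.get(self.source if pw.trigger == "source"
                                        else self.target)
            if cells is None or cells.size == 0:
                continue
            syn = self._synapses_of(pw.trigger, cells)
            if syn.size == 0:
                continue
            dsteps = pw.delay_steps[syn]
            if dsteps.size and dsteps.min() == dsteps.max():
                pw.queue.push(step + int(dsteps[0]), syn)
            else:
                for d in np.unique(dsteps):
                    pw.queue.push(step + int(d), syn[dsteps == d])

    def deliver(self, step, t, dt):
        """Pop due synapses and run their event statements."""
        self._current_t, self._current_dt = t, dt
        for pw in self.pathways.values():
            due = pw.queue.pop(step)
            if due.size:
                pw.block.execute(self, due)

    def state_update(self, t, dt, stamp=None):
        if self.updater is None:
            return
        self._current_t, self._current_dt = t, dt
        ns = self.eval_namespace(t, dt)
        self.updater.step(ns, dt)
        for v in self.eqs.diff_names:
            if not np.all(np.isfinite(self.state_arrays[v])):
                raise IntegrationError(
                    f"synaptic variable {v!r} of {self.name} became non-finite "
                    f"at t={t}")

    def update_summed(self, t, dt):
        """SET each summed target variable to the per-target sum (0 if none)."""
        if not self.summed_entries:
            return
        ns = self.eval_namespace(t, dt)
        order = [nm for nm in order_subexpressions(self.eqs)
                 if self.eqs[nm].kind == "subexpression"
                 and not self.eqs[nm].is_summed]
        for nm in order:
            ns[nm] = compile_expression(self.eqs[nm].expr).evaluate(ns)
        for base, grp, kern in self.summed_kernels:
            vals = np.broadcast_to(np.asarray(kern.evaluate(ns), dtype=float),
                                   (self.n,))
            idx = self.j_arr if grp is self.target else self.i_arr
            grp.state_arrays[base][...] = np.bincount(
                idx, weights=vals, minlength=grp.n)

    # statement-execution context (same contract as NeuronGroup) ---------------
    _current_t = 0.0
    _current_dt = 0.0

    def _statement_namespace(self, names, indices):
        ns = dict(RUNTIME_FUNCTIONS)
        for nm in names:
            if nm in UNIT_REGISTRY:
                ns[nm] = float(UNIT_REGISTRY[nm].value)
        ns.update(self.constant_values())
        ns.update(self.function_impls())
        n_sel = self.i_arr[indices].size
        ns["rand"] = lambda: self.rng.random(n_sel)
        ns["randn"] = lambda: self.rng.standard_normal(n_sel)
        ns["t"] = self._current_t
        ns["dt"] = self._current_dt
        ns["N"] = self.n
        ns["i"] = self.i_arr[indices]
        ns["j"] = self.j_arr[indices]
        for var, arr in self.state_arrays.items():
            if var in names:
                ns[var] = arr[indices]
        for grp, gidx, suffix in ((self.source, self.i_arr[indices], "_pre"),
                                  (self.target, self.j_arr[indices], "_post")):
            for var, arr in grp.state_arrays.items():
                key = var + suffix
                if key in names:
                    ns[key] = arr[gidx]
            for var, binding in grp.linked.items():
                key = var + suffix
                if key in names:
                    ns[key] = binding.read()[gidx]
        return ns

    def _write(self, target, op, indices, values, ns):
        if target.endswith("_pre") and target[:-4] in self.source.state_arrays:
            arr = self.source.state_arrays[target[:-4]]
            idx = self.i_arr[indices]
        elif target.endswith("_post") and target[:-5] in self.target.state_arrays:
            arr = self.target.state_arrays[target[:-5]]
            idx = self.j_arr[indices]
        else:
            arr = self.state_arrays[target]
            idx = indices
        if op == "=":
            arr[idx] = values
        elif op == "+=":
            np.add.at(arr, idx, values)
        elif op == "-=":
            np.subtract.at(arr, idx, values)
        elif op == "*=":
            np.multiply.at(arr, idx, values)
        elif op == "/=":
            np.divide.at(arr, idx, values)
        ns[target] = arr[idx]

    # ------------------------------------------------------------- snapshots --
    def snapshot(self):
        return {"state": {k: v.copy() for k, v in self.state_arrays.items()},
                "queues": {name: pw.queue.snapshot()
                           for name, pw in self.pathways.items()}}

    def restore(self, snap):
        for k, v in snap["state"].items():
            self.state_arrays[k][...] = v
        for name, qsnap in snap["queues"].items():
            self.pathways[name].queue.restore(qsnap)

    # ------------------------------------------------------------- export -----
    def to_dataframe(self):
        """Connectivity and per-synapse state as a DataFrame (SI scale)."""
        data = {"i": self.i_arr, "j": self.j_arr}
        for name, pw in self.pathways.items():
            data[f"delay_{name}_seconds"] = pw.delay
        for var, arr in self.state_arrays.items():
            data[var] = arr
        return pd.DataFrame(data)

    def write_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def pairs_from_csv(path):
        df = pd.read_csv(path)
        return df["i"].to_numpy(np.int64), df["j"].to_numpy(np.int64)

    def __repr__(self):
        return f"<Synapses {self.name!r}, {self.source.name}->{self.target.name}, " \
               f"n={self.n}>"


def check_summed_collisions(synapse_list):
    """Raise if two populations sum into the same target variable."""
    seen = {}
    for syn in synapse_list:
        for e in syn.summed_entries:
            base, grp = syn._suffix_target(e.name)
            key = (id(grp), base)
            if key in seen and seen[key] is not syn:
                raise SummedTargetCollision(
                    f"variable {base!r} is summed into by two synapse "
                    f"populations ({seen[key].name} and {syn.name})")
            seen[key] = syn
    return True
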