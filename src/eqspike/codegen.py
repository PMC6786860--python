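"""Compilation of validated expressions and statements into vectorized kernels.

From the abstract model description we generate independent blocks of code
that the network schedule then runs in sequence each timestep: numerical
integration, threshold testing, synaptic propagation, and post-spike resets.
"Compilation" here means rendering the expression tree to numpy-vectorized
Python source (word booleans become logical_and/or/not, comparisons chain
correctly) and compiling it once with :func:`compile`; evaluation is then a
single ``eval`` of the code object against a namespace of state arrays and
constants, i.e. one fused vector operation per expression per step.

``rand()``/``randn()`` inside expressions draw one value per evaluated
instance, in instance order, from the network RNG stream, so runs are exactly
reproducible under a fixed seed.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field

import numpy as np
from scipy.special import exprel as _scipy_exprel

from .equations import Expression, Statement, parse_statements
from .errors import AssignmentToConstant, UnresolvedIdentifier

__all__ = ["CompiledExpression", "CodeBlock", "compile_expression",
           "compile_statements", "build_blocks", "scalar_interpreter",
           "RUNTIME_FUNCTIONS"]


def _int_func(x):
    return np.asarray(x).astype(np.int64) if np.ndim(x) else int(x)


#: implementations of the built-in functions available in every expression
RUNTIME_FUNCTIONS = {
    "exp": np.exp, "log": np.log, "expm1": np.expm1, "log1p": np.log1p,
    "exprel": _scipy_exprel, "sin": np.sin, "cos": np.cos, "tan": np.tan,
    "tanh": np.tanh, "abs": np.abs, "floor": np.floor, "ceil": np.ceil,
    "sign": np.sign, "sqrt": np.sqrt, "clip": np.clip, "int": _int_func,
    "_logical_and": np.logical_and, "_logical_or": np.logical_or,
    "_logical_not": np.logical_not,
}


class _Renderer(ast.NodeTransformer):
    """Rewrite word booleans to explicit vectorized calls; leave the rest."""

    def visit_BoolOp(self, node):
        values = [self.visit(v) for v in node.values]
        fname = "_logical_and" if isinstance(node.op, ast.And) else "_logical_or"
        out = values[0]
        for v in values[1:]:
            out = ast.Call(func=ast.Name(id=fname, ctx=ast.Load()),
                           args=[out, v], keywords=[])
        return out

    def visit_UnaryOp(self, node):
        node = self.generic_visit(node)
        if isinstance(node.op, ast.Not):
            return ast.Call(func=ast.Name(id="_logical_not", ctx=ast.Load()),
                            args=[node.operand], keywords=[])
        return node

    def visit_Compare(self, node):
        node = self.generic_visit(node)
        if len(node.ops) == 1:
            return node
        # chain a < b < c -> logical_and(a < b, b < c); operands re-used verbatim
        left = node.left
        parts = []
        for op, comp in zip(node.ops, node.comparators):
            parts.append(ast.Compare(left=left, ops=[op], comparators=[comp]))
            left = comp
        out = parts[0]
        for p in parts[1:]:
            out = ast.Call(func=ast.Name(id="_logical_and", ctx=ast.Load()),
                           args=[out, p], keywords=[])
        return out


@dataclass
class CompiledExpression:
    """A compiled, evaluable expression over named state arrays and constants."""

    source: str
    code: object = field(repr=False)
    names: frozenset[str] = frozenset()
    functions: frozenset[str] = frozenset()
    uses_random: bool = False

    def evaluate(self, namespace):
        """Evaluate against a fully-populated mapping name -> array/scalar/callable."""
        return eval(self.code, {"__builtins__": {}}, namespace)


def compile_expression(expr):
    """Compile a parsed (and dimension-validated) Expression to a kernel."""
    if not isinstance(expr, Expression):
        raise TypeError("compile_expression expects a parsed Expression")
    tree = ast.fix_missing_locations(_Renderer().visit(ast.Expression(body=expr.node)))
    code = compile(tree, f"<eqspike:{expr.code}>", "eval")
    return CompiledExpression(
        source=expr.code, code=code,
        names=expr.identifiers, functions=expr.functions,
        uses_random=bool({"rand", "randn"} & expr.functions),
    )


@dataclass
class CompiledStatement:
    target: str
    op: str
    expr: CompiledExpression


@dataclass
class CodeBlock:
    """One schedule-slot kernel: state_update, threshold, reset, synapse_event
    or summed_update.  ``reads``/``writes`` list the state variables touched;
    the kernel never touches anything else."""

    kind: str
    statements: list[CompiledStatement] = field(default_factory=list)
    reads: frozenset[str] = frozenset()
    writes: frozenset[str] = frozenset()
    payload: object = None     # updater / threshold kernel, depending on kind

    def execute(self, context, indices):
        """Run the statements sequentially over an instance-index subset.

        ``context`` must provide ``_statement_namespace(names, indices)``
        returning a mapping, and ``_write(target, op, indices, values)``
        applying one assignment in place.
        """
        needed = set()
        for st in self.statements:
            needed |= st.expr.names | st.expr.functions
            needed.add(st.target)
        ns = context._statement_namespace(needed, indices)
        for st in self.statements:
            value = st.expr.evaluate(ns)
            context._write(st.target, st.op, indices, value, ns)


def compile_statements(text, writable, constants=(), kind="reset", context=""):
    """Compile a statement string into a CodeBlock.

    ``writable`` is the set of assignable variable names; assigning anything
    in ``constants`` (or outside ``writable``) raises AssignmentToConstant.
    """
    stmts = text if isinstance(text, list) else parse_statements(text, context)
    compiled, reads, writes = [], set(), set()
    for st in stmts:
        if st.target in constants:
            raise AssignmentToConstant(
                f"{context}: cannot assign to constant {st.target!r}")
        if st.target not in writable:
            raise AssignmentToConstant(
                f"{context}: {st.target!r} is not a writable variable")
        compiled.append(CompiledStatement(st.target, st.op, compile_expression(st.expr)))
        reads |= st.expr.identifiers
        writes.add(st.target)
        if st.op != "=":
            reads.add(st.target)
    return CodeBlock(kind=kind, statements=compiled,
                     reads=frozenset(reads), writes=frozenset(writes))


def build_blocks(obj):
    """The ordered per-timestep code blocks of a group or synapse population.

    A NeuronGroup yields state_update (+ threshold + reset when defined); a
    synapse population yields state_update for per-synapse dynamics,
    summed_update for graded bindings, and one synapse_event block per
    pathway.  The network schedule runs these kinds in its fixed slot order.
    """
    blocks = []
    if getattr(obj, "is_synapse", False):
        if obj.eqs.diff_names:
            blocks.append(CodeBlock(kind="state_update", payload=obj))
        if obj.summed_entries:
            blocks.append(CodeBlock(kind="summed_update", payload=obj))
        for pw in obj.pathways.values():
            blocks.append(CodeBlock(kind="synapse_event", payload=pw))
    else:
        if obj.eqs.diff_names:
            blocks.append(CodeBlock(kind="state_update", payload=obj))
        if obj.threshold_expr is not None:
            blocks.append(CodeBlock(
                kind="threshold", payload=obj.threshold_expr,
                reads=obj.threshold_expr.names))
        if obj.reset_block is not None:
            blocks.append(obj.reset_block)
    return blocks


def make_random_callables(rng, n):
    """Zero-arg rand()/randn() drawing one value per instance, instance order."""
    return {"rand": lambda: rng.random(n), "randn": lambda: rng.standard_normal(n)}


def scalar_interpreter(expr, namespace):
    """Naive per-instance tree-walking evaluation of a parsed Expression.

    Reference semantics for the compiled kernels (used as a test oracle, and
    for arbitrating any question about evaluation order).  ``namespace`` maps
    names to scalars and functions to scalar callables.
    """
    node = expr.node if isinstance(expr, Expression) else expr

    def visit(n):
        if isinstance(n, ast.Constant):
            return n.value
        if isinstance(n, ast.Name):
            try:
                return namespace[n.id]
            except KeyError:
                raise UnresolvedIdentifier([n.id]) from None
        if isinstance(n, ast.UnaryOp):
            v = visit(n.operand)
            if isinstance(n.op, ast.USub):
                return -v
            if isinstance(n.op, ast.Not):
                return not v
            return +v
        if isinstance(n, ast.BinOp):
            a, b = visit(n.left), visit(n.right)
            if isinstance(n.op, ast.Add):
                return a + b
            if isinstance(n.op, ast.Sub):
                return a - b
            if isinstance(n.op, ast.Mult):
                return a * b
            if isinstance(n.op, ast.Div):
                return a / b
            return a ** b
        if isinstance(n, ast.BoolOp):
            if isinstance(n.op, ast.And):
                return all(bool(visit(v)) for v in n.values)
            return any(bool(visit(v)) for v in n.values)
        if isinstance(n, ast.Compare):
            import operator
            ops = {ast.Lt: operator.lt, ast.Gt: operator.gt, ast.LtE: operator.le,
                   ast.GtE: operator.ge, ast.Eq: operator.eq, ast.NotEq: operator.ne}
            left, ok = visit(n.left), True
            for op, comp in zip(n.ops, n.comparators):
                right = visit(comp)
                ok = ok and ops[type(op)](left, right)
                left = right
            return ok
        if isinstance(n, ast.Call):
            fn = namespace[n.func.id]
            return fn(*(visit(a) for a in n.args))
        raise TypeError(f"unexpected node {type(n).__name__}")

    return visit(node)
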