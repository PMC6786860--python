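"""Model descriptions as unit-annotated equation strings.

A model is a multi-line string in which each non-empty line is one of

    dX/dt = rhs : unit (flag, flag)      -- differential equation
    X = rhs : unit (flags)               -- subexpression
    X : unit (flags)                     -- parameter

The right-hand-side grammar is a small expression language: identifiers,
numeric literals, ``+ - * / **``, parentheses, function calls, comparisons
and the word booleans ``and / or / not``.  It is parsed by whitelisting the
corresponding subset of Python's own grammar, so source order of operations
is preserved exactly.

Numeric literals are dimensionless; every dimensioned constant must enter via
the namespace.  This makes dimension inference total: given a dimension for
every free identifier, the dimension of any expression is determined, and a
model validates iff every rhs matches its declared dimension (for
differential entries, declared dimension / time).

Statement strings (reset, on_pre, ...) reuse the same expression grammar plus
assignment ``X = expr`` and augmented assignment ``X += expr`` (also ``-=``,
``*=``, ``/=``), executed sequentially top to bottom.
"""

from __future__ import annotations

import ast
import re
from dataclasses import dataclass, field
from fractions import Fraction
from graphlib import CycleError, TopologicalSorter

from .errors import (CyclicDependency, DimensionMismatch, DuplicateDefinition,
                     EquationError, IllegalFlag, IllegalNoise,
                     UnresolvedIdentifier)
from .units import DIMENSIONLESS, TIME, Dimension, Quantity, UNIT_REGISTRY, \
    parse_unit_expression

__all__ = [
    "Expression", "EquationEntry", "EquationSet", "Statement",
    "parse_expression", "parse_equations", "parse_statements",
    "validate_dimensions", "order_subexpressions", "detect_stochastic",
    "format_equations", "infer_dimension", "RESERVED_DIMS",
]

# dimension of the white-noise symbol: time**(-1/2)
XI_DIM = TIME ** Fraction(-1, 2)

#: names with fixed meaning inside every expression
RESERVED_DIMS = {
    "t": TIME,
    "dt": TIME,
    "xi": XI_DIM,
    "i": DIMENSIONLESS,
    "j": DIMENSIONLESS,
    "N": DIMENSIONLESS,
}

_ALLOWED_NODES = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.BoolOp, ast.Compare,
    ast.Call, ast.Name, ast.Constant, ast.Load,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow,
    ast.USub, ast.UAdd, ast.Not, ast.And, ast.Or,
    ast.Lt, ast.Gt, ast.LtE, ast.GtE, ast.Eq, ast.NotEq,
)


@dataclass(frozen=True)
class Expression:
    """A parsed right-hand side: source text, AST, and the set of free names."""

    code: str
    node: ast.expr
    identifiers: frozenset[str]
    functions: frozenset[str]

    def __str__(self):
        return self.code


def parse_expression(code, context="expression"):
    """Parse ``code`` under the rhs grammar; reject anything outside it."""
    code = " ".join(str(code).split())
    try:
        tree = ast.parse(code, mode="eval")
    except SyntaxError as exc:
        raise EquationError(f"syntax error in {context}: {code!r} ({exc.msg})") from None
    names, funcs = set(), set()
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise EquationError(
                f"illegal construct {type(node).__name__} in {context}: {code!r}")
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float, bool)):
                raise EquationError(f"illegal literal {node.value!r} in {context}")
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.keywords:
                raise EquationError(f"only simple calls f(x, ...) allowed in {context}")
            funcs.add(node.func.id)
        if isinstance(node, ast.Name):
            names.add(node.id)
    return Expression(code, tree.body, frozenset(names - funcs), frozenset(funcs))


# ---------------------------------------------------------------------------
# Equation sets
# ---------------------------------------------------------------------------

_VALID_FLAGS = {
    "differential": {"unless_refractory", "constant"},
    "subexpression": {"summed"},
    "parameter": {"constant", "linked"},
}

_VAR_TYPES = {"integer": "integer", "boolean": "boolean", "bool": "boolean"}


@dataclass
class EquationEntry:
    name: str
    kind: str                      # differential | subexpression | parameter
    expr: Expression | None
    dim: Dimension
    var_type: str = "float"        # float | integer | boolean
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_summed(self):
        return "summed" in self.flags

    @property
    def is_constant(self):
        return "constant" in self.flags


class EquationSet:
    """Ordered mapping name -> :class:`EquationEntry` with structural checks."""

    def __init__(self, entries):
        self.entries: dict[str, EquationEntry] = {}
        for e in entries:
            if e.name in self.entries:
                raise DuplicateDefinition(f"variable {e.name!r} defined twice")
            if e.name in UNIT_REGISTRY:
                raise DuplicateDefinition(f"variable {e.name!r} shadows a unit name")
            if e.name in RESERVED_DIMS:
                raise DuplicateDefinition(f"variable {e.name!r} shadows a reserved name")
            self.entries[e.name] = e
        self.validated = False

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, name):
        return name in self.entries

    def __getitem__(self, name):
        return self.entries[name]

    def __len__(self):
        return len(self.entries)

    def __eq__(self, other):
        if not isinstance(other, EquationSet):
            return NotImplemented
        if list(self.entries) != list(other.entries):
            return False
        for a, b in zip(self, other):
            if (a.name, a.kind, a.dim, a.var_type, a.flags) != \
               (b.name, b.kind, b.dim, b.var_type, b.flags):
                return False
            ca = a.expr.code if a.expr else None
            cb = b.expr.code if b.expr else None
            if ca != cb:
                return False
        return True

    def of_kind(self, *kinds):
        return [e for e in self if e.kind in kinds]

    @property
    def diff_names(self):
        return [e.name for e in self if e.kind == "differential"]

    @property
    def identifiers(self):
        """Free names referenced by any rhs that are not defined in this set."""
        out = set()
        for e in self:
            if e.expr is not None:
                out |= e.expr.identifiers
                out |= e.expr.functions
        return out - set(self.entries)


_LINE_DIFF = re.compile(r"^d\s*([A-Za-z_]\w*)\s*/\s*dt\s*=\s*(.+)$")
_LINE_SUB = re.compile(r"^([A-Za-z_]\w*)\s*=\s*(.+)$")
_LINE_PARAM = re.compile(r"^([A-Za-z_]\w*)$")


def _split_unit_flags(rest, lineno):
    """Split ``'rhs : unit (flags)'`` tail into (unit_text, flags)."""
    # a trailing parenthesized list is flags only if it is a comma-separated
    # list of identifiers (so unit exponents like second**(-1) stay units)
    m = re.match(r"^(.*?)\s*(\((\s*[A-Za-z_]\w*(\s*,\s*[A-Za-z_]\w*)*\s*)\))?\s*$",
                 rest)
    unit_text = m.group(1).strip()
    flags = frozenset(f.strip() for f in m.group(3).split(",")) \
        if m.group(3) else frozenset()
    if not unit_text:
        raise EquationError(f"line {lineno}: missing unit annotation")
    return unit_text, flags


def _parse_unit_field(unit_text, lineno):
    if unit_text in _VAR_TYPES:
        return DIMENSIONLESS, _VAR_TYPES[unit_text]
    if unit_text == "1":
        return DIMENSIONLESS, "float"
    try:
        return parse_unit_expression(unit_text).dim, "float"
    except Exception as exc:
        raise EquationError(f"line {lineno}: bad unit {unit_text!r} ({exc})") from None


def parse_equations(text):
    """Parse a multi-line model description into an :class:`EquationSet`."""
    entries = []
    for lineno, raw in enumerate(str(text).splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise EquationError(f"line {lineno}: missing ':unit' annotation in {line!r}")
        head, rest = line.rsplit(":", 1)
        head = head.strip()
        unit_text, flags = _split_unit_flags(rest.strip(), lineno)
        dim, var_type = _parse_unit_field(unit_text, lineno)

        m = _LINE_DIFF.match(head)
        if m:
            kind, name, rhs = "differential", m.group(1), m.group(2)
        else:
            m = _LINE_SUB.match(head)
            if m:
                kind, name, rhs = "subexpression", m.group(1), m.group(2)
            else:
                m = _LINE_PARAM.match(head)
                if not m:
                    raise EquationError(f"line {lineno}: cannot parse {line!r}")
                kind, name, rhs = "parameter", m.group(1), None

        bad = flags - _VALID_FLAGS[kind]
        if bad:
            raise IllegalFlag(
                f"line {lineno}: flag(s) {sorted(bad)} not allowed on {kind} entry {name!r}")
        expr = parse_expression(rhs, f"line {lineno}") if rhs is not None else None
        entries.append(EquationEntry(name, kind, expr, dim, var_type, flags))
    return EquationSet(entries)


def format_equations(eqs):
    """Render an EquationSet back to model text (parse∘format is the identity)."""
    lines = []
    for e in eqs:
        unit = {"integer": "integer", "boolean": "boolean"}.get(e.var_type)
        if unit is None:
            unit = "1" if e.dim.is_dimensionless else str(e.dim)
        flags = f" ({', '.join(sorted(e.flags))})" if e.flags else ""
        if e.kind == "differential":
            lines.append(f"d{e.name}/dt = {e.expr.code} : {unit}{flags}")
        elif e.kind == "subexpression":
            lines.append(f"{e.name} = {e.expr.code} : {unit}{flags}")
        else:
            lines.append(f"{e.name} : {unit}{flags}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Dimension inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimInfo:
    dim: Dimension
    boolean: bool = False


#: built-in functions: (arity, argument rule, return rule)
_DIMLESS = object()
_SAME = object()
_BUILTIN_FUNCS = {
    "exp": (1, _DIMLESS, DIMENSIONLESS), "log": (1, _DIMLESS, DIMENSIONLESS),
    "expm1": (1, _DIMLESS, DIMENSIONLESS), "log1p": (1, _DIMLESS, DIMENSIONLESS),
    "exprel": (1, _DIMLESS, DIMENSIONLESS),
    "sin": (1, _DIMLESS, DIMENSIONLESS), "cos": (1, _DIMLESS, DIMENSIONLESS),
    "tan": (1, _DIMLESS, DIMENSIONLESS), "tanh": (1, _DIMLESS, DIMENSIONLESS),
    "abs": (1, _SAME, _SAME), "floor": (1, _SAME, _SAME), "ceil": (1, _SAME, _SAME),
    "sign": (1, None, DIMENSIONLESS), "sqrt": (1, None, "sqrt"),
    "clip": (3, _SAME, _SAME), "int": (1, _DIMLESS, DIMENSIONLESS),
    "rand": (0, None, DIMENSIONLESS), "randn": (0, None, DIMENSIONLESS),
}


def _resolve_dim(name, namespace):
    """Dimension of a free identifier: namespace, then units, then reserved."""
    if name in namespace:
        obj = namespace[name]
        if isinstance(obj, Dimension):
            return obj
        if isinstance(obj, Quantity):
            return obj.dim
        if isinstance(obj, (int, float, bool)):
            return DIMENSIONLESS
        return None
    if name in UNIT_REGISTRY:
        return UNIT_REGISTRY[name].dim
    if name in RESERVED_DIMS:
        return RESERVED_DIMS[name]
    return None


def infer_dimension(expr, namespace, functions=None, context=""):
    """Infer the DimInfo of an Expression given ``name -> Dimension`` bindings.

    ``namespace`` may map names to Dimension, Quantity or plain numbers;
    ``functions`` maps user function names to (arg_dims, return_dim) tuples.
    Raises DimensionMismatch / UnresolvedIdentifier.
    """
    functions = functions or {}

    def visit(node):
        if isinstance(node, ast.Constant):
            if isinstance(node.value, bool):
                return DimInfo(DIMENSIONLESS, True)
            return DimInfo(DIMENSIONLESS)
        if isinstance(node, ast.Name):
            dim = _resolve_dim(node.id, namespace)
            if dim is None:
                raise UnresolvedIdentifier([node.id], context)
            return DimInfo(dim)
        if isinstance(node, ast.UnaryOp):
            inner = visit(node.operand)
            if isinstance(node.op, ast.Not):
                _require_boolish(inner, "not", context)
                return DimInfo(DIMENSIONLESS, True)
            return inner
        if isinstance(node, ast.BinOp):
            left, right = visit(node.left), visit(node.right)
            if isinstance(node.op, (ast.Add, ast.Sub)):
                if left.dim != right.dim:
                    raise DimensionMismatch(
                        f"{context}: cannot add/subtract {left.dim} and {right.dim} "
                        f"in {ast.unparse(node)!r}", left.dim, right.dim)
                return DimInfo(left.dim)
            if isinstance(node.op, ast.Mult):
                return DimInfo(left.dim * right.dim)
            if isinstance(node.op, ast.Div):
                return DimInfo(left.dim / right.dim)
            if isinstance(node.op, ast.Pow):
                if not right.dim.is_dimensionless:
                    raise DimensionMismatch(f"{context}: exponent has dimension {right.dim}")
                if left.dim.is_dimensionless:
                    return DimInfo(DIMENSIONLESS)
                exponent = _literal_exponent(node.right)
                if exponent is None:
                    raise DimensionMismatch(
                        f"{context}: dimensional base needs a literal rational exponent "
                        f"in {ast.unparse(node)!r}")
                return DimInfo(left.dim ** exponent)
            raise EquationError(f"unsupported operator in {context}")
        if isinstance(node, ast.Compare):
            dims = [visit(node.left)] + [visit(c) for c in node.comparators]
            first = dims[0]
            for d in dims[1:]:
                if d.dim != first.dim:
                    raise DimensionMismatch(
                        f"{context}: comparison between {first.dim} and {d.dim}",
                        first.dim, d.dim)
            return DimInfo(DIMENSIONLESS, True)
        if isinstance(node, ast.BoolOp):
            for v in node.values:
                _require_boolish(visit(v), "and/or", context)
            return DimInfo(DIMENSIONLESS, True)
        if isinstance(node, ast.Call):
            fname = node.func.id
            args = [visit(a) for a in node.args]
            if fname in functions:
                arg_dims, ret = functions[fname]
                if len(args) != len(arg_dims):
                    raise EquationError(
                        f"{context}: {fname}() takes {len(arg_dims)} args, got {len(args)}")
                for k, (got, want) in enumerate(zip(args, arg_dims)):
                    if got.dim != want:
                        raise DimensionMismatch(
                            f"{context}: argument {k} of {fname}() has dimension "
                            f"{got.dim}, expected {want}", got.dim, want)
                return DimInfo(ret)
            if fname in _BUILTIN_FUNCS:
                arity, arg_rule, ret_rule = _BUILTIN_FUNCS[fname]
                if len(args) != arity:
                    raise EquationError(
                        f"{context}: {fname}() takes {arity} args, got {len(args)}")
                if arg_rule is _DIMLESS:
                    for a in args:
                        if not a.dim.is_dimensionless:
                            raise DimensionMismatch(
                                f"{context}: {fname}() needs dimensionless arguments, "
                                f"got {a.dim}")
                elif arg_rule is _SAME and arity > 1:
                    for a in args[1:]:
                        if a.dim != args[0].dim:
                            raise DimensionMismatch(
                                f"{context}: {fname}() arguments differ in dimension")
                if ret_rule is _SAME:
                    return DimInfo(args[0].dim)
                if ret_rule == "sqrt":
                    return DimInfo(args[0].dim ** Fraction(1, 2))
                return DimInfo(ret_rule)
            raise UnresolvedIdentifier([fname], context)
        raise EquationError(f"unsupported node {type(node).__name__} in {context}")

    node = expr.node if isinstance(expr, Expression) else expr
    return visit(node)


def _require_boolish(info, op, context):
    if not info.dim.is_dimensionless:
        raise DimensionMismatch(f"{context}: {op} applied to dimension {info.dim}")


def _literal_exponent(node):
    """Rational value of a literal exponent node, or None."""
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        inner = _literal_exponent(node.operand)
        if inner is None:
            return None
        return -inner if isinstance(node.op, ast.USub) else inner
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        frac = Fraction(node.value).limit_denominator(1000)
        return frac if abs(float(frac) - node.value) < 1e-12 else None
    if isinstance(node, ast.BinOp) and isinstance(node.op, ast.Div):
        a, b = _literal_exponent(node.left), _literal_exponent(node.right)
        return a / b if a is not None and b is not None else None
    return None


def validate_dimensions(eqs, namespace, functions=None):
    """Check every rhs against its declared dimension; returns ``eqs`` validated.

    ``namespace`` supplies dimensions for every free identifier; entry names of
    the set itself resolve to their declared dimensions.  Differential entries
    must have rhs dimension declared/time; boolean subexpressions must be
    dimensionless.
    """
    functions = dict(functions or {})
    local = dict(namespace)
    for e in eqs:
        local.setdefault(e.name, e.dim)
    for e in eqs:
        if e.expr is None:
            continue
        info = infer_dimension(e.expr, local, functions, context=e.name)
        expected = e.dim / TIME if e.kind == "differential" else e.dim
        if info.boolean:
            if not expected.is_dimensionless:
                raise DimensionMismatch(
                    f"entry {e.name!r}: boolean expression declared with dimension {e.dim}")
        elif info.dim != expected:
            raise DimensionMismatch(
                f"entry {e.name!r}: rhs has dimension {info.dim}, expected {expected}",
                info.dim, expected)
    eqs.validated = True
    return eqs


def order_subexpressions(eqs):
    """Topological evaluation order: subexpressions before dependents, then
    differential entries.  Raises CyclicDependency."""
    subs = {e.name: e for e in eqs if e.kind == "subexpression"}
    ts = TopologicalSorter()
    for name, e in subs.items():
        ts.add(name, *(d for d in e.expr.identifiers if d in subs))
    try:
        ordered = list(ts.static_order())
    except CycleError as exc:
        raise CyclicDependency(exc.args[1]) from None
    return ordered + eqs.diff_names


def detect_stochastic(eqs):
    """Names of differential entries whose rhs references the noise symbol xi.

    xi is reserved, has dimension time**(-1/2), and may only appear linearly
    inside differential equations; anything else raises IllegalNoise.
    """
    import sympy

    from ._sympy_bridge import expression_to_sympy

    noisy = set()
    for e in eqs:
        if e.expr is None or "xi" not in e.expr.identifiers:
            continue
        if e.kind != "differential":
            raise IllegalNoise(
                f"xi may only appear in differential equations, found in {e.name!r}")
        sym_expr, symbols = expression_to_sympy(e.expr)
        xi = symbols["xi"]
        deriv = sympy.diff(sym_expr, xi)
        if deriv.has(xi):
            raise IllegalNoise(f"xi appears nonlinearly in d{e.name}/dt")
        noisy.add(e.name)
    return noisy


# ---------------------------------------------------------------------------
# Statements
# ---------------------------------------------------------------------------

_STMT_RE = re.compile(r"^([A-Za-z_]\w*)\s*(\+=|-=|\*=|/=|=)\s*(.+)$")


@dataclass(frozen=True)
class Statement:
    target: str
    op: str          # '=', '+=', '-=', '*=', '/='
    expr: Expression


def parse_statements(text, context="statements"):
    """Parse statements separated by ';' or newlines, executed in order."""
    stmts = []
    for part in re.split(r"[;\n]", str(text)):
        part = part.split("#", 1)[0].strip()
        if not part:
            continue
        m = _STMT_RE.match(part)
        if m is None:
            raise EquationError(f"cannot parse statement {part!r} in {context}")
        target, op, rhs = m.groups()
        if op == "=" and rhs.startswith("="):
            raise EquationError(f"'==' is not an assignment: {part!r}")
        stmts.append(Statement(target, op, parse_expression(rhs, context)))
    return stmts
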