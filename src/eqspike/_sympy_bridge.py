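"""Conversion of parsed expressions to sympy, used for symbolic analysis:
linearity detection (exact integration), conditional-linear decomposition
(exponential Euler) and the xi-linearity check.  Only arithmetic expressions
go through this path; boolean/threshold expressions never need it."""

from __future__ import annotations

import ast

import sympy

from .equations import Expression
from .errors import EquationError

_FUNC_MAP = {
    "exp": sympy.exp, "log": sympy.log, "sqrt": sympy.sqrt,
    "sin": sympy.sin, "cos": sympy.cos, "tan": sympy.tan, "tanh": sympy.tanh,
    "abs": sympy.Abs, "sign": sympy.sign, "floor": sympy.floor,
    "ceil": sympy.ceiling, "expm1": lambda x: sympy.exp(x) - 1,
    "log1p": lambda x: sympy.log(1 + x),
}


def expression_to_sympy(expr, extra_functions=None):
    """Return (sympy expression, {name: Symbol}) for a parsed Expression.

    Unknown function names become undefined ``sympy.Function``s, which keeps
    e.g. a user-registered ``sound(t)`` opaque but differentiable (derivative
    w.r.t. an unrelated state variable is zero).
    """
    symbols = {name: sympy.Symbol(name, real=True) for name in expr.identifiers}
    extra_functions = extra_functions or {}

    def visit(node):
        if isinstance(node, ast.Constant):
            if isinstance(node.value, bool):
                raise EquationError("boolean literal in arithmetic expression")
            return sympy.Float(node.value) if isinstance(node.value, float) \
                else sympy.Integer(node.value)
        if isinstance(node, ast.Name):
            return symbols[node.id]
        if isinstance(node, ast.UnaryOp):
            if isinstance(node.op, ast.USub):
                return -visit(node.operand)
            if isinstance(node.op, ast.UAdd):
                return visit(node.operand)
            raise EquationError("boolean operator in arithmetic expression")
        if isinstance(node, ast.BinOp):
            left, right = visit(node.left), visit(node.right)
            if isinstance(node.op, ast.Add):
                return left + right
            if isinstance(node.op, ast.Sub):
                return left - right
            if isinstance(node.op, ast.Mult):
                return left * right
            if isinstance(node.op, ast.Div):
                return left / right
            if isinstance(node.op, ast.Pow):
                return left ** right
        if isinstance(node, ast.Call):
            fname = node.func.id
            args = [visit(a) for a in node.args]
            if fname in _FUNC_MAP:
                return _FUNC_MAP[fname](*args)
            if fname in extra_functions:
                return extra_functions[fname](*args)
            return sympy.Function(fname)(*args)
        raise EquationError(
            f"cannot convert {type(node).__name__} to a symbolic expression")

    node = expr.node if isinstance(expr, Expression) else expr
    return visit(node), symbols


def inline_subexpressions(eqs, order=None):
    """Sympy rhs of every differential entry with subexpressions substituted in.

    Returns (dict name -> sympy expr, dict of all symbols seen).
    """
    from .equations import order_subexpressions

    order = order or order_subexpressions(eqs)
    sub_exprs = {}
    all_symbols = {}
    for name in order:
        entry = eqs[name]
        if entry.kind != "subexpression":
            continue
        s, syms = expression_to_sympy(entry.expr)
        all_symbols.update(syms)
        s = s.subs([(sympy.Symbol(k, real=True), v) for k, v in sub_exprs.items()])
        sub_exprs[name] = s
    out = {}
    for name in eqs.diff_names:
        s, syms = expression_to_sympy(eqs[name].expr)
        all_symbols.update(syms)
        # substitute repeatedly: subexpressions may reference each other
        for k in reversed(list(sub_exprs)):
            s = s.subs(sympy.Symbol(k, real=True), sub_exprs[k])
        out[name] = s
    return out, all_symbols
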