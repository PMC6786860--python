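"""Physical quantities with dimensional bookkeeping.

Every value handed to the simulator is either a plain number (dimensionless)
or a :class:`Quantity`: a float/array stored in SI base scale together with a
:class:`Dimension`, a vector of seven rational exponents over the SI base
dimensions (length, mass, time, current, temperature, amount, luminous
intensity).  Display units (mV, ms, mS/cm2, ...) exist only at parse/format
time; arithmetic and simulation always operate on SI-scaled values, so "1 mV"
is the float 0.001 tagged with the dimension of voltage.

Exponents are rationals rather than integers so that e.g. the white-noise
term xi of dimension time**(-1/2) is representable.
"""

from __future__ import annotations

import re
from fractions import Fraction

import numpy as np

from .errors import DimensionMismatch, UnknownUnit

__all__ = [
    "Dimension", "Quantity", "DIMENSIONLESS", "get_dimension",
    "quantity_arith", "parse_unit_expression", "format_quantity",
    "UNIT_REGISTRY",
]

_BASE_NAMES = ("metre", "kilogram", "second", "amp", "kelvin", "mole", "candela")


class Dimension:
    """An immutable 7-vector of rational exponents over the SI base dimensions."""

    __slots__ = ("exponents",)

    def __init__(self, exponents=None):
        if exponents is None:
            exponents = (Fraction(0),) * 7
        exps = tuple(Fraction(e) for e in exponents)
        if len(exps) != 7:
            raise ValueError("Dimension needs exactly 7 exponents")
        object.__setattr__(self, "exponents", exps)

    def __setattr__(self, *a):  # immutability
        raise AttributeError("Dimension is immutable")

    @property
    def is_dimensionless(self):
        return all(e == 0 for e in self.exponents)

    def __mul__(self, other):
        return Dimension(tuple(a + b for a, b in zip(self.exponents, other.exponents)))

    def __truediv__(self, other):
        return Dimension(tuple(a - b for a, b in zip(self.exponents, other.exponents)))

    def __pow__(self, exponent):
        exponent = Fraction(exponent)
        return Dimension(tuple(a * exponent for a in self.exponents))

    def __eq__(self, other):
        if not isinstance(other, Dimension):
            return NotImplemented
        return self.exponents == other.exponents

    def __hash__(self):
        return hash(self.exponents)

    def __str__(self):
        if self.is_dimensionless:
            return "1"
        parts = []
        for name, e in zip(_BASE_NAMES, self.exponents):
            if e != 0:
                parts.append(f"{name}**({e})" if e != 1 else name)
        return " * ".join(parts)

    def __repr__(self):
        return f"Dimension({self})"


DIMENSIONLESS = Dimension()


def _base(index):
    exps = [0] * 7
    exps[index] = 1
    return Dimension(exps)


LENGTH = _base(0)
MASS = _base(1)
TIME = _base(2)
CURRENT = _base(3)
TEMPERATURE = _base(4)
AMOUNT = _base(5)
LUMINOUS = _base(6)


def get_dimension(obj):
    """Dimension of a Quantity, plain number, or array (the latter two: dimensionless)."""
    if isinstance(obj, Quantity):
        return obj.dim
    return DIMENSIONLESS


def _check_same(a, b, op):
    da, db = get_dimension(a), get_dimension(b)
    if da != db:
        raise DimensionMismatch(
            f"cannot {op} quantities with dimensions {da} and {db}", da, db
        )
    return da


def _value(obj):
    return obj.value if isinstance(obj, Quantity) else obj


class Quantity:
    """A scalar or array of floats in SI base scale, tagged with a Dimension.

    Addition, subtraction and comparison are defined only between quantities of
    equal dimension; multiplication/division/power follow the exponent rules.
    Values broadcast element-wise like numpy arrays.  Equality compares
    SI-scaled values exactly -- tolerances are the caller's concern.
    """

    __slots__ = ("value", "dim")

    def __init__(self, value, dim=DIMENSIONLESS):
        if isinstance(value, Quantity):
            dim = value.dim * dim if dim is not DIMENSIONLESS else value.dim
            value = value.value
        if isinstance(value, np.ndarray):
            value = value.astype(float, copy=False)
        else:
            value = float(value)
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "dim", dim)

    def __setattr__(self, *a):
        raise AttributeError("Quantity is immutable")

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def wrap(value, dim):
        if dim.is_dimensionless:
            return value if not isinstance(value, Quantity) else value.value
        return Quantity(value, dim)

    @property
    def is_dimensionless(self):
        return self.dim.is_dimensionless

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        dim = _check_same(self, other, "add")
        return Quantity.wrap(self.value + _value(other), dim)

    __radd__ = __add__

    def __sub__(self, other):
        dim = _check_same(self, other, "subtract")
        return Quantity.wrap(self.value - _value(other), dim)

    def __rsub__(self, other):
        dim = _check_same(self, other, "subtract")
        return Quantity.wrap(_value(other) - self.value, dim)

    def __mul__(self, other):
        return Quantity.wrap(self.value * _value(other), self.dim * get_dimension(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return Quantity.wrap(self.value / _value(other), self.dim / get_dimension(other))

    def __rtruediv__(self, other):
        return Quantity.wrap(_value(other) / self.value, get_dimension(other) / self.dim)

    def __pow__(self, exponent):
        if isinstance(exponent, Quantity):
            if not exponent.is_dimensionless:
                raise DimensionMismatch("exponent must be dimensionless",
                                        self.dim, exponent.dim)
            exponent = exponent.value
        if self.is_dimensionless:
            return self.value ** exponent
        if np.ndim(exponent) != 0:
            raise DimensionMismatch("a dimensional quantity needs a scalar exponent")
        frac = Fraction(float(exponent)).limit_denominator(1000)
        if abs(float(frac) - float(exponent)) > 1e-12:
            raise DimensionMismatch(
                f"cannot raise a dimensional quantity to a non-rational power {exponent}")
        return Quantity(self.value ** float(frac), self.dim ** frac)

    def __neg__(self):
        return Quantity.wrap(-self.value, self.dim)

    def __pos__(self):
        return self

    def __abs__(self):
        return Quantity.wrap(abs(self.value), self.dim)

    # -- comparison -----------------------------------------------------------
    def _cmp(self, other, op, name):
        _check_same(self, other, name)
        return op(self.value, _value(other))

    def __lt__(self, other):
        return self._cmp(other, np.less, "compare")

    def __le__(self, other):
        return self._cmp(other, np.less_equal, "compare")

    def __gt__(self, other):
        return self._cmp(other, np.greater, "compare")

    def __ge__(self, other):
        return self._cmp(other, np.greater_equal, "compare")

    def __eq__(self, other):
        if isinstance(other, Quantity) or np.isscalar(other) or isinstance(other, np.ndarray):
            da, db = self.dim, get_dimension(other)
            if da != db:
                return False
            return bool(np.all(self.value == _value(other)))
        return NotImplemented

    def __ne__(self, other):
        eq = self.__eq__(other)
        return NotImplemented if eq is NotImplemented else not eq

    def __hash__(self):
        v = self.value
        if isinstance(v, np.ndarray):
            v = v.tobytes()
        return hash((v, self.dim))

    # -- conversions ----------------------------------------------------------
    def __float__(self):
        if not self.is_dimensionless:
            raise DimensionMismatch(
                f"cannot convert quantity of dimension {self.dim} to a bare float")
        return float(self.value)

    def __bool__(self):
        return bool(np.any(self.value))

    def __len__(self):
        return len(self.value)

    def __getitem__(self, idx):
        return Quantity.wrap(np.asarray(self.value)[idx], self.dim)

    def in_units(self, unit):
        """Numeric value of this quantity expressed in ``unit`` (a Quantity)."""
        _check_same(self, unit, "convert")
        return self.value / unit.value

    def __repr__(self):
        return f"Quantity({self.value!r}, {self.dim})"

    def __str__(self):
        return format_quantity(self)


def quantity_arith(a, b, op):
    """Dispatch helper: combine two quantities under one of add/sub/mul/div/pow/cmp."""
    a = a if isinstance(a, Quantity) else Quantity(a)
    if op == "add":
        return a + b
    if op == "sub":
        return a - b
    if op == "mul":
        return a * b
    if op == "div":
        return a / b
    if op == "pow":
        return a ** b
    if op == "cmp":
        return a < b
    raise ValueError(f"unknown op {op!r}")


# ---------------------------------------------------------------------------
# Unit registry
# ---------------------------------------------------------------------------

UNIT_REGISTRY: dict[str, Quantity] = {}


def _register(name, quantity):
    UNIT_REGISTRY[name] = quantity


def _build_registry():
    metre = Quantity(1.0, LENGTH)
    gram = Quantity(1e-3, MASS)
    second = Quantity(1.0, TIME)
    amp = Quantity(1.0, CURRENT)
    kelvin = Quantity(1.0, TEMPERATURE)
    mole = Quantity(1.0, AMOUNT)
    candela = Quantity(1.0, LUMINOUS)

    hertz = Quantity(1.0, DIMENSIONLESS / TIME)
    newton = Quantity(1.0, MASS * LENGTH / TIME ** 2)
    pascal = newton / metre ** 2
    joule = newton * metre
    watt = joule / second
    coulomb = amp * second
    volt = watt / amp
    farad = coulomb / volt
    ohm = volt / amp
    siemens = amp / volt

    prefixes = {"G": 1e9, "M": 1e6, "k": 1e3, "c": 1e-2, "m": 1e-3,
                "u": 1e-6, "n": 1e-9, "p": 1e-12, "f": 1e-15}

    # full names (with common aliases); bare single-letter SI symbols are
    # deliberately not registered so that model variables named s, g, m, h, n,
    # v ... never shadow a unit.
    full = {
        "metre": metre, "meter": metre, "gram": gram, "second": second,
        "amp": amp, "ampere": amp, "kelvin": kelvin, "mole": mole, "mol": mole,
        "candela": candela, "hertz": hertz, "newton": newton, "pascal": pascal,
        "joule": joule, "watt": watt, "coulomb": coulomb, "volt": volt,
        "farad": farad, "ohm": ohm, "siemens": siemens,
        "kilogram": Quantity(1.0, MASS),
    }
    for name, q in full.items():
        _register(name, q)

    symbols = {"V": volt, "S": siemens, "A": amp, "F": farad, "Hz": hertz,
               "ohm": ohm, "m": metre, "s": second, "g": gram, "W": watt,
               "J": joule, "N": newton, "C": coulomb, "Pa": pascal, "mol": mole}
    multi_letter = {"Hz", "ohm", "mol", "Pa"}
    for sym, q in symbols.items():
        if sym in multi_letter:
            _register(sym, q)
        for pre, factor in prefixes.items():
            _register(pre + sym, Quantity(factor) * q)

    # powered length units for areas and volumes (cm2, um2, m2, mm3, ...)
    length_units = {"m2": metre ** 2, "m3": metre ** 3}
    for pre, factor in prefixes.items():
        lu = Quantity(factor) * metre
        length_units[pre + "m2"] = lu ** 2
        length_units[pre + "m3"] = lu ** 3
    for name, q in length_units.items():
        _register(name, q)


_build_registry()


# ---------------------------------------------------------------------------
# Parsing and formatting of unit expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<number>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_]\w*)"
    r"|(?P<op>\*\*|[*/()\-+]))"
)


def _tokenize(text):
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise UnknownUnit(f"cannot parse unit expression {text!r} at position {pos}")
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    tokens.append(("end", ""))
    return tokens


class _UnitParser:
    """expr := term (('*'|'/') term)*;  term := factor ['**' exponent]"""

    def __init__(self, text):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos]

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, value):
        kind, val = self.next()
        if val != value:
            raise UnknownUnit(f"expected {value!r} in {self.text!r}, got {val!r}")

    def parse(self):
        q = self.expr()
        if self.peek()[0] != "end":
            raise UnknownUnit(f"trailing input in unit expression {self.text!r}")
        return q

    def expr(self):
        q = self.term()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            rhs = self.term()
            q = q * rhs if op == "*" else q / rhs
        return q

    def term(self):
        q = self.factor()
        if self.peek()[1] == "**":
            self.next()
            e = self.exponent()
            q = (q if isinstance(q, Quantity) else Quantity(q)) ** e
        return q

    def factor(self):
        kind, val = self.next()
        if val == "(":
            q = self.expr()
            self.expect(")")
            return q
        if val == "-":
            return -self.factor()
        if kind == "number":
            return Quantity(float(val))
        if kind == "name":
            try:
                return UNIT_REGISTRY[val]
            except KeyError:
                raise UnknownUnit(f"unknown unit name {val!r}") from None
        raise UnknownUnit(f"unexpected token {val!r} in {self.text!r}")

    def exponent(self):
        # signed number, or parenthesized rational like (-3/2)
        kind, val = self.next()
        sign = 1
        if val == "-":
            sign = -1
            kind, val = self.next()
        if val == "(":
            inner_sign = 1
            kind, val = self.next()
            if val == "-":
                inner_sign = -1
                kind, val = self.next()
            if kind != "number":
                raise UnknownUnit(f"bad exponent in {self.text!r}")
            num = Fraction(val)
            if self.peek()[1] == "/":
                self.next()
                k2, v2 = self.next()
                if k2 != "number":
                    raise UnknownUnit(f"bad exponent in {self.text!r}")
                num = num / Fraction(v2)
            self.expect(")")
            return sign * inner_sign * num
        if kind != "number":
            raise UnknownUnit(f"bad exponent in {self.text!r}")
        return sign * Fraction(val)


def parse_unit_expression(text):
    """Parse a unit expression like ``"10*mV"``, ``"mS/cm2"`` or ``"ms**-1"``.

    Returns the equivalent SI-scaled :class:`Quantity`.  Raises
    :class:`UnknownUnit` for unregistered names or malformed text.
    """
    q = _UnitParser(str(text).strip()).parse()
    return q if isinstance(q, Quantity) else Quantity(q)


def format_quantity(q):
    """Canonical, re-parseable product form: ``'0.001 * metre**(1) * second**(-2)'``."""
    if not isinstance(q, Quantity):
        return repr(float(q))
    parts = [repr(float(q.value)) if np.ndim(q.value) == 0 else repr(q.value)]
    for name, e in zip(_BASE_NAMES, q.dim.exponents):
        if e != 0:
            parts.append(f"{name}**({e})")
    return " * ".join(parts)


# convenience module-level units used throughout the fixtures and tests
second = UNIT_REGISTRY["second"]
ms = UNIT_REGISTRY["ms"]
us = UNIT_REGISTRY["us"]
volt = UNIT_REGISTRY["volt"]
mV = UNIT_REGISTRY["mV"]
uV = UNIT_REGISTRY["uV"]
amp = UNIT_REGISTRY["amp"]
mA = UNIT_REGISTRY["mA"]
uA = UNIT_REGISTRY["uA"]
nA = UNIT_REGISTRY["nA"]
pA = UNIT_REGISTRY["pA"]
siemens = UNIT_REGISTRY["siemens"]
mS = UNIT_REGISTRY["mS"]
uS = UNIT_REGISTRY["uS"]
nS = UNIT_REGISTRY["nS"]
farad = UNIT_REGISTRY["farad"]
uF = UNIT_REGISTRY["uF"]
nF = UNIT_REGISTRY["nF"]
pF = UNIT_REGISTRY["pF"]
ohm = UNIT_REGISTRY["ohm"]
Mohm = UNIT_REGISTRY["Mohm"]
hertz = UNIT_REGISTRY["Hz"]
Hz = UNIT_REGISTRY["Hz"]
kHz = UNIT_REGISTRY["kHz"]
metre = UNIT_REGISTRY["metre"]
cm = UNIT_REGISTRY["cm"]
mm = UNIT_REGISTRY["mm"]
um = UNIT_REGISTRY["um"]
cm2 = UNIT_REGISTRY["cm2"]
um2 = UNIT_REGISTRY["um2"]
mole = UNIT_REGISTRY["mole"]
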