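"""Parsing and evaluation of custom propensity expressions.

The grammar is deliberately small: identifiers, numeric literals, the binary
operators ``+ - * / ^`` (with ``^`` meaning power), unary minus, parentheses,
and the functions ``exp``, ``log``, ``pow``, ``min``, ``max``.  Identifiers are
case-sensitive and must match ``[A-Za-z_][A-Za-z0-9_]*``.  Expressions are
pure functions of the supplied state and parameter values; time-dependent
propensities are not part of the grammar.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import sympy

__all__ = [
    "ExpressionError",
    "PropensityExpression",
    "parse_expression",
    "evaluate_propensity_expression",
]

IDENTIFIER_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

_FUNCTIONS = {
    "exp": (1, math.exp),
    "log": (1, math.log),
    "pow": (2, math.pow),
    "min": (2, min),
    "max": (2, max),
}

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<number>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/^(),])"
    r")"
)


class ExpressionError(ValueError):
    """Raised for parse failures, unknown identifiers, or invalid evaluation."""


# ---------------------------------------------------------------------------
# AST nodes


@dataclass(frozen=True)
class _Num:
    value: float


@dataclass(frozen=True)
class _Name:
    name: str


@dataclass(frozen=True)
class _BinOp:
    op: str
    left: object
    right: object


@dataclass(frozen=True)
class _Neg:
    operand: object


@dataclass(frozen=True)
class _Call:
    func: str
    args: tuple


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExpressionError(f"unexpected character {rest[0]!r} in expression {text!r}")
        pos = m.end()
        for kind in ("number", "name", "op"):
            value = m.group(kind)
            if value is not None:
                tokens.append((kind, value))
                break
    return tokens


class _Parser:
    """Recursive-descent parser; precedence: +- < */ < unary- < ^ (right-assoc)."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        token = self.peek()
        self.pos += 1
        return token

    def expect_op(self, op: str):
        kind, value = self.next()
        if kind != "op" or value != op:
            raise ExpressionError(f"expected {op!r} in expression {self.text!r}")

    def parse(self):
        node = self.parse_sum()
        if self.pos != len(self.tokens):
            raise ExpressionError(f"trailing tokens in expression {self.text!r}")
        return node

    def parse_sum(self):
        node = self.parse_product()
        while True:
            kind, value = self.peek()
            if kind == "op" and value in "+-":
                self.next()
                node = _BinOp(value, node, self.parse_product())
            else:
                return node

    def parse_product(self):
        node = self.parse_unary()
        while True:
            kind, value = self.peek()
            if kind == "op" and value in "*/":
                self.next()
                node = _BinOp(value, node, self.parse_unary())
            else:
                return node

    def parse_unary(self):
        kind, value = self.peek()
        if kind == "op" and value == "-":
            self.next()
            return _Neg(self.parse_unary())
        if kind == "op" and value == "+":
            self.next()
            return self.parse_unary()
        return self.parse_power()

    def parse_power(self):
        base = self.parse_atom()
        kind, value = self.peek()
        if kind == "op" and value == "^":
            self.next()
            # right-associative; exponent may carry its own unary minus
            return _BinOp("^", base, self.parse_unary())
        return base

    def parse_atom(self):
        kind, value = self.next()
        if kind == "number":
            return _Num(float(value))
        if kind == "name":
            nkind, nvalue = self.peek()
            if nkind == "op" and nvalue == "(":
                if value not in _FUNCTIONS:
                    raise ExpressionError(f"unknown function {value!r} in expression {self.text!r}")
                self.next()
                arity = _FUNCTIONS[value][0]
                args = [self.parse_sum()]
                while len(args) < arity:
                    self.expect_op(",")
                    args.append(self.parse_sum())
                self.expect_op(")")
                return _Call(value, tuple(args))
            return _Name(value)
        if kind == "op" and value == "(":
            node = self.parse_sum()
            self.expect_op(")")
            return node
        raise ExpressionError(f"malformed expression {self.text!r}")


class PropensityExpression:
    """A parsed custom propensity.

    Instances are immutable; evaluation is a pure function of the value maps
    passed to :meth:`evaluate`.
    """

    def __init__(self, text: str):
        self.text = text
        self._ast = _Parser(text).parse()
        self.identifiers = frozenset(self._collect_names(self._ast))

    @staticmethod
    def _collect_names(node, acc=None):
        if acc is None:
            acc = set()
        if isinstance(node, _Name):
            acc.add(node.name)
        elif isinstance(node, _BinOp):
            PropensityExpression._collect_names(node.left, acc)
            PropensityExpression._collect_names(node.right, acc)
        elif isinstance(node, _Neg):
            PropensityExpression._collect_names(node.operand, acc)
        elif isinstance(node, _Call):
            for arg in node.args:
                PropensityExpression._collect_names(arg, acc)
        return acc

    def evaluate(self, values: dict) -> float:
        missing = self.identifiers - values.keys()
        if missing:
            raise ExpressionError(
                f"unknown identifier(s) {sorted(missing)} in expression {self.text!r}"
            )
        return self._eval(self._ast, values)

    @staticmethod
    def _eval(node, values):
        if isinstance(node, _Num):
            return node.value
        if isinstance(node, _Name):
            return float(values[node.name])
        if isinstance(node, _Neg):
            return -PropensityExpression._eval(node.operand, values)
        if isinstance(node, _BinOp):
            left = PropensityExpression._eval(node.left, values)
            right = PropensityExpression._eval(node.right, values)
            if node.op == "+":
                return left + right
            if node.op == "-":
                return left - right
            if node.op == "*":
                return left * right
            if node.op == "/":
                return left / right
            return math.pow(left, right)
        fn = _FUNCTIONS[node.func][1]
        return fn(*(PropensityExpression._eval(arg, values) for arg in node.args))

    def to_sympy(self) -> sympy.Expr:
        """Translate to a sympy expression (used for ODE rate laws / Jacobians)."""
        return self._sympy(self._ast)

    @staticmethod
    def _sympy(node):
        if isinstance(node, _Num):
            return sympy.Float(node.value)
        if isinstance(node, _Name):
            return sympy.Symbol(node.name)
        if isinstance(node, _Neg):
            return -PropensityExpression._sympy(node.operand)
        if isinstance(node, _BinOp):
            left = PropensityExpression._sympy(node.left)
            right = PropensityExpression._sympy(node.right)
            return {
                "+": lambda: left + right,
                "-": lambda: left - right,
                "*": lambda: left * right,
                "/": lambda: left / right,
                "^": lambda: left ** right,
            }[node.op]()
        args = [PropensityExpression._sympy(a) for a in node.args]
        if node.func == "exp":
            return sympy.exp(args[0])
        if node.func == "log":
            return sympy.log(args[0])
        if node.func == "pow":
            return args[0] ** args[1]
        if node.func == "min":
            return sympy.Min(*args)
        if node.func == "max":
            return sympy.Max(*args)
        raise AssertionError(node.func)

    def is_differentiable(self) -> bool:
        """min/max introduce kinks; everything else in the grammar is smooth."""
        return not self._has_minmax(self._ast)

    @staticmethod
    def _has_minmax(node):
        if isinstance(node, _Call):
            if node.func in ("min", "max"):
                return True
            return any(PropensityExpression._has_minmax(a) for a in node.args)
        if isinstance(node, _BinOp):
            return PropensityExpression._has_minmax(node.left) or PropensityExpression._has_minmax(
                node.right
            )
        if isinstance(node, _Neg):
            return PropensityExpression._has_minmax(node.operand)
        return False

    def __repr__(self):
        return f"PropensityExpression({self.text!r})"

    def __eq__(self, other):
        return isinstance(other, PropensityExpression) and self.text == other.text

    def __hash__(self):
        return hash(self.text)


def parse_expression(text: str) -> PropensityExpression:
    return PropensityExpression(text)


def evaluate_propensity_expression(
    expression: str | PropensityExpression,
    state: dict,
    parameters: dict | None = None,
) -> float:
    """Evaluate a custom propensity at the given state.

    Raises :class:`ExpressionError` on parse failure, on identifiers found in
    neither map, and on a negative result (propensities must be nonnegative).
    """
    expr = expression if isinstance(expression, PropensityExpression) else parse_expression(expression)
    values = dict(parameters or {})
    values.update(state)
    result = expr.evaluate(values)
    if result < 0:
        raise ExpressionError(
            f"propensity expression {expr.text!r} evaluated to negative value {result}"
        )
    return result
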