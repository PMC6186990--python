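"""Expression mini-language shared by all modules.

The dialect is deliberately small: identifiers, ``+ - * / **``, parentheses,
the functions ``exp``, ``log``, ``sqrt``, ``sinh``, ``cosh``, ``tanh``, the
time symbol ``t``, and derivatives spelled with trailing primes
(``g_ex''``) which are mapped to flat symbols ``g_ex__d2``.  Plain names
such as ``I`` or ``E`` always parse as symbols, never as SymPy's imaginary
unit or Euler's number; Euler's number is written ``exp(1)``.

Numeric literals are converted to exact rationals so that the symbolic
zero-tests downstream are sound (``0.1`` becomes ``1/10``, not a binary
float).
"""

from __future__ import annotations

import re

import sympy as sp
from sympy.parsing.sympy_parser import (
    parse_expr,
    rationalize,
    standard_transformations,
)
from sympy.printing.str import StrPrinter

__all__ = [
    "TIME",
    "parse_expression",
    "expr_to_str",
    "derivative_symbol",
    "derivative_order",
]

#: The independent time variable of every shape and ODE.
TIME = sp.Symbol("t", real=True)

_FUNCTIONS = {
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "sinh": sp.sinh,
    "cosh": sp.cosh,
    "tanh": sp.tanh,
}

# names the tokenizer's auto-symbol machinery needs to resolve
_GLOBALS = {
    **_FUNCTIONS,
    "Symbol": sp.Symbol,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
}

_TRANSFORMATIONS = standard_transformations + (rationalize,)

_PRIME_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)('+)")
_DERIV_RE = re.compile(r"\A([A-Za-z_][A-Za-z0-9_]*?)__d([0-9]+)\Z")


class ExpressionError(ValueError):
    """Raised when a definition cannot be parsed in the dialect."""


def derivative_symbol(name: str, order: int) -> sp.Symbol:
    """Flat symbol standing for the ``order``-th time derivative of ``name``."""
    if order == 0:
        return sp.Symbol(name)
    return sp.Symbol(f"{name}__d{order}")


def derivative_order(symbol: sp.Symbol | str) -> tuple[str, int]:
    """Invert :func:`derivative_symbol`: return ``(base name, order)``."""
    name = str(symbol)
    m = _DERIV_RE.match(name)
    if m:
        return m.group(1), int(m.group(2))
    return name, 0


def parse_expression(text: str, *, where: str = "expression") -> sp.Expr:
    """Parse ``text`` in the dialect, mapping primes to derivative symbols.

    ``where`` names the field being parsed and is used in error messages.
    """
    if not isinstance(text, str):
        # numeric JSON values are accepted for convenience
        if isinstance(text, bool):
            raise ExpressionError(f"cannot parse {where}: boolean {text!r}")
        if isinstance(text, (int, float)):
            return sp.nsimplify(text, rational=True)
        raise ExpressionError(f"cannot parse {where}: {text!r}")
    prepared = _PRIME_RE.sub(lambda m: f"{m.group(1)}__d{len(m.group(2))}", text)
    try:
        expr = parse_expr(
            prepared,
            local_dict={"t": TIME},
            global_dict=_GLOBALS,
            transformations=_TRANSFORMATIONS,
            evaluate=True,
        )
    except Exception as err:  # sympy raises a zoo of exception types
        raise ExpressionError(f"cannot parse {where}: {text!r} ({err})") from err
    if not isinstance(expr, sp.Expr):
        raise ExpressionError(f"{where} is not a scalar expression: {text!r}")
    return expr


class _DialectPrinter(StrPrinter):
    """String printer emitting only constructs the dialect can re-parse."""

    def _print_Exp1(self, expr):
        return "exp(1)"

    def _print_ExpBase(self, expr):
        return f"exp({self._print(expr.args[0])})"


_PRINTER = _DialectPrinter()


def expr_to_str(expr: sp.Expr) -> str:
    """Serialize ``expr`` so that :func:`parse_expression` round-trips it."""
    return _PRINTER.doprint(sp.sympify(expr))
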