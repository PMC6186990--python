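"""Canonicalization of postsynaptic shapes.

A shape ``iota(t)`` (a postsynaptic current or conductance time course,
e.g. an exponential decay or an alpha function) is admissible when it
satisfies a linear homogeneous ODE with constant coefficients,

    (d/dt)^n iota = sum_{i<n} a_i (d/dt)^i iota,

for some order ``n`` and coefficients ``a_i`` that may depend on model
parameters but not on time or state.  This module decides admissibility
for shapes given either as explicit functions of time or as ODEs with
initial values, and reduces them to a canonical :class:`Shape`.

For function-form shapes the order and coefficients are found
constructively: the candidate coefficients at order ``n`` are obtained by
solving an ``n x n`` linear system built from the shape and its
derivatives evaluated at integer times, and the candidate is accepted only
if the residual of the shape ODE simplifies to zero symbolically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import sympy as sp

from ._expr import TIME, derivative_symbol, expr_to_str
from .model_io import ShapeSpec

__all__ = [
    "Shape",
    "ShapeError",
    "find_nonzero_time",
    "check_order_one",
    "derive_shape_ode",
    "shape_from_function",
    "shape_from_ode",
    "analyse_shape",
    "is_identically_zero",
    "shape_summary",
]

#: how far to scan integer times for a point where the shape is nonzero
_NONZERO_SCAN_BOUND = 100
#: extra diagonal shifts tried when the evaluation matrix X is singular
_SINGULAR_SHIFT_BUDGET = 10


class ShapeError(ValueError):
    """A shape does not obey a linear homogeneous constant-coefficient ODE."""


@dataclass
class Shape:
    """A shape reduced to canonical linear-homogeneous form.

    ``coefficients`` lists ``a_0 .. a_{n-1}``; ``initial_values`` lists the
    shape and its first ``n-1`` derivatives at ``t = 0`` (the values a
    single incoming spike of unit weight deposits on the shape state).
    """

    symbol: str
    order: int
    coefficients: list[sp.Expr]
    initial_values: list[sp.Expr]
    source_form: str
    definition: sp.Expr = field(default=sp.Integer(0))

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("shape order must be >= 1")
        if len(self.coefficients) != self.order or len(self.initial_values) != self.order:
            raise ValueError("coefficients and initial values must match the order")

    def state_symbols(self) -> list[sp.Symbol]:
        """Derivative-chain state symbols ``[iota, iota', ...]`` (low order first)."""
        return [derivative_symbol(self.symbol, k) for k in range(self.order)]

    def derivative_rhs(self) -> sp.Expr:
        """Right-hand side of the order-``n`` derivative in state symbols."""
        return sp.Add(
            *(a * derivative_symbol(self.symbol, i) for i, a in enumerate(self.coefficients))
        )


# ---------------------------------------------------------------------------
# symbolic zero test
# ---------------------------------------------------------------------------

def is_identically_zero(expr: sp.Expr, *, samples: int = 20) -> bool:
    """Decide whether ``expr`` is identically zero in its free symbols.

    Canonical simplification is tried first.  If it is inconclusive, the
    expression is evaluated at pseudo-random rational points with 50-digit
    precision; any sample clearly away from zero decides non-zero.  This
    guards against simplifier weakness without letting double-precision
    rounding masquerade as a zero.
    """
    expr = sp.sympify(expr)
    if expr.is_zero is True:
        return True
    simplified = sp.simplify(sp.expand(expr))
    if simplified.is_zero is True:
        return True
    free = sorted(simplified.free_symbols, key=str)
    if not free:
        if simplified.is_zero is False:
            return False
        value = abs(simplified.evalf(50))
        return bool(value < sp.Float("1e-30"))
    # deterministic pseudo-random rational sample points, bounded away from 0
    rng = itertools.cycle([sp.Rational(p, q) for p, q in
                           [(3, 2), (7, 5), (5, 3), (11, 7), (13, 4), (9, 8), (17, 6)]])
    for k in range(1, samples + 1):
        subs = {s: next(rng) + sp.Rational(k, samples + 1) for s in free}
        try:
            value = abs(simplified.subs(subs).evalf(50))
        except (TypeError, ValueError):
            continue
        if value.is_comparable and value > sp.Float("1e-30"):
            return False
    return True


# ---------------------------------------------------------------------------
# function-form shapes
# ---------------------------------------------------------------------------

def find_nonzero_time(expr: sp.Expr) -> int:
    """Smallest integer ``t* >= 1`` with ``expr(t*) != 0`` (scanning 1, 2, ...)."""
    for t_star in range(1, _NONZERO_SCAN_BOUND + 1):
        value = expr.subs(TIME, sp.Integer(t_star))
        if not is_identically_zero(value, samples=5):
            return t_star
    raise ShapeError("shape is (numerically) zero")


def check_order_one(expr: sp.Expr) -> sp.Expr | None:
    """Return ``a_0`` if ``expr' = a_0 expr`` holds identically, else None."""
    t_star = find_nonzero_time(expr)
    derivative = sp.diff(expr, TIME)
    a0 = sp.simplify(
        derivative.subs(TIME, sp.Integer(t_star)) / expr.subs(TIME, sp.Integer(t_star))
    )
    if is_identically_zero(derivative - a0 * expr):
        return a0
    return None


def _invertible_evaluation_matrix(
    derivatives: list[sp.Expr], order: int
) -> tuple[sp.Matrix, list[int]]:
    """Find times ``(t_1 .. t_n)`` making X = [d^j iota(t_i)] invertible.

    Starts at ``(1, .., n)`` and shifts the whole window by one until the
    determinant is nonzero or the shift budget is exhausted.
    """
    for shift in range(_SINGULAR_SHIFT_BUDGET + 1):
        times = [shift + i + 1 for i in range(order)]
        X = sp.Matrix(
            order,
            order,
            lambda i, j: derivatives[j].subs(TIME, sp.Integer(times[i])),
        )
        if not is_identically_zero(X.det(), samples=5):
            return X, times
    raise ShapeError(
        f"could not find an invertible evaluation matrix for order {order} "
        f"within {_SINGULAR_SHIFT_BUDGET} shifts"
    )


def derive_shape_ode(expr: sp.Expr, max_order: int = 10, *, symbol: str = "shape") -> Shape:
    """Construct the minimal linear homogeneous ODE satisfied by ``expr``.

    Orders ``1 .. max_order`` are tried in turn; a candidate coefficient
    vector is accepted only when the ODE residual vanishes identically.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if is_identically_zero(expr):
        raise ShapeError("shape is (numerically) zero")

    a0 = check_order_one(expr)
    if a0 is not None:
        return Shape(
            symbol=symbol,
            order=1,
            coefficients=[a0],
            initial_values=[sp.simplify(expr.subs(TIME, 0))],
            source_form="function_of_time",
            definition=expr,
        )

    derivatives = [expr, sp.diff(expr, TIME)]
    for order in range(2, max_order + 1):
        derivatives.append(sp.diff(derivatives[-1], TIME))
        X, times = _invertible_evaluation_matrix(derivatives, order)
        rhs = sp.Matrix(
            [derivatives[order].subs(TIME, sp.Integer(ti)) for ti in times]
        )
        factors = [sp.simplify(a) for a in X.LUsolve(rhs)]
        residual = derivatives[order] - sp.Add(
            *(factors[i] * derivatives[i] for i in range(order))
        )
        if is_identically_zero(residual):
            initial_values = [
                sp.simplify(derivatives[k].subs(TIME, 0)) for k in range(order)
            ]
            return Shape(
                symbol=symbol,
                order=order,
                coefficients=factors,
                initial_values=initial_values,
                source_form="function_of_time",
                definition=expr,
            )
    raise ShapeError(
        f"shape {symbol!r} does not obey a linear homogeneous ODE of order <= {max_order}"
    )


def shape_from_function(spec: ShapeSpec, max_order: int = 10) -> Shape:
    """Canonicalize a function-of-time shape specification."""
    return derive_shape_ode(spec.definition, max_order=max_order, symbol=spec.symbol)


# ---------------------------------------------------------------------------
# ODE-form shapes
# ---------------------------------------------------------------------------

def shape_from_ode(spec: ShapeSpec) -> Shape:
    """Canonicalize an ODE-with-initial-values shape specification.

    The definition is the right-hand side of the order-``n`` derivative of
    the shape, where ``n`` is the number of supplied initial values.  Each
    derivative's factor is extracted; the check succeeds only when the
    factors are constant in time and state and the remaining residue is
    identically zero (linearity and homogeneity).
    """
    n = spec.order
    if n < 1:
        raise ShapeError(f"shape {spec.symbol!r}: no initial values supplied")
    state = [derivative_symbol(spec.symbol, k) for k in range(n)]
    rhs = spec.definition
    for free in rhs.free_symbols:
        if free not in state and str(free).startswith(f"{spec.symbol}__d"):
            raise ShapeError(
                f"shape {spec.symbol!r}: derivative {free} exceeds the declared "
                f"order {n} implied by the initial values"
            )
    if TIME in rhs.free_symbols:
        raise ShapeError(
            f"shape {spec.symbol!r}: coefficients must not depend on t"
        )
    coefficients: list[sp.Expr] = []
    residue = rhs
    for sym in state:
        factor = sp.simplify(sp.diff(rhs, sym))
        nonlinear = any(f in factor.free_symbols for f in state)
        if nonlinear or not is_identically_zero(sp.diff(rhs, sym, 2)):
            raise ShapeError(
                f"shape {spec.symbol!r}: derivative {sym} occurs non-linearly"
            )
        coefficients.append(factor)
        residue = residue - factor * sym
    residue = sp.simplify(residue)
    if not is_identically_zero(residue):
        raise ShapeError(
            f"shape {spec.symbol!r}: inhomogeneous term {residue} remains after "
            "subtracting all derivative contributions"
        )
    return Shape(
        symbol=spec.symbol,
        order=n,
        coefficients=coefficients,
        initial_values=[spec.initial_values[k] for k in range(n)],
        source_form="ode_with_initial_values",
        definition=spec.definition,
    )


def analyse_shape(spec: ShapeSpec, max_order: int = 10) -> Shape:
    """Dispatch on the shape's source form."""
    if spec.form == "function":
        return shape_from_function(spec, max_order=max_order)
    return shape_from_ode(spec)


def shape_summary(shape: Shape) -> dict:
    """JSON-serializable canonical form of a shape."""
    return {
        "symbol": shape.symbol,
        "order": shape.order,
        "coefficients": [expr_to_str(a) for a in shape.coefficients],
        "initial_values": [expr_to_str(v) for v in shape.initial_values],
        "source_form": shape.source_form,
    }
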