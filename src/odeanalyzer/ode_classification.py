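"""Classification of state-variable ODEs.

A state ODE ``d/dt y = r(y, ...)`` can be evolved exactly by a propagator
matrix only when it is linear with a constant coefficient: the second
derivative of the right-hand side with respect to its own symbol must
vanish, and the first derivative (the coefficient of the symbol) must be
constant, i.e. free of time, of all state symbols and of all shape
symbols.  Parameters are allowed in the coefficient.

Classification never fails; it only routes the model to the analytic or
the numeric branch.  A single non-conforming ODE routes the whole system
to the numeric branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import sympy as sp

from ._expr import TIME, derivative_order
from .shape_analysis import Shape, is_identically_zero

__all__ = ["ClassifiedOde", "classify_ode"]


@dataclass
class ClassifiedOde:
    """A state ODE with its linearity verdict and extracted factors."""

    symbol: str
    rhs: sp.Expr
    linear_constant_coefficient: bool
    symbol_factor: sp.Expr | None = None
    shape_factors: dict[str, sp.Expr] = field(default_factory=dict)


def _depends_on_dynamics(
    expr: sp.Expr, state_symbols: Iterable[str], shape_symbols: Iterable[str]
) -> bool:
    """True if ``expr`` involves t, a state symbol, or a shape (derivative)."""
    states = set(state_symbols)
    shapes = set(shape_symbols)
    for free in expr.free_symbols:
        if free == TIME:
            return True
        base, _ = derivative_order(free)
        if base in states or base in shapes:
            return True
    return False


def classify_ode(
    symbol: str,
    rhs: sp.Expr,
    shapes: Sequence[Shape],
    *,
    state_symbols: Sequence[str] | None = None,
) -> ClassifiedOde:
    """Decide whether ``d/dt symbol = rhs`` is linear constant coefficient.

    When it is, the factor of the symbol itself and the factor of every
    shape symbol are extracted (these populate the system matrix of the
    analytic scheme).
    """
    sym = sp.Symbol(symbol)
    states = list(state_symbols) if state_symbols is not None else [symbol]
    shape_names = [s.symbol for s in shapes]

    second = sp.simplify(sp.diff(rhs, sym, 2))
    coefficient = sp.simplify(sp.diff(rhs, sym))
    linear = is_identically_zero(second)
    constant = not _depends_on_dynamics(coefficient, states, shape_names)

    if not (linear and constant):
        return ClassifiedOde(symbol=symbol, rhs=rhs, linear_constant_coefficient=False)

    shape_factors = {
        name: sp.simplify(sp.diff(rhs, sp.Symbol(name))) for name in shape_names
    }
    return ClassifiedOde(
        symbol=symbol,
        rhs=rhs,
        linear_constant_coefficient=True,
        symbol_factor=coefficient,
        shape_factors=shape_factors,
    )
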