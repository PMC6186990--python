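"""Exact propagator-based evolution schemes for linear models.

For a membrane equation ``d/dt V = vf*V + sum_s sf_s * s(t) + b`` whose
drive consists of postsynaptic shapes ``s`` satisfying linear homogeneous
ODEs and an optional constant bias ``b``, the joint system of each shape's
derivative chain together with ``V`` is linear with constant coefficients,

    d/dt y = A y,    y(t + h) = e^{A h} y(t) = P(h) y(t),

so one matrix exponential per shape evolves the state exactly over a grid
step ``h``.  Incoming spikes enter as state increments: a spike of weight
``w`` arriving at a grid point adds ``w`` times the shape's initial values
to the shape's sub-state.  Several shapes superpose: each contributes its
own propagator and its own additive term to the ``V`` update, and the bias
contributes the closed-form term ``-(b/vf) * (1 - e^{vf h})``.

For shapes of order 1 and 2 the system matrix is written in lower
triangular form (for order 2 via the auxiliary combination
``y_1 = s' + x s`` with ``x = -a_1/2 + sqrt(a_1^2/4 + a_0)``), which keeps
the propagator entries compact; higher orders, and order-2 shapes whose
``x`` would be complex, use the generic companion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from ._expr import TIME, derivative_order, derivative_symbol, expr_to_str
from .model_io import ModelSpec, ValidationError
from .ode_classification import ClassifiedOde
from .shape_analysis import Shape, is_identically_zero

__all__ = [
    "PropagatorError",
    "SystemMatrix",
    "PropagatorScheme",
    "build_system_matrix",
    "compute_propagator",
    "compose_update_step",
    "build_scheme",
    "serialize_scheme",
    "evolve_analytic",
    "resolve_parameters",
    "decomposes_linearly",
]

#: symbolic grid step used in all propagator expressions
STEP = sp.Symbol("h")


class PropagatorError(RuntimeError):
    """The symbolic matrix exponential could not be computed in closed form;
    the model should be routed to the numeric branch."""


@dataclass
class SystemMatrix:
    """Homogeneous system matrix for one shape coupled to the state ODE.

    ``state_order`` names the components of ``y`` (the state symbol last);
    ``transform_T`` maps the plain derivative vector
    ``((d/dt)^{n-1} s, ..., s, V)`` to ``y`` and is the identity unless the
    triangular order-2 form is used.
    """

    A: sp.Matrix
    state_order: list[str]
    transform_T: sp.Matrix
    triangular: bool
    x_aux: sp.Expr | None = None
    shape: Shape | None = None
    ode_symbol: str = ""


@dataclass
class PropagatorScheme:
    """Complete analytic update scheme for one state ODE and its shapes."""

    ode_symbol: str
    symbol_factor: sp.Expr
    systems: list[SystemMatrix]
    propagators: list[sp.Matrix]
    state_order: list[str]
    update_exprs: dict[str, sp.Expr]          # without the bias term
    update_instructions: list[str]            # full, including bias
    spike_increments: dict[str, list[sp.Expr]]
    bias: sp.Expr = field(default_factory=lambda: sp.Integer(0))
    bias_update: sp.Expr = field(default_factory=lambda: sp.Integer(0))
    initial_state: dict[str, sp.Expr] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# routing helper
# ---------------------------------------------------------------------------

def _parameter_only(
    expr: sp.Expr,
    ode: ClassifiedOde,
    shapes: list[Shape],
    state_symbols: list[str] | None = None,
) -> bool:
    dynamic = {ode.symbol} | {s.symbol for s in shapes} | set(state_symbols or ())
    for free in expr.free_symbols:
        if free == TIME:
            return False
        base, _ = derivative_order(free)
        if base in dynamic:
            return False
    return True


def linear_remainder(
    ode: ClassifiedOde,
    shapes: list[Shape],
    state_symbols: list[str] | None = None,
) -> sp.Expr | None:
    """Bias term left after removing the symbol and shape contributions.

    Returns None when the right-hand side does not decompose as
    ``vf*symbol + sum_s sf_s*s + const(parameters)`` — in particular when
    it couples to another state variable.
    """
    if not ode.linear_constant_coefficient:
        return None
    rest = ode.rhs - ode.symbol_factor * sp.Symbol(ode.symbol)
    for shape in shapes:
        factor = ode.shape_factors.get(shape.symbol, sp.Integer(0))
        if not _parameter_only(factor, ode, shapes, state_symbols):
            return None
        rest = rest - factor * sp.Symbol(shape.symbol)
    rest = sp.simplify(rest)
    if not _parameter_only(rest, ode, shapes, state_symbols):
        return None
    if not _parameter_only(ode.symbol_factor, ode, shapes, state_symbols):
        return None
    return rest


def decomposes_linearly(
    ode: ClassifiedOde,
    shapes: list[Shape],
    state_symbols: list[str] | None = None,
) -> bool:
    return linear_remainder(ode, shapes, state_symbols) is not None


# ---------------------------------------------------------------------------
# system matrix
# ---------------------------------------------------------------------------

def _provably_real(expr: sp.Expr) -> bool:
    """Conservative check that ``sqrt(expr)`` stays real for real parameters."""
    expr = sp.simplify(expr)
    if expr.is_zero is True or expr.is_nonnegative is True:
        return True
    root = sp.simplify(sp.sqrt(sp.factor(expr)))
    if root.has(sp.I):
        return False
    # a surviving half-integer power means the sign is genuinely unknown
    return not any(
        p.exp.is_Rational and p.exp.q == 2 for p in root.atoms(sp.Pow)
    )


def build_system_matrix(
    shape: Shape, ode: ClassifiedOde, *, force_generic: bool = False
) -> SystemMatrix:
    """Assemble ``A`` (and the transform ``T``) for one shape.

    Order 1 and order 2 (with a real auxiliary root ``x``) yield lower
    triangular matrices; everything else uses the companion form whose
    first row carries the shape coefficients ``a_{n-1} .. a_0``.
    ``force_generic`` requests the companion form regardless of order (the
    two forms evolve identical trajectories; the triangular one is merely
    cheaper to evaluate).
    """
    if not ode.linear_constant_coefficient:
        raise ValueError("system matrix requires a linear constant-coefficient ODE")
    n = shape.order
    sf = ode.shape_factors.get(shape.symbol, sp.Integer(0))
    vf = ode.symbol_factor
    sym = shape.symbol

    if n == 1 and not force_generic:
        a0 = shape.coefficients[0]
        A = sp.Matrix([[a0, 0], [sf, vf]])
        return SystemMatrix(
            A=A,
            state_order=[sym, ode.symbol],
            transform_T=sp.eye(2),
            triangular=True,
            shape=shape,
            ode_symbol=ode.symbol,
        )

    if n == 2 and not force_generic:
        a0, a1 = shape.coefficients
        disc = sp.simplify(a1**2 / 4 + a0)
        if _provably_real(disc):
            x = sp.simplify(-a1 / 2 + sp.sqrt(disc))
            A = sp.Matrix(
                [
                    [a1 + x, 0, 0],
                    [1, -x, 0],
                    [0, sf, vf],
                ]
            )
            T = sp.Matrix([[1, x, 0], [0, 1, 0], [0, 0, 1]])
            return SystemMatrix(
                A=A,
                state_order=[f"{sym}__x", sym, ode.symbol],
                transform_T=T,
                triangular=True,
                x_aux=x,
                shape=shape,
                ode_symbol=ode.symbol,
            )

    # generic companion form, y = ((d/dt)^{n-1} s, ..., s, V)
    A = sp.zeros(n + 1, n + 1)
    for j in range(n):
        A[0, j] = shape.coefficients[n - 1 - j]
    for i in range(1, n):
        A[i, i - 1] = 1
    A[n, n - 1] = sf
    A[n, n] = vf
    state_order = [str(derivative_symbol(sym, n - 1 - j)) for j in range(n)]
    state_order.append(ode.symbol)
    return SystemMatrix(
        A=A,
        state_order=state_order,
        transform_T=sp.eye(n + 1),
        triangular=False,
        shape=shape,
        ode_symbol=ode.symbol,
    )


def compute_propagator(sys: SystemMatrix, h: sp.Symbol = STEP) -> sp.Matrix:
    """Symbolic one-step propagator ``P(h) = e^{A h}``, simplified."""
    try:
        P = (sys.A * h).exp()
    except (NotImplementedError, ValueError) as err:
        raise PropagatorError(
            "symbolic matrix exponential unavailable; use the numeric branch"
        ) from err
    return P.applyfunc(lambda e: sp.simplify(sp.expand(e)))


# ---------------------------------------------------------------------------
# update step
# ---------------------------------------------------------------------------

def _spike_increment(sys: SystemMatrix) -> list[sp.Expr]:
    """State increment per unit synaptic weight for one incoming spike.

    The plain derivative vector jumps by the shape's initial values
    (highest derivative first, no jump in the state variable); the stored
    state jumps by ``T`` times that vector.
    """
    shape = sys.shape
    n = shape.order
    jump = sp.Matrix([shape.initial_values[n - 1 - j] for j in range(n)] + [0])
    y_jump = sys.transform_T * jump
    return [sp.simplify(y_jump[i]) for i in range(n)]


def compose_update_step(
    propagators: list[sp.Matrix],
    shapes: list[Shape],
    ode: ClassifiedOde,
    bias: sp.Expr | None = None,
    *,
    systems: list[SystemMatrix] | None = None,
    h: sp.Symbol = STEP,
) -> PropagatorScheme:
    """Merge per-shape propagators into one simultaneous update scheme.

    All right-hand sides read pre-step values; the instructions may
    therefore be executed in any order.  Each shape's sub-state evolves by
    its own propagator block, all shapes contribute additively to the
    state-variable update, and a constant bias adds its closed-form term.
    """
    if systems is None:
        systems = [build_system_matrix(shape, ode) for shape in shapes]
    if len(propagators) != len(shapes):
        raise ValueError("need exactly one propagator per shape")
    vf = ode.symbol_factor
    bias = sp.Integer(0) if bias is None else sp.sympify(bias)

    state_order: list[str] = []
    update_exprs: dict[str, sp.Expr] = {}
    spike_increments: dict[str, list[sp.Expr]] = {}
    v_terms: list[sp.Expr] = []

    for sys, P, shape in zip(systems, propagators, shapes):
        n = shape.order
        local = sys.state_order[:n]
        state_order.extend(local)
        for i in range(n):
            expr = sp.Add(*(P[i, j] * sp.Symbol(local[j]) for j in range(n)))
            update_exprs[local[i]] = sp.simplify(expr)
        v_terms.append(sp.Add(*(P[n, j] * sp.Symbol(local[j]) for j in range(n))))
        spike_increments[shape.symbol] = _spike_increment(sys)

    state_order.append(ode.symbol)
    v_expr = sp.exp(vf * h) * sp.Symbol(ode.symbol) + sp.Add(*v_terms)
    update_exprs[ode.symbol] = sp.simplify(v_expr)

    if is_identically_zero(bias):
        bias_update = sp.Integer(0)
    elif is_identically_zero(vf):
        bias_update = bias * h
    else:
        bias_update = sp.simplify(-(bias / vf) * (1 - sp.exp(vf * h)))

    instructions = []
    for name in state_order:
        expr = update_exprs[name]
        if name == ode.symbol and bias_update != 0:
            expr = expr + bias_update
        instructions.append(f"{name} = {expr_to_str(expr)}")

    return PropagatorScheme(
        ode_symbol=ode.symbol,
        symbol_factor=vf,
        systems=systems,
        propagators=propagators,
        state_order=state_order,
        update_exprs=update_exprs,
        update_instructions=instructions,
        spike_increments=spike_increments,
        bias=bias,
        bias_update=bias_update,
    )


def build_scheme(ode: ClassifiedOde, shapes: list[Shape], model: ModelSpec) -> PropagatorScheme:
    """Full analytic pipeline for one classified ODE: matrices, propagators,
    update step, and initial state."""
    bias = linear_remainder(ode, shapes)
    if bias is None:
        raise ValueError(
            f"ode {ode.symbol!r} does not decompose into symbol, shape and "
            "constant contributions"
        )
    systems = [build_system_matrix(shape, ode) for shape in shapes]
    propagators = [compute_propagator(sys) for sys in systems]
    scheme = compose_update_step(
        propagators, shapes, ode, bias=bias, systems=systems
    )
    init = {name: sp.Integer(0) for name in scheme.state_order}
    spec = next(o for o in model.odes if o.symbol == ode.symbol)
    init[ode.symbol] = spec.initial_value()
    scheme.initial_state = init
    return scheme


def serialize_scheme(scheme: PropagatorScheme) -> dict:
    """JSON-serializable form: named propagator entries, instruction list,
    initial state and per-shape spike increments."""
    propagators: dict[str, str] = {}
    for sys, P in zip(scheme.systems, scheme.propagators):
        sym = sys.shape.symbol
        for i in range(P.rows):
            for j in range(P.cols):
                if P[i, j] != 0:
                    propagators[f"P_{sym}_{i}_{j}"] = expr_to_str(P[i, j])
    return {
        "propagators": propagators,
        "update_instructions": list(scheme.update_instructions),
        "state": {name: expr_to_str(v) for name, v in scheme.initial_state.items()},
        "spike_increments": {
            sym: [expr_to_str(e) for e in vec]
            for sym, vec in scheme.spike_increments.items()
        },
    }


# ---------------------------------------------------------------------------
# numeric execution (for validation and downstream use)
# ---------------------------------------------------------------------------

def resolve_parameters(parameters: dict[str, sp.Expr]) -> dict[str, sp.Expr]:
    """Resolve parameter defaults (which may reference one another) to numbers."""
    resolved: dict[str, sp.Expr] = {}
    remaining = dict(parameters)
    for _ in range(len(parameters) + 1):
        progress = False
        for name, expr in list(remaining.items()):
            value = sp.sympify(expr).subs(
                {sp.Symbol(k): v for k, v in resolved.items()}
            )
            if not value.free_symbols:
                resolved[name] = value
                del remaining[name]
                progress = True
        if not remaining:
            return resolved
        if not progress:
            break
    raise ValidationError(
        f"parameters cannot be resolved to numbers: {sorted(remaining)}"
    )


def _numeric_update(
    scheme: PropagatorScheme,
    parameters: dict[str, sp.Expr],
    h_value: float,
) -> tuple[np.ndarray, np.ndarray, float, dict[str, np.ndarray]]:
    """Evaluate the linear update numerically: matrix M, the unit bias
    response, and per-shape increment vectors.

    The update matrix is assembled from matrix exponentials of the
    parameter-substituted system matrices rather than by evaluating the
    general symbolic propagator entries: the generic entries contain
    removable singularities at degenerate parameter points (equal shape
    and membrane time constants), where direct substitution would be
    ill-defined while ``e^{A h}`` itself is perfectly smooth.
    """
    from scipy.linalg import expm

    resolved = resolve_parameters(parameters)
    subs = {sp.Symbol(k): v for k, v in resolved.items()}
    names = scheme.state_order
    m = len(names)
    v_idx = names.index(scheme.ode_symbol)
    vf = float(scheme.symbol_factor.subs(subs).evalf(30))
    M = np.zeros((m, m))
    M[v_idx, v_idx] = float(np.exp(vf * h_value))
    for sys in scheme.systems:
        n = sys.shape.order
        A = np.array(sys.A.subs(subs).evalf(30), dtype=float)
        B = expm(A * h_value)
        offset = names.index(sys.state_order[0])
        M[offset:offset + n, offset:offset + n] = B[:n, :n]
        M[v_idx, offset:offset + n] = B[n, :n]
    if vf == 0.0:
        bias_unit = h_value
    else:
        bias_unit = -(1.0 / vf) * (1.0 - float(np.exp(vf * h_value)))
    increments = {}
    for sym, vec in scheme.spike_increments.items():
        full = np.zeros(m)
        sys = next(s for s in scheme.systems if s.shape.symbol == sym)
        offset = names.index(sys.state_order[0])
        for k, e in enumerate(vec):
            full[offset + k] = float(sp.sympify(e).subs(subs).evalf(30))
        increments[sym] = full
    return M, np.zeros(m), bias_unit, increments


def evolve_analytic(
    scheme: PropagatorScheme,
    initial_state: dict[str, float] | np.ndarray | None,
    spike_times_and_weights: list[tuple[float, str, float]] | list[tuple[float, float]],
    h: float,
    n_steps: int,
    *,
    parameters: dict[str, sp.Expr],
    bias_values: np.ndarray | None = None,
) -> np.ndarray:
    """Iterate the update scheme over ``n_steps`` grid steps.

    ``spike_times_and_weights`` lists ``(time, weight)`` events (delivered
    to the first shape) or ``(time, shape_symbol, weight)`` events; spike
    times must sit on the grid.  ``bias_values``, if given, supplies a
    piecewise-constant bias value for each step, overriding the scheme's
    constant bias.  Returns the trajectory, shape ``(n_steps + 1, m)``.
    """
    M, _, bias_unit, increments = _numeric_update(scheme, parameters, h)
    names = scheme.state_order
    m = len(names)

    state = np.zeros(m)
    if isinstance(initial_state, dict):
        for name, value in initial_state.items():
            state[names.index(name)] = float(value)
    elif initial_state is not None:
        state = np.asarray(initial_state, dtype=float).copy()
    else:
        resolved = resolve_parameters(parameters)
        subs = {sp.Symbol(k): v for k, v in resolved.items()}
        for i, name in enumerate(names):
            state[i] = float(scheme.initial_state.get(name, sp.Integer(0)).subs(subs))

    default_shape = scheme.systems[0].shape.symbol if scheme.systems else None
    events: dict[int, dict[str, float]] = {}
    for event in spike_times_and_weights:
        if len(event) == 2:
            time, weight = event
            shape_sym = default_shape
        else:
            time, shape_sym, weight = event
        idx = time / h
        if abs(idx - round(idx)) > 1e-9:
            raise ValueError(f"spike time {time} is not on the grid (h = {h})")
        k = int(round(idx))
        if not 0 <= k <= n_steps:
            raise ValueError(f"spike time {time} outside the simulated window")
        events.setdefault(k, {}).setdefault(shape_sym, 0.0)
        events[k][shape_sym] += weight

    resolved = resolve_parameters(parameters)
    subs = {sp.Symbol(k): v for k, v in resolved.items()}
    default_bias = float(scheme.bias.subs(subs).evalf(30)) if scheme.bias != 0 else 0.0
    v_idx = names.index(scheme.ode_symbol)

    def apply_events(k: int, x: np.ndarray) -> None:
        for sym, w in events.get(k, {}).items():
            if sym is None or sym not in increments:
                raise ValueError(
                    f"no shape available to receive the spike at step {k}"
                )
            x += w * increments[sym]

    trajectory = np.zeros((n_steps + 1, m))
    apply_events(0, state)
    trajectory[0] = state
    for step in range(1, n_steps + 1):
        state = M @ state
        b = default_bias if bias_values is None else float(bias_values[step - 1])
        state[v_idx] += b * bias_unit
        apply_events(step, state)
        trajectory[step] = state
    return trajectory
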