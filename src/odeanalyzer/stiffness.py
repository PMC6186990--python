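"""Empirical stiffness detection for the numeric branch.

The tester integrates the model over a fixed grid under Poisson spike
bombardment twice — once with an explicit embedded Runge-Kutta 4(5)
stepper and once with an implicit adaptive stepper — and compares the
minimal and average accepted internal step sizes.  A system that forces
the explicit stepper down to (or below) steps near machine precision
while the implicit stepper copes, or whose implicit average step exceeds
the explicit one by more than a factor ``beta``, is deemed stiff and an
implicit scheme is recommended.  The decision tree:

* ``m_expl < 10*eps`` and ``m_impl < 10*eps``  -> warning (no recommendation)
* ``m_expl < 10*eps <= m_impl``                -> implicit
* ``m_impl < 10*eps <= m_expl``                -> explicit
* both ``>= 10*eps``: implicit iff ``s_impl > beta * s_expl``, else explicit

An explicit run that aborts with a non-finite state counts as
``m_expl < 10*eps`` (the abort is itself evidence of stiffness).
``beta`` defaults to 6, calibrated conservatively on the controlled stiff
pair ``y1' = a*y1, y2' = -2*y2 + y1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import RK45

from ._steppers import BaderDeuflhard

from ._expr import TIME, derivative_symbol
from .model_io import ModelSpec, SolverRecommendation
from .analytic_solver import resolve_parameters
from .shape_analysis import Shape

__all__ = [
    "MACHINE_EPSILON",
    "SpikeTrainConfig",
    "StepStats",
    "NumericSystem",
    "generate_spike_trains",
    "build_numeric_system",
    "integrate_adaptive",
    "classify_stiffness",
    "stiffness_test",
    "StiffnessError",
]

#: double-precision unit roundoff; "close to machine precision" means < 10*eps
MACHINE_EPSILON = float(np.finfo(float).eps)

# the explicit stepper uses mostly absolute error control, mirroring a
# desired-accuracy setting; the relative tolerance is kept at a floor
_RTOL_FLOOR = 100 * MACHINE_EPSILON


class StiffnessError(RuntimeError):
    """The system could not be integrated by either scheme."""


@dataclass
class SpikeTrainConfig:
    """Poisson spike bombardment used during the stiffness test.

    ``rate`` is the event rate per unit model time (default 0.1, i.e. two
    expected events per default 20-unit run), ``weight`` the increment a
    single event deposits on the driven state.
    """

    rate: float = 0.1
    duration: float = 20.0
    trials: int = 5
    seed: int = 0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.duration <= 0 or self.trials < 1:
            raise ValueError("invalid spike-train configuration")


@dataclass
class StepStats:
    """Accepted-step statistics of one adaptive integration run."""

    scheme: str
    min_step: float
    avg_step: float
    accepted_steps: int
    failed: bool = False
    machine_epsilon: float = MACHINE_EPSILON

    def effectively_below_cutoff(self) -> bool:
        """Minimal step below 10*eps; a failed run counts as below."""
        return self.failed or self.min_step < 10 * self.machine_epsilon


def generate_spike_trains(
    config: SpikeTrainConfig, resolution: float | None = None
) -> list[np.ndarray]:
    """Per-trial Poisson event times in ``(0, duration]``, grid-aligned.

    Homogeneous Poisson process realizations (exponential inter-event
    intervals with mean ``1/rate``), deterministic given the seed.  With a
    ``resolution`` the times are snapped to the nearest grid point.
    """
    trains: list[np.ndarray] = []
    for trial in range(config.trials):
        rng = np.random.default_rng([int(config.seed) % 2**31, trial])
        times: list[float] = []
        t = 0.0
        if config.rate > 0:
            while True:
                t += rng.exponential(1.0 / config.rate)
                if t > config.duration:
                    break
                times.append(t)
        arr = np.asarray(times)
        if resolution is not None and arr.size:
            arr = np.round(arr / resolution) * resolution
            arr = arr[(arr > 0) & (arr <= config.duration)]
        trains.append(arr)
    return trains


# ---------------------------------------------------------------------------
# numeric system construction
# ---------------------------------------------------------------------------

@dataclass
class NumericSystem:
    """First-order numeric form of a model: state names, RHS callable,
    initial state, and the per-unit-weight spike increment vector."""

    state_names: list[str]
    rhs: object  # callable (t, y) -> ndarray
    jac: object  # callable (t, y) -> ndarray, the symbolic Jacobian
    y0: np.ndarray
    spike_increment: np.ndarray


def build_numeric_system(
    model: ModelSpec, shapes: list[Shape] | None = None
) -> NumericSystem:
    """Lower a model to a flat first-order ODE system with resolved parameters.

    Each shape of order ``n`` contributes ``n`` chained state variables
    obeying its canonical linear ODE.  Spikes increment the shape states
    by the shape's initial values; for models that declare no shapes the
    unit weight is deposited on every state variable instead.
    """
    from .shape_analysis import analyse_shape

    if shapes is None:
        shapes = [analyse_shape(s) for s in model.shapes]
    resolved = resolve_parameters(model.parameters)
    subs = {sp.Symbol(k): v for k, v in resolved.items()}

    names: list[str] = []
    exprs: list[sp.Expr] = []
    y0: list[float] = []
    increment: list[float] = []

    for ode in model.odes:
        names.append(ode.symbol)
        exprs.append(ode.definition)
        y0.append(float(sp.sympify(ode.initial_value()).subs(subs).evalf(30)))
        increment.append(0.0 if shapes else 1.0)

    for shape in shapes:
        n = shape.order
        for k in range(n):
            names.append(str(derivative_symbol(shape.symbol, k)))
            if k < n - 1:
                exprs.append(derivative_symbol(shape.symbol, k + 1))
            else:
                exprs.append(shape.derivative_rhs())
            y0.append(0.0)
            increment.append(float(sp.sympify(shape.initial_values[k]).subs(subs).evalf(30)))

    symbols = [sp.Symbol(n) for n in names]
    substituted = [sp.sympify(e).subs(subs) for e in exprs]
    f = sp.lambdify((TIME, symbols), substituted, modules="numpy")
    jac_matrix = sp.Matrix(substituted).jacobian(symbols)
    jf = sp.lambdify((TIME, symbols), jac_matrix, modules="numpy")

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return np.asarray(f(t, y), dtype=float)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        return np.asarray(jf(t, y), dtype=float)

    return NumericSystem(
        state_names=names,
        rhs=rhs,
        jac=jac,
        y0=np.asarray(y0),
        spike_increment=np.asarray(increment),
    )


# ---------------------------------------------------------------------------
# adaptive integration
# ---------------------------------------------------------------------------

_SCHEMES = ("explicit", "implicit")


def integrate_adaptive(
    system: NumericSystem,
    scheme: str,
    spikes: np.ndarray,
    h: float,
    tol: float,
    duration: float | None = None,
) -> StepStats:
    """Integrate grid interval by grid interval, recording accepted steps.

    Each interval ``[t, t+h]`` is integrated with the adaptive stepper at
    absolute accuracy ``tol``; spike increments are applied to the state
    at their grid points.  The proposed step size carries over between
    intervals (capped by the interval length).  A non-finite state or a
    stepper failure aborts the run and marks it failed.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; use 'explicit' or 'implicit'")
    if h <= 0 or tol <= 0:
        raise ValueError("resolution and accuracy must be positive")
    if duration is None:
        duration = max(float(np.max(spikes)) if len(spikes) else 0.0, 20.0 * h)
    n_steps = max(1, int(round(duration / h)))

    spike_bins: dict[int, float] = {}
    for s in np.atleast_1d(spikes):
        k = int(round(float(s) / h))
        spike_bins[k] = spike_bins.get(k, 0.0) + 1.0

    y = system.y0.copy()
    min_step = math.inf
    total = 0.0
    count = 0
    # the first trial step is the grid resolution itself; thereafter the
    # controller's proposal carries over from interval to interval
    carry: float | None = h
    failed = False

    for k in range(n_steps):
        if k in spike_bins:
            y = y + spike_bins[k] * system.spike_increment
        t0, t1 = k * h, (k + 1) * h
        # the carried-over proposal must not exceed the exact interval length
        first = min(carry, t1 - t0) if carry is not None else None
        try:
            if scheme == "explicit":
                solver = RK45(
                    system.rhs, t0, y, t_bound=t1,
                    rtol=_RTOL_FLOOR, atol=tol, first_step=first,
                )
            else:
                solver = BaderDeuflhard(
                    system.rhs, t0, y, t_bound=t1, jac=system.jac,
                    rtol=_RTOL_FLOOR, atol=tol, first_step=first,
                )
            intended = float(solver.h_abs)
            while solver.status == "running":
                intended = float(solver.h_abs)
                solver.step()
                if not np.all(np.isfinite(solver.y)):
                    failed = True
                    break
                step = solver.step_size
                if step is not None and step > 0:
                    # a sub-ulp final step that merely lands on the grid
                    # boundary is a rounding artifact, not a controller
                    # decision; genuine near-epsilon stepping shows up in
                    # every step of the interval, not just the last
                    sliver = solver.status == "finished" and step < 1e-9 * h
                    if not sliver:
                        min_step = min(min_step, step)
                        total += step
                        count += 1
            if solver.status == "failed":
                failed = True
            y = solver.y
            # keep the proposal the controller wanted: a step clipped at the
            # grid boundary must not feed its (inflated) successor forward
            if solver.status == "finished" and intended > t1 - solver.t_old:
                carry = intended
            elif solver.h_abs and np.isfinite(solver.h_abs):
                carry = float(solver.h_abs)
        except (FloatingPointError, ValueError, OverflowError):
            failed = True
        if failed or not np.all(np.isfinite(y)):
            failed = True
            break

    if count == 0:
        failed = True
        min_step, avg = 0.0, 0.0
    else:
        avg = total / count
    return StepStats(
        scheme=scheme,
        min_step=0.0 if failed else min_step,
        avg_step=avg,
        accepted_steps=count,
        failed=failed,
    )


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

def classify_stiffness(
    expl: StepStats, impl: StepStats, beta: float = 6.0
) -> SolverRecommendation:
    """Map a pair of step statistics to a solver recommendation."""
    cutoff = 10 * MACHINE_EPSILON
    expl_small = expl.effectively_below_cutoff()
    impl_small = impl.effectively_below_cutoff()

    if expl_small and impl_small:
        scheme, rule = "warning", "both minimal step sizes below 10*eps"
    elif expl_small:
        scheme, rule = "numeric-implicit", "explicit minimal step below 10*eps"
    elif impl_small:
        scheme, rule = "numeric-explicit", "implicit minimal step below 10*eps"
    elif impl.avg_step > beta * expl.avg_step:
        scheme, rule = "numeric-implicit", f"s_implicit > {beta} * s_explicit"
    else:
        scheme, rule = "numeric-explicit", f"s_implicit <= {beta} * s_explicit"

    evidence = {
        "m_explicit": expl.min_step,
        "s_explicit": expl.avg_step,
        "explicit_failed": expl.failed,
        "m_implicit": impl.min_step,
        "s_implicit": impl.avg_step,
        "implicit_failed": impl.failed,
        "machine_epsilon": MACHINE_EPSILON,
        "cutoff": cutoff,
        "beta": beta,
        "decision": rule,
    }
    return SolverRecommendation(scheme=scheme, stiffness_evidence=evidence)


def _aggregate(runs: list[StepStats], scheme: str) -> StepStats:
    """Minimum of minima, mean of averages; any failed trial marks the
    aggregate failed (abort evidence propagates)."""
    ok = [r for r in runs if not r.failed]
    failed = len(ok) < len(runs)
    if not ok:
        return StepStats(scheme=scheme, min_step=0.0, avg_step=0.0,
                         accepted_steps=0, failed=True)
    return StepStats(
        scheme=scheme,
        min_step=min(r.min_step for r in ok),
        avg_step=float(np.mean([r.avg_step for r in ok])),
        accepted_steps=sum(r.accepted_steps for r in ok),
        failed=failed,
    )


def stiffness_test(
    model: ModelSpec,
    h: float,
    tol: float,
    config: SpikeTrainConfig,
    beta: float = 6.0,
    *,
    shapes: list[Shape] | None = None,
) -> SolverRecommendation:
    """Run both schemes over all spike-train trials and classify.

    Deterministic given the configuration seed.
    """
    system = build_numeric_system(model, shapes=shapes)
    trains = generate_spike_trains(config, resolution=h)

    runs: dict[str, list[StepStats]] = {"explicit": [], "implicit": []}
    for train in trains:
        scaled = train  # weights enter via the increment vector
        for scheme in ("explicit", "implicit"):
            sys_scaled = NumericSystem(
                state_names=system.state_names,
                rhs=system.rhs,
                jac=system.jac,
                y0=system.y0,
                spike_increment=system.spike_increment * config.weight,
            )
            runs[scheme].append(
                integrate_adaptive(sys_scaled, scheme, scaled, h, tol,
                                   duration=config.duration)
            )

    expl = _aggregate(runs["explicit"], "explicit")
    impl = _aggregate(runs["implicit"], "implicit")
    if expl.failed and impl.failed and expl.accepted_steps == 0 and impl.accepted_steps == 0:
        raise StiffnessError("system cannot be integrated at this accuracy")
    return classify_stiffness(expl, impl, beta=beta)
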