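"""Reading, validating and writing model and solver documents.

A model document is JSON (or an equivalent mapping) with three sections:

``odes``
    list of ``{"symbol", "definition", "initial_values"}`` entries, each
    describing the right-hand side of a first-order state-variable ODE,
``shapes``
    list of ``{"type": "function"|"ode", "symbol", "definition",
    "initial_values"}`` entries describing postsynaptic shapes either as
    explicit functions of time or as linear ODEs with initial conditions,
``parameters``
    flat mapping of parameter names to default-value expressions.

Every free symbol appearing in a definition must be the time variable
``t``, a declared ODE/shape symbol (or a primed derivative of a shape
symbol), or a key of ``parameters``.

The module also hosts the command-line entry point which orchestrates the
full analysis pipeline: shape analysis, linearity classification, and
either the generation of an exact propagator-based update scheme or the
empirical stiffness test.
"""

from __future__ import annotations

import argparse
import json
import sys
from dataclasses import dataclass, field
from typing import Any, Mapping

import sympy as sp

from ._expr import (
    TIME,
    ExpressionError,
    derivative_order,
    derivative_symbol,
    expr_to_str,
    parse_expression,
)

__all__ = [
    "ValidationError",
    "OdeSpec",
    "ShapeSpec",
    "ModelSpec",
    "SolverRecommendation",
    "load_input",
    "write_output",
    "read_output",
    "analyse",
    "cli_main",
    "main",
]


class ValidationError(ValueError):
    """A document violates the model-input schema."""


_IDENT_RE_MSG = "nonempty identifier"


def _require_identifier(name: Any, where: str) -> str:
    if not isinstance(name, str) or not name.isidentifier():
        raise ValidationError(f"{where}: symbol must be a {_IDENT_RE_MSG}, got {name!r}")
    return name


@dataclass
class OdeSpec:
    """One state-variable ODE ``d/dt symbol = definition``."""

    symbol: str
    definition: sp.Expr
    initial_values: dict[str, sp.Expr] = field(default_factory=dict)

    def initial_value(self) -> sp.Expr:
        return self.initial_values.get(self.symbol, sp.Integer(0))


@dataclass
class ShapeSpec:
    """A postsynaptic shape, before canonicalization.

    ``form`` is ``"function"`` (definition is an explicit function of time)
    or ``"ode"`` (definition is the right-hand side of the highest-order
    derivative; ``initial_values`` maps derivative orders ``0..n-1`` to
    expressions, where ``n`` is the order of the shape ODE).
    """

    symbol: str
    form: str
    definition: sp.Expr
    initial_values: dict[int, sp.Expr] = field(default_factory=dict)

    @property
    def order(self) -> int:
        """Declared order (only meaningful for the ODE form)."""
        return len(self.initial_values)


@dataclass
class ModelSpec:
    """A fully parsed and validated model document."""

    odes: list[OdeSpec]
    shapes: list[ShapeSpec]
    parameters: dict[str, sp.Expr]

    def ode_symbols(self) -> list[str]:
        return [o.symbol for o in self.odes]

    def shape_symbols(self) -> list[str]:
        return [s.symbol for s in self.shapes]


@dataclass
class SolverRecommendation:
    """Outcome of the analysis: which solver to use, with evidence.

    ``scheme`` is one of ``analytical``, ``numeric-explicit``,
    ``numeric-implicit`` or ``warning``.  An analytical recommendation
    carries the serialized propagator scheme; a numeric one carries the
    step-size statistics that produced the decision.
    """

    scheme: str
    shape_summaries: list[dict] = field(default_factory=list)
    propagator: dict | None = None
    stiffness_evidence: dict | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("analytical", "numeric-explicit", "numeric-implicit", "warning"):
            raise ValidationError(f"unknown solver scheme {self.scheme!r}")
        if self.scheme == "analytical":
            if self.propagator is None:
                raise ValidationError("analytical recommendation requires a propagator")
        elif self.stiffness_evidence is None:
            raise ValidationError(f"{self.scheme} recommendation requires stiffness evidence")

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"solver": self.scheme, "shapes": self.shape_summaries}
        if self.propagator is not None:
            out["propagators"] = self.propagator["propagators"]
            out["update_instructions"] = self.propagator["update_instructions"]
            out["state"] = self.propagator["state"]
            out["spike_increments"] = self.propagator["spike_increments"]
        if self.stiffness_evidence is not None:
            out["stiffness"] = self.stiffness_evidence
        return out


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def _parse_shape_entry(entry: Mapping, index: int) -> ShapeSpec:
    where = f"shapes[{index}]"
    if not isinstance(entry, Mapping):
        raise ValidationError(f"{where}: expected a mapping")
    for key in ("type", "symbol", "definition"):
        if key not in entry:
            raise ValidationError(f"{where}: missing key: {key}")
    form = entry["type"]
    if form not in ("function", "ode"):
        raise ValidationError(f"{where}: type must be 'function' or 'ode', got {form!r}")
    symbol = _require_identifier(entry["symbol"], where)
    definition = parse_expression(entry["definition"], where=f"{where}.definition ({symbol})")
    initial_values: dict[int, sp.Expr] = {}
    if form == "ode":
        if "initial_values" not in entry or not entry["initial_values"]:
            raise ValidationError(f"{where} ({symbol}): missing key: initial_values")
        for key, value in entry["initial_values"].items():
            order = _initial_value_order(key, symbol, where)
            initial_values[order] = parse_expression(
                value, where=f"{where}.initial_values[{key}]"
            )
        n = len(initial_values)
        if sorted(initial_values) != list(range(n)):
            raise ValidationError(
                f"{where} ({symbol}): initial values must cover derivative orders 0..{n - 1}"
            )
    elif entry.get("initial_values"):
        raise ValidationError(
            f"{where} ({symbol}): function-form shapes take no initial values"
        )
    return ShapeSpec(symbol=symbol, form=form, definition=definition, initial_values=initial_values)


def _initial_value_order(key: Any, symbol: str, where: str) -> int:
    """Initial-value keys are derivative orders or primed symbol names."""
    if isinstance(key, int):
        return key
    text = str(key).strip()
    if text.isdigit():
        return int(text)
    # primed spelling ("g_ex''") or flat derivative spelling ("g_ex__d2")
    primes = len(text) - len(text.rstrip("'"))
    stripped = text.rstrip("'")
    if stripped == symbol:
        return primes
    base, order = derivative_order(stripped)
    if base == symbol and primes == 0:
        return order
    raise ValidationError(f"{where} ({symbol}): unrecognized initial-value key {key!r}")


def load_input(document: str | Mapping) -> ModelSpec:
    """Parse and validate a model document (JSON text or a mapping)."""
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as err:
            raise ValidationError(f"input is not valid JSON: {err}") from err
    if not isinstance(document, Mapping):
        raise ValidationError("input must be a JSON object or a mapping")
    for key in ("odes", "shapes", "parameters"):
        if key not in document:
            raise ValidationError(f"missing key: {key}")

    parameters: dict[str, sp.Expr] = {}
    if not isinstance(document["parameters"], Mapping):
        raise ValidationError("parameters: expected a mapping")
    for name, value in document["parameters"].items():
        _require_identifier(name, "parameters")
        parameters[name] = parse_expression(value, where=f"parameters[{name}]")

    odes: list[OdeSpec] = []
    for i, entry in enumerate(document["odes"]):
        where = f"odes[{i}]"
        if not isinstance(entry, Mapping):
            raise ValidationError(f"{where}: expected a mapping")
        for key in ("symbol", "definition"):
            if key not in entry:
                raise ValidationError(f"{where}: missing key: {key}")
        symbol = _require_identifier(entry["symbol"], where)
        definition = parse_expression(entry["definition"], where=f"{where}.definition ({symbol})")
        initial_values = {
            str(k): parse_expression(v, where=f"{where}.initial_values[{k}]")
            for k, v in entry.get("initial_values", {}).items()
        }
        odes.append(OdeSpec(symbol=symbol, definition=definition, initial_values=initial_values))

    if not isinstance(document["shapes"], (list, tuple)):
        raise ValidationError("shapes: expected a list")
    shapes = [_parse_shape_entry(e, i) for i, e in enumerate(document["shapes"])]

    spec = ModelSpec(odes=odes, shapes=shapes, parameters=parameters)
    _validate_symbols(spec)
    return spec


def _validate_symbols(spec: ModelSpec) -> None:
    names = spec.ode_symbols() + spec.shape_symbols()
    for name in names:
        if names.count(name) > 1:
            raise ValidationError(f"symbol {name!r} declared more than once")
    declared = set(names)
    params = set(spec.parameters)
    clash = declared & params
    if clash:
        raise ValidationError(f"symbols also declared as parameters: {sorted(clash)}")

    def check(expr: sp.Expr, where: str, *, allow_states: bool, shape: str | None = None):
        for free in expr.free_symbols:
            base, order = derivative_order(free)
            if free == TIME or base == str(TIME):
                continue
            if base in params:
                continue
            if shape is not None and base == shape:
                continue
            if allow_states and base in declared:
                continue
            raise ValidationError(f"{where}: unknown symbol: {base}")

    for ode in spec.odes:
        check(ode.definition, f"ode {ode.symbol}", allow_states=True)
        for value in ode.initial_values.values():
            check(value, f"ode {ode.symbol} initial value", allow_states=False)
    for sh in spec.shapes:
        if sh.form == "function":
            check(sh.definition, f"shape {sh.symbol}", allow_states=False)
        else:
            check(sh.definition, f"shape {sh.symbol}", allow_states=False, shape=sh.symbol)
            for value in sh.initial_values.values():
                check(value, f"shape {sh.symbol} initial value", allow_states=False)
    for name, value in spec.parameters.items():
        check(value, f"parameter {name}", allow_states=False)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_output(rec: SolverRecommendation, destination: str | None = None) -> str:
    """Serialize a recommendation to JSON text (optionally writing a file)."""
    text = json.dumps(rec.to_dict(), indent=2, sort_keys=True)
    if destination is not None:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def read_output(document: str | Mapping) -> SolverRecommendation:
    """Parse a solver document written by :func:`write_output`."""
    if isinstance(document, (str, bytes)):
        document = json.loads(document)
    scheme = document["solver"]
    propagator = None
    if "propagators" in document:
        propagator = {
            "propagators": document["propagators"],
            "update_instructions": document["update_instructions"],
            "state": document["state"],
            "spike_increments": document["spike_increments"],
        }
    return SolverRecommendation(
        scheme=scheme,
        shape_summaries=list(document.get("shapes", [])),
        propagator=propagator,
        stiffness_evidence=document.get("stiffness"),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _log(quiet: bool, message: str) -> None:
    if not quiet:
        print(f"[ode_analyzer] {message}", file=sys.stderr)


def analyse(
    model: ModelSpec,
    *,
    max_order: int = 10,
    accuracy: float = 1e-3,
    resolution: float = 0.1,
    trials: int = 5,
    seed: int = 0,
    beta: float = 6.0,
    spike_rate: float = 0.1,
    spike_weight: float = 1.0,
    duration: float = 20.0,
    force_numeric: bool = False,
    quiet: bool = False,
) -> SolverRecommendation:
    """Run the full analysis pipeline on a validated model.

    Shapes are first reduced to canonical linear-homogeneous form (an error
    is raised if any shape fails that test).  If every state ODE is a
    linear constant-coefficient equation driven only by shapes and
    parameter constants, an exact propagator-based update scheme is
    generated; otherwise the model is handed to the empirical stiffness
    test, which recommends an explicit or implicit adaptive integrator.
    """
    from . import analytic_solver, ode_classification, shape_analysis, stiffness

    shapes = []
    for spec in model.shapes:
        _log(quiet, f"analysing shape {spec.symbol} ({spec.form} form)")
        shapes.append(shape_analysis.analyse_shape(spec, max_order=max_order))
    summaries = [shape_analysis.shape_summary(s) for s in shapes]

    classified = [
        ode_classification.classify_ode(
            ode.symbol, ode.definition, shapes, state_symbols=model.ode_symbols()
        )
        for ode in model.odes
    ]
    for c in classified:
        _log(quiet, f"ode {c.symbol}: linear constant coefficient = {c.linear_constant_coefficient}")

    analytic = (
        not force_numeric
        and len(model.odes) == 1
        and classified[0].linear_constant_coefficient
        and analytic_solver.decomposes_linearly(classified[0], shapes, model.ode_symbols())
    )
    if analytic:
        _log(quiet, "generating analytical propagator scheme")
        scheme = analytic_solver.build_scheme(classified[0], shapes, model)
        return SolverRecommendation(
            scheme="analytical",
            shape_summaries=summaries,
            propagator=analytic_solver.serialize_scheme(scheme),
        )

    _log(quiet, "running stiffness test (explicit vs implicit adaptive integration)")
    config = stiffness.SpikeTrainConfig(
        rate=spike_rate, duration=duration, trials=trials, seed=seed, weight=spike_weight
    )
    rec = stiffness.stiffness_test(
        model, h=resolution, tol=accuracy, config=config, beta=beta, shapes=shapes
    )
    rec.shape_summaries = summaries
    return rec


# ---------------------------------------------------------------------------
# command line
# ---------------------------------------------------------------------------

def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="ode_analyzer",
        description=(
            "Classify a neuron-model ODE system and generate an exact "
            "propagator update scheme or recommend a numeric integrator."
        ),
    )
    parser.add_argument("input", help="path to the JSON model document")
    parser.add_argument("--output", help="write the solver document to this path")
    parser.add_argument("--max-order", type=int, default=10,
                        help="highest shape-ODE order to search for (default 10)")
    parser.add_argument("--accuracy", type=float, default=1e-3,
                        help="absolute accuracy for the stiffness-test integrators")
    parser.add_argument("--resolution", type=float, default=0.1,
                        help="grid resolution h for the stiffness test")
    parser.add_argument("--trials", type=int, default=5,
                        help="number of Poisson spike-train trials (default 5)")
    parser.add_argument("--seed", type=int, default=0, help="spike-train seed")
    parser.add_argument("--beta", type=float, default=6.0,
                        help="average-step-size ratio threshold (default 6)")
    parser.add_argument("--quiet", action="store_true", help="suppress diagnostics")
    return parser


def cli_main(argv: list[str] | None = None) -> int:
    """Entry point: ``ode_analyzer [stiffness] INPUT.json [options]``."""
    argv = list(sys.argv[1:] if argv is None else argv)
    force_numeric = False
    if argv and argv[0] == "stiffness":
        force_numeric = True
        argv = argv[1:]
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as err:
        return int(err.code or 0)
    try:
        with open(args.input, encoding="utf-8") as fh:
            model = load_input(fh.read())
        rec = analyse(
            model,
            max_order=args.max_order,
            accuracy=args.accuracy,
            resolution=args.resolution,
            trials=args.trials,
            seed=args.seed,
            beta=args.beta,
            force_numeric=force_numeric,
            quiet=args.quiet,
        )
    except (OSError, ValidationError, ExpressionError) as err:
        print(f"ode_analyzer: error: {err}", file=sys.stderr)
        return 1
    except Exception as err:  # shape/classification failures carry diagnostics
        print(f"ode_analyzer: error: {err}", file=sys.stderr)
        return 2
    text = write_output(rec, args.output)
    if args.output is None:
        print(text)
    else:
        _log(args.quiet, f"solver document written to {args.output}")
    return 0


def main() -> None:  # console-script shim
    raise SystemExit(cli_main())
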