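"""Reference models used throughout the tests and examples.

All fixtures are generated programmatically as model documents and loaded
through :func:`odeanalyzer.model_io.load_input`, so they double as schema
documentation.  The catalog covers the three routing outcomes:

``iaf_psc_alpha``
    current-based integrate-and-fire with an alpha-shaped postsynaptic
    current — linear constant coefficient, solved analytically.
``iaf_cond_alpha``
    conductance-based integrate-and-fire with one function-form and one
    ODE-form alpha conductance — the conductances multiply the membrane
    potential, so the coefficient is not constant and the model is
    integrated numerically (non-stiff at the default parameters).
``adex_cond_alpha``
    adaptive exponential integrate-and-fire — the exponential spike
    initiation term is non-linear; numeric branch regardless of parameters.
``fitzhugh_nagumo`` / ``morris_lecar``
    non-linear oscillator models whose stiffness depends on the grid
    resolution and parametrization.
``stiff_pair``
    the controlled stiff benchmark ``y1' = a*y1, y2' = -2*y2 + y1`` with
    ``a = -100`` and ``y1(0) = y2(0) = 1``, whose stiffness is dialled
    directly by ``a``.
"""

from __future__ import annotations

from typing import Mapping

from .model_io import ModelSpec, load_input

__all__ = ["FIXTURE_NAMES", "fixture_document", "make_fixture", "euler_reference"]


def _iaf_psc_alpha() -> dict:
    return {
        "odes": [
            {
                "symbol": "V",
                "definition": "-V/Tau + I/C",
                "initial_values": {"V": "0"},
            }
        ],
        "shapes": [
            {
                "type": "function",
                "symbol": "I",
                "definition": "exp(1)/tau_syn * t * exp(-t/tau_syn)",
            }
        ],
        "parameters": {"Tau": "10", "C": "250", "tau_syn": "2"},
    }


def _iaf_psc_alpha_bias() -> dict:
    doc = _iaf_psc_alpha()
    doc["odes"][0]["definition"] = "-V/Tau + I/C + I_e/C"
    doc["parameters"]["I_e"] = "100"
    return doc


def _iaf_cond_alpha() -> dict:
    return {
        "odes": [
            {
                "symbol": "V_m",
                "definition": (
                    "-(V_m - E_L)/Tau"
                    " + (g_ex*(E_ex - V_m) + g_in*(E_in - V_m) + I_e)/C"
                ),
                "initial_values": {"V_m": "E_L"},
            }
        ],
        "shapes": [
            {
                "type": "function",
                "symbol": "g_in",
                "definition": "exp(1)/tau_syn_in * t * exp(-t/tau_syn_in)",
            },
            {
                "type": "ode",
                "symbol": "g_ex",
                "definition": "-g_ex/tau_syn_ex**2 - 2*g_ex'/tau_syn_ex",
                "initial_values": {"g_ex": "0", "g_ex'": "exp(1)/tau_syn_ex"},
            },
        ],
        "parameters": {
            "Tau": "10",
            "C": "250",
            "E_L": "-70",
            "E_ex": "0",
            "E_in": "-85",
            "I_e": "0",
            "tau_syn_ex": "0.2",
            "tau_syn_in": "2",
            "V_th": "-55",
            "V_reset": "-60",
            "t_ref": "2",
            "g_L": "16.6667",
        },
    }


def _adex_cond_alpha() -> dict:
    # documented placeholder parameters; the routing (numeric) is
    # parameter-independent because of the exponential term
    return {
        "odes": [
            {
                "symbol": "V",
                "definition": (
                    "(E_L - V)/Tau + (g_ex*(E_ex - V)"
                    " + g*delta*exp((V - V_T)/delta) - w)/C"
                ),
                "initial_values": {"V": "E_L"},
            },
            {
                "symbol": "w",
                "definition": "c*(V - E_L)/tau_w - w/tau_w",
                "initial_values": {"w": "0"},
            },
        ],
        "shapes": [
            {
                "type": "function",
                "symbol": "g_ex",
                "definition": "exp(1)/tau_syn * t * exp(-t/tau_syn)",
            }
        ],
        "parameters": {
            "Tau": "9.37",
            "C": "281",
            "E_L": "-70.6",
            "E_ex": "0",
            "g": "30",
            "delta": "2",
            "V_T": "-50.4",
            "c": "4",
            "tau_w": "144",
            "tau_syn": "0.2",
        },
    }


def _fitzhugh_nagumo() -> dict:
    return {
        "odes": [
            {
                "symbol": "V",
                "definition": "V - V**3/3 - W + 0.25",
                "initial_values": {"V": "0"},
            },
            {
                "symbol": "W",
                "definition": "tau*(V + 0.7 - 0.8*W)",
                "initial_values": {"W": "0"},
            },
        ],
        "shapes": [],
        # recovery-variable rate -0.8*tau = -100: the same fast decay rate
        # as the controlled stiff pair, so the oscillator sits squarely in
        # the regime where the explicit/implicit trade-off is visible
        "parameters": {"tau": "125"},
    }


def _morris_lecar() -> dict:
    m = "(1 + tanh((V + 0.01)/0.15))/2"
    w_inf = "(1 + tanh((V + 0.12)/0.3))/2"
    lam = "cosh((V - 0.22)/(2*0.3))"
    return {
        "odes": [
            {
                "symbol": "V",
                "definition": (
                    f"I_inj + 2*W*(-0.7 - V) + 0.5*(-0.5 - V) + 1.1*({m})*(1 - V)"
                ),
                "initial_values": {"V": "-0.3"},
            },
            {
                "symbol": "W",
                "definition": f"alpha*({lam})*(({w_inf}) - W)",
                "initial_values": {"W": "0.1"},
            },
        ],
        "shapes": [],
        "parameters": {"I_inj": "0.07", "alpha": "1"},
    }


def _stiff_pair() -> dict:
    return {
        "odes": [
            {"symbol": "y1", "definition": "a*y1", "initial_values": {"y1": "1"}},
            {
                "symbol": "y2",
                "definition": "-2*y2 + y1",
                "initial_values": {"y2": "1"},
            },
        ],
        "shapes": [],
        "parameters": {"a": "-100"},
    }


_FACTORIES = {
    "iaf_psc_alpha": _iaf_psc_alpha,
    "iaf_psc_alpha_bias": _iaf_psc_alpha_bias,
    "iaf_cond_alpha": _iaf_cond_alpha,
    "adex_cond_alpha": _adex_cond_alpha,
    "fitzhugh_nagumo": _fitzhugh_nagumo,
    "morris_lecar": _morris_lecar,
    "stiff_pair": _stiff_pair,
}

FIXTURE_NAMES = tuple(sorted(_FACTORIES))


def fixture_document(name: str, overrides: Mapping[str, str] | None = None) -> dict:
    """Raw JSON-style document for a catalog model, with parameter overrides."""
    if name not in _FACTORIES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    doc = _FACTORIES[name]()
    for key, value in (overrides or {}).items():
        if key not in doc["parameters"]:
            raise KeyError(f"fixture {name!r} has no parameter {key!r}")
        doc["parameters"][key] = str(value)
    return doc


def make_fixture(name: str, overrides: Mapping[str, str] | None = None) -> ModelSpec:
    """Fully parameterized, validated model from the catalog."""
    return load_input(fixture_document(name, overrides))


def euler_reference(a: float, h: float, n: int) -> float:
    """Explicit-Euler amplification ``(1 + a*h)**n`` applied to initial value 1.

    The worked oracle for the stiff decay ``dy/dt = a*y``: with
    ``a = -100`` and ``h = 1/200`` the amplification per step is exactly
    ``1/2``, and a step ``h = 1/2`` gives the explosive factor ``-49``.
    """
    return (1.0 + a * h) ** n
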