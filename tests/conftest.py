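"""Shared helpers: reference trajectories via a high-accuracy adaptive
oracle, and small model documents used across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from odeanalyzer.model_io import ModelSpec
from odeanalyzer.stiffness import build_numeric_system


def reference_trajectory(
    model: ModelSpec,
    spike_times: np.ndarray,
    h: float,
    n_steps: int,
    weight: float = 1.0,
) -> tuple[list[str], np.ndarray]:
    """High-accuracy adaptive integration of a model on the spike grid.

    Independent of the propagator machinery: the model is lowered to a
    flat first-order system and integrated segment by segment with a
    tightly-toleranced embedded Runge-Kutta method, applying spike
    increments at their grid points (same event convention as the
    analytic evolution: a spike at t = k*h is added to the state at
    index k).  Returns (state names, trajectory of shape (n_steps+1, m)).
    """
    system = build_numeric_system(model)
    bins: dict[int, float] = {}
    for s in np.atleast_1d(spike_times):
        k = int(round(float(s) / h))
        bins[k] = bins.get(k, 0.0) + weight

    y = system.y0.copy()
    if 0 in bins:
        y = y + bins[0] * system.spike_increment
    trajectory = [y.copy()]
    for k in range(1, n_steps + 1):
        sol = solve_ivp(
            system.rhs,
            ((k - 1) * h, k * h),
            y,
            method="DOP853",
            rtol=1e-12,
            atol=1e-14,
        )
        y = sol.y[:, -1]
        if k in bins:
            y = y + bins[k] * system.spike_increment
        trajectory.append(y.copy())
    return system.state_names, np.asarray(trajectory)


@pytest.fixture
def minimal_document() -> dict:
    """Smallest well-formed model: leaky membrane driven by one shape."""
    return {
        "odes": [
            {"symbol": "V", "definition": "-V/Tau + I/C", "initial_values": {"V": "0"}}
        ],
        "shapes": [
            {"type": "function", "symbol": "I", "definition": "exp(-t/tau_syn)"}
        ],
        "parameters": {"Tau": "10", "C": "250", "tau_syn": "2"},
    }


@pytest.fixture
def two_shape_document() -> dict:
    """Current-based membrane with one alpha (order 2) and one exponential
    (order 1) postsynaptic current."""
    return {
        "odes": [
            {
                "symbol": "V",
                "definition": "-V/Tau + I1/C + I2/C",
                "initial_values": {"V": "0"},
            }
        ],
        "shapes": [
            {
                "type": "function",
                "symbol": "I1",
                "definition": "exp(1)/tau_1 * t * exp(-t/tau_1)",
            },
            {"type": "function", "symbol": "I2", "definition": "exp(-t/tau_2)"},
        ],
        "parameters": {"Tau": "10", "C": "250", "tau_1": "2", "tau_2": "5"},
    }
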