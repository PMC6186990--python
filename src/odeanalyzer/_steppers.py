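"""Semi-implicit extrapolation stepper (Bader-Deuflhard).

The implicit workhorse of the stiffness tester: the semi-implicit midpoint
rule of Bader and Deuflhard, accelerated by polynomial extrapolation in
the squared substep size, with adaptive step-size control.  The method is
A-stable at every extrapolation order, so its accepted steps on a stiff
problem are limited by accuracy (and by the grid interval), not by
stability -- exactly the contrast with an explicit embedded Runge-Kutta
pair that the step-size comparison exploits.

The implementation follows the classical formulation: over a macro step
``H`` split into ``m`` substeps of size ``hs = H/m`` (with the even
sequence m = 2, 6, 10, 14, 22),

    D_0 = (I - hs J)^{-1} hs f(y_0),              y_1 = y_0 + D_0
    D_k = D_{k-1} + 2 (I - hs J)^{-1} (hs f(y_k) - D_{k-1}),
    y_{k+1} = y_k + D_k,                          k = 1 .. m-1
    yhat = y_m + (I - hs J)^{-1} (hs f(y_m) - D_{m-1})      (smoothing)

where ``J`` is the Jacobian of ``f`` frozen at the step's start.  The
results for successive ``m`` are extrapolated; the difference between the
two highest extrapolation columns estimates the error.

The class mimics the small part of the ``scipy.integrate`` solver API the
stiffness tester uses (``step``, ``status``, ``t``, ``t_old``, ``y``,
``step_size``, ``h_abs``).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import lu_factor, lu_solve

__all__ = ["BaderDeuflhard"]

_SEQUENCE = (2, 6, 10, 14, 22)
_SAFETY = 0.9
_MIN_FACTOR = 0.02
_MAX_FACTOR = 4.0


class BaderDeuflhard:
    """Adaptive semi-implicit midpoint extrapolation integrator."""

    def __init__(
        self,
        fun,
        t0: float,
        y0: np.ndarray,
        t_bound: float,
        *,
        jac,
        rtol: float,
        atol: float,
        first_step: float | None = None,
    ) -> None:
        self.fun = fun
        self.jac = jac
        self.t = float(t0)
        self.t_old: float | None = None
        self.y = np.asarray(y0, dtype=float).copy()
        self.t_bound = float(t_bound)
        self.rtol = rtol
        self.atol = atol
        span = abs(self.t_bound - self.t)
        self.h_abs = span if first_step is None else min(float(first_step), span)
        self.status = "running" if span > 0 else "finished"

    # ------------------------------------------------------------------
    @property
    def step_size(self) -> float | None:
        if self.t_old is None:
            return None
        return abs(self.t - self.t_old)

    def step(self) -> str | None:
        if self.status != "running":
            raise RuntimeError("attempt to step on a non-running solver")
        success, message = self._step_impl()
        if not success:
            self.status = "failed"
            return message
        if self.t >= self.t_bound:
            self.status = "finished"
        return None

    # ------------------------------------------------------------------
    def _scale(self, y: np.ndarray) -> np.ndarray:
        return self.atol + self.rtol * np.abs(y)

    def _semi_implicit_midpoint(
        self, t: float, y: np.ndarray, h: float, m: int, J: np.ndarray
    ) -> np.ndarray | None:
        n = y.size
        hs = h / m
        try:
            lu = lu_factor(np.eye(n) - hs * J)
        except Exception:
            return None
        with np.errstate(all="ignore"):
            delta = lu_solve(lu, hs * self.fun(t, y))
            yk = y + delta
            for i in range(1, m):
                rhs = hs * self.fun(t + i * hs, yk) - delta
                delta = delta + 2.0 * lu_solve(lu, rhs)
                yk = yk + delta
            smoothing = lu_solve(lu, hs * self.fun(t + h, yk) - delta)
            result = yk + smoothing
        if not np.all(np.isfinite(result)):
            return None
        return result

    def _step_impl(self) -> tuple[bool, str]:
        t, y = self.t, self.y
        remaining = self.t_bound - t
        h = min(self.h_abs, remaining)
        min_step = 16 * np.finfo(float).eps * max(1.0, abs(t))
        scale = self._scale(y)
        J = np.asarray(self.jac(t, y), dtype=float)
        if not np.all(np.isfinite(J)):
            return False, "non-finite Jacobian"

        while True:
            if h < min_step or not np.isfinite(h):
                return False, "step size underflow"
            table: list[list[np.ndarray]] = []
            err = np.inf
            accepted_level = None
            failed_substep = False
            for k, m in enumerate(_SEQUENCE):
                yk = self._semi_implicit_midpoint(t, y, h, m, J)
                if yk is None:
                    failed_substep = True
                    break
                row = [yk]
                for j in range(1, k + 1):
                    ratio = (_SEQUENCE[k] / _SEQUENCE[k - j]) ** 2
                    row.append(
                        row[j - 1]
                        + (row[j - 1] - table[k - 1][j - 1]) / (ratio - 1.0)
                    )
                table.append(row)
                if k >= 1:
                    err_vec = (row[k] - row[k - 1]) / scale
                    err = float(np.sqrt(np.mean(err_vec**2)))
                    if np.isfinite(err) and err <= 1.0:
                        accepted_level = k
                        break
            if accepted_level is not None:
                y_new = table[accepted_level][accepted_level]
                order = 2 * accepted_level + 1
                factor = _SAFETY * err ** (-1.0 / (order + 1)) if err > 0 else _MAX_FACTOR
                factor = min(_MAX_FACTOR, max(_MIN_FACTOR, factor))
                self.t_old = t
                self.t = t + h
                self.y = y_new
                self.h_abs = h * factor
                return True, "accepted"
            # reject: shrink and retry
            if failed_substep or not np.isfinite(err):
                h *= 0.2
            else:
                order = 2 * len(_SEQUENCE) - 1
                factor = _SAFETY * err ** (-1.0 / (order + 1))
                h *= min(0.7, max(_MIN_FACTOR, factor))
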