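"""Shared ODE integration helpers: trajectories and settle-to-steady-state.

Thin wrappers over :func:`scipy.integrate.solve_ivp` (LSODA: adaptive,
stiffness-switching) that add the conventions used across the package:
states are clamped to the nonnegative orthant within solver tolerance, and
convergence is declared when the right-hand-side max-norm falls below a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConvergenceError

__all__ = ["SolverConfig", "Trajectory", "integrate", "settle"]


@dataclass(frozen=True)
class SolverConfig:
    """Integration and convergence tolerances.

    rtol/atol are passed to the adaptive integrator; ``conv_tol`` is the
    right-hand-side max-norm below which a state counts as converged (units:
    state units per time unit); ``clamp_tol`` is how far below zero a
    reported state may dip before being treated as a solver failure rather
    than round-off.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    conv_tol: float = 1e-6
    clamp_tol: float = 1e-6
    method: str = "LSODA"


@dataclass
class Trajectory:
    """A simulated time series of states with a convergence flag."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_dim)
    columns: tuple[str, ...]
    converged: bool
    final_rhs_norm: float

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "t", self.times)
        return df


def _clamped(rhs: Callable[[np.ndarray], np.ndarray]):
    # The model right-hand sides reject negative components; the adaptive
    # stepper may probe marginally below zero, so evaluate on the projection.
    def wrapped(t, y):
        return rhs(np.maximum(y, 0.0))

    return wrapped


def integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    y0: np.ndarray,
    horizon: float,
    columns: tuple[str, ...],
    config: SolverConfig | None = None,
    n_points: int = 200,
) -> Trajectory:
    """Integrate ``dy/dt = rhs(y)`` over ``[0, horizon]`` and record states.

    Raises :class:`ConvergenceError` (carrying the last valid state in its
    message) if the solver fails.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    cfg = config or SolverConfig()
    y0 = np.asarray(y0, dtype=float)
    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(
        _clamped(rhs), (0.0, horizon), y0, method=cfg.method,
        rtol=cfg.rtol, atol=cfg.atol, t_eval=t_eval,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else y0
        raise ConvergenceError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0:g}: "
            f"{sol.message}; last valid state {last.tolist()}"
        )
    states = sol.y.T
    if np.any(states < -cfg.clamp_tol):
        raise ConvergenceError(
            f"trajectory left the nonnegative orthant by more than "
            f"{cfg.clamp_tol:g}"
        )
    states = np.maximum(states, 0.0)
    final_norm = float(np.max(np.abs(rhs(states[-1]))))
    return Trajectory(
        times=sol.t,
        states=states,
        columns=columns,
        converged=final_norm < cfg.conv_tol,
        final_rhs_norm=final_norm,
    )


def settle(
    rhs: Callable[[np.ndarray], np.ndarray],
    y0: np.ndarray,
    horizon: float,
    config: SolverConfig | None = None,
    chunk: float | None = None,
) -> tuple[np.ndarray, bool]:
    """Integrate in chunks until the RHS norm converges or ``horizon`` runs out.

    Returns ``(final_state, converged)`` without storing the trajectory;
    used for basin-of-attraction mapping where only the endpoint matters.
    """
    cfg = config or SolverConfig()
    y = np.asarray(y0, dtype=float)
    if chunk is None:
        chunk = horizon / 20.0
    t = 0.0
    f = _clamped(rhs)
    while t < horizon:
        step = min(chunk, horizon - t)
        sol = solve_ivp(
            f, (0.0, step), y, method=cfg.method,
            rtol=cfg.rtol, atol=cfg.atol, t_eval=[step],
        )
        if not sol.success:
            raise ConvergenceError(
                f"integration failed near t={t:g}: {sol.message}"
            )
        y = np.maximum(sol.y[:, -1], 0.0)
        t += step
        if np.max(np.abs(rhs(y))) < cfg.conv_tol:
            return y, True
    return y, False
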