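"""Three-node thalamocortical firing-rate loop and its bifurcation analysis.

The model tracks the mean firing rates of the primary somatosensory cortex
(S), the thalamic reticular nucleus (T) and the thalamic ventroposterolateral
nucleus (V), coupled through Hill-type input-output curves:

    tau*dS/dt + theta*S = f1(b*V)
    tau*dT/dt + theta*T = f2(b*(V + S))
    tau*dV/dt + theta*V = g(a*T) * (b*S)^h / (fa(a*T)^h + (b*S)^h)

where f1, f2 are increasing Hill curves with maxima m1 (excitatory) and m2
(inhibitory), g is a decreasing Hill curve with maximum m1, and fa(a*T) =
e0 + (increasing m2-Hill of a*T).  GABAergic inhibition from TRN thus both
depresses the maximal VPL response (through g) and desensitizes it (through
the raised half-saturation fa).  The dimensionless couplings ``a``
(GABAergic strength), ``b`` (glutamatergic strength) and ``theta``
(self-limiting coefficient) all live in (0, 1].

For strong inhibition the loop is monostable with a low-firing-rate resting
state (the origin); below a critical GABAergic strength ``a_hat`` a
saddle-node fold creates an additional high-firing-rate stable state — the
putative chronic-pain regime.  This module locates equilibria by reducing
the steady state to a scalar problem in V, classifies them via Jacobian
eigenvalues, and finds ``a_hat(b, theta)`` by bisection on the count of
stable equilibria.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import SolverConfig, Trajectory, integrate, settle
from .errors import ConvergenceError, DomainError, ParameterError
from .hill import HillSpec
from .stability import Equilibrium, classify_stability, numerical_jacobian

__all__ = [
    "ThalamoParams",
    "ThalamoState",
    "BifurcationResult",
    "thalamo_rhs",
    "simulate",
    "find_equilibria",
    "count_stable",
    "bifurcation_point",
    "bifurcation_curve",
]


@dataclass(frozen=True)
class ThalamoParams:
    """Constants of the thalamocortical loop equations.

    tau : time constant, seconds.  m1/m2 : maximal excitatory/inhibitory
    firing rates, Hz.  e, e0 : half-saturation and basal half-saturation,
    Hz.  h : Hill coefficient.  a, b, theta : GABAergic strength,
    glutamatergic strength and self-limiting coefficient, each in (0, 1].
    """

    a: float = 0.3
    b: float = 1.0
    theta: float = 1.0
    tau: float = 0.5
    m1: float = 100.0
    m2: float = 80.0
    e: float = 20.0
    e0: float = 20.0
    h: float = 2.5

    def __post_init__(self) -> None:
        for name in ("a", "b", "theta", "tau", "m1", "m2", "e", "e0", "h"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("a", "b", "theta"):
            if getattr(self, name) > 1.0:
                raise ParameterError(f"{name} must not exceed 1")

    # The three Hill building blocks of the loop.
    @property
    def f1(self) -> HillSpec:  # VPL -> SSC excitation
        return HillSpec("increasing", m=self.m1, e=self.e, h=self.h)

    @property
    def f2(self) -> HillSpec:  # VPL+SSC -> TRN excitation
        return HillSpec("increasing", m=self.m2, e=self.e, h=self.h)

    @property
    def g(self) -> HillSpec:  # TRN inhibition depressing the VPL maximum
        return HillSpec("decreasing", m=self.m1, e=self.e, h=self.h)

    @property
    def fa(self) -> HillSpec:  # TRN inhibition raising the VPL half-saturation
        return HillSpec("increasing", m=self.m2, e=self.e, h=self.h, offset=self.e0)


@dataclass(frozen=True)
class ThalamoState:
    """Mean firing rates (Hz) of SSC (S), TRN (T) and VPL (V)."""

    S: float
    T: float
    V: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.T < 0 or self.V < 0:
            raise DomainError("firing rates must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.T, self.V], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ThalamoState":
        return cls(*(float(v) for v in arr))


def _rhs_array(y: np.ndarray, p: ThalamoParams) -> np.ndarray:
    S, T, V = y
    f1 = p.f1(p.b * V)
    f2 = p.f2(p.b * (V + S))
    g = p.g(p.a * T)
    fa = p.fa(p.a * T)
    bs = p.b * S
    drive = g * bs**p.h / (fa**p.h + bs**p.h) if bs > 0 else 0.0
    return np.array(
        [
            (f1 - p.theta * S) / p.tau,
            (f2 - p.theta * T) / p.tau,
            (drive - p.theta * V) / p.tau,
        ]
    )


def thalamo_rhs(state: ThalamoState, params: ThalamoParams) -> np.ndarray:
    """Time derivative (Hz/s) of the (S, T, V) firing-rate vector."""
    return _rhs_array(state.as_array(), params)


def simulate(
    initial: ThalamoState,
    params: ThalamoParams,
    horizon: float = 60.0,
    config: SolverConfig | None = None,
    n_points: int = 400,
) -> Trajectory:
    """Integrate the loop for ``horizon`` seconds from ``initial``.

    States are reported clamped to the nonnegative orthant (dips below zero
    beyond solver tolerance raise); the trajectory carries a ``converged``
    flag set when the final right-hand-side max-norm is below tolerance.
    """
    return integrate(
        lambda y: _rhs_array(y, params),
        initial.as_array(),
        horizon,
        columns=("S", "T", "V"),
        config=config,
        n_points=n_points,
    )


# --- Equilibrium enumeration -------------------------------------------------
#
# At steady state, S* = f1(bV*)/theta and T* = f2(b(V*+S*))/theta are explicit
# in V*, so the whole problem reduces to one scalar equation in V on
# [0, m1/theta].


def _steady_ST(V, p: ThalamoParams):
    S = p.f1(p.b * V) / p.theta
    T = p.f2(p.b * (V + S)) / p.theta
    return S, T


def _v_residual(V, p: ThalamoParams):
    S, T = _steady_ST(V, p)
    g = p.g(p.a * T)
    fa = p.fa(p.a * T)
    bs = p.b * np.asarray(S)
    with np.errstate(divide="ignore", invalid="ignore"):
        drive = np.where(
            bs > 0, g * bs**p.h / (fa**p.h + bs**p.h), 0.0
        )
    return drive - p.theta * np.asarray(V)


def find_equilibria(
    params: ThalamoParams,
    grid_points: int = 2001,
    refine: int = 10,
    dedup_tol: float = 1e-4,
    residual_tol: float = 1e-8,
) -> list[Equilibrium]:
    """Enumerate all steady states of the loop, classified by stability.

    Roots of the reduced scalar problem are bracketed on a dense V-grid
    (locally refined ``refine``-fold around sign changes), polished with a
    root finder, deduplicated within ``dedup_tol`` Hz, and classified via
    the eigenvalues of the full 3x3 Jacobian.  The origin is always an
    equilibrium (every Hill numerator vanishes) and is included explicitly.
    """
    p = params
    v_max = p.m1 / p.theta
    grid = np.linspace(0.0, v_max, grid_points)
    res = _v_residual(grid, p)

    roots: list[float] = [0.0]
    for i in range(len(grid) - 1):
        r0, r1 = res[i], res[i + 1]
        if r0 == 0.0 and grid[i] > 0:
            roots.append(float(grid[i]))
        elif r0 * r1 < 0:
            # refine the bracket before polishing, in case of clustered roots
            sub = np.linspace(grid[i], grid[i + 1], refine + 1)
            sres = _v_residual(sub, p)
            for j in range(len(sub) - 1):
                if sres[j] * sres[j + 1] < 0:
                    roots.append(
                        float(
                            brentq(
                                lambda v: float(_v_residual(v, p)),
                                sub[j],
                                sub[j + 1],
                                xtol=1e-12,
                            )
                        )
                    )
                elif sres[j] == 0.0 and sub[j] > 0:
                    roots.append(float(sub[j]))

    deduped: list[float] = []
    for v in sorted(roots):
        if not deduped or v - deduped[-1] > dedup_tol:
            deduped.append(v)

    out: list[Equilibrium] = []
    for v in deduped:
        S, T = _steady_ST(v, p)
        state = np.array([float(S), float(T), v])
        rhs = lambda y: _rhs_array(y, p)
        residual = float(np.max(np.abs(rhs(state))))
        if residual > residual_tol:
            raise ConvergenceError(
                f"equilibrium candidate V={v:g} has residual {residual:g}"
            )
        eig = np.linalg.eigvals(numerical_jacobian(rhs, state))
        out.append(
            Equilibrium(
                state=tuple(state),
                eigenvalues=tuple(eig),
                stability=classify_stability(eig),
                residual=residual,
            )
        )
    return out


def count_stable(params: ThalamoParams, **kwargs) -> int:
    """Number of stable equilibria at the given parameters."""
    return sum(eq.is_stable for eq in find_equilibria(params, **kwargs))


@dataclass(frozen=True)
class BifurcationResult:
    """Critical GABAergic strength ``a_hat`` at fixed (b, theta).

    The system is bistable (two stable states) for ``a`` just below
    ``a_hat`` and monostable just above; ``bracket`` is the final bisection
    interval, of width at most ``tol``.
    """

    a_hat: float
    b: float
    theta: float
    bracket: tuple[float, float]
    tol: float

    def to_dict(self) -> dict:
        return {
            "a_hat": self.a_hat,
            "b": self.b,
            "theta": self.theta,
            "bracket": list(self.bracket),
            "tol": self.tol,
        }


def bifurcation_point(
    b: float,
    theta: float = 1.0,
    params: ThalamoParams | None = None,
    tol: float = 1e-3,
    bracket: tuple[float, float] = (0.02, 0.6),
    **eq_kwargs,
) -> BifurcationResult:
    """Locate the saddle-node fold ``a_hat(b, theta)`` by bisection.

    Bisects the GABAergic strength ``a`` on the count of stable equilibria:
    at least two (bistable) at the lower bracket end, exactly one
    (monostable) at the upper.  Raises :class:`ConvergenceError` if the
    bracket does not straddle a regime change.
    """
    base = params or ThalamoParams()
    base = replace(base, b=b, theta=theta)

    def stable_at(a: float) -> int:
        return count_stable(replace(base, a=a), **eq_kwargs)

    lo, hi = bracket
    if not (0.0 < lo < hi <= 1.0):
        raise ParameterError("bracket must satisfy 0 < lo < hi <= 1")
    n_lo, n_hi = stable_at(lo), stable_at(hi)
    if not (n_lo >= 2 and n_hi == 1):
        raise ConvergenceError(
            f"no bifurcation in bracket [{lo}, {hi}]: stable counts "
            f"({n_lo}, {n_hi}); expected (>=2, 1)"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stable_at(mid) >= 2:
            lo = mid
        else:
            hi = mid
    return BifurcationResult(
        a_hat=0.5 * (lo + hi), b=b, theta=theta, bracket=(lo, hi), tol=tol
    )


def bifurcation_curve(
    b_values: Sequence[float],
    theta: float = 1.0,
    params: ThalamoParams | None = None,
    tol: float = 1e-3,
    bracket: tuple[float, float] = (0.02, 0.6),
) -> pd.DataFrame:
    """``a_hat`` across a grid of glutamatergic strengths ``b``.

    Grid points where no fold exists inside the bracket are flagged in the
    ``flag`` column ("no_bifurcation") rather than dropped, with NaN
    ``a_hat``.
    """
    rows = []
    for b in b_values:
        if not (0.0 < b <= 1.0):
            raise ParameterError(f"b={b} outside (0, 1]")
        try:
            res = bifurcation_point(b, theta, params=params, tol=tol, bracket=bracket)
            rows.append(
                {"b": b, "theta": theta, "a_hat": res.a_hat, "flag": "ok"}
            )
        except ConvergenceError:
            rows.append(
                {"b": b, "theta": theta, "a_hat": np.nan, "flag": "no_bifurcation"}
            )
    return pd.DataFrame(rows)


def settle_state(
    initial: ThalamoState,
    params: ThalamoParams,
    horizon: float = 200.0,
    config: SolverConfig | None = None,
) -> tuple[ThalamoState, bool]:
    """Endpoint-only integration to (near) steady state; returns (state, converged)."""
    y, ok = settle(
        lambda y: _rhs_array(y, params), initial.as_array(), horizon, config=config
    )
    return ThalamoState.from_array(y), ok
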