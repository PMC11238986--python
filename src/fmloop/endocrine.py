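"""Mutually inhibitory HPG-HPA endocrine loop: equilibria and basins.

Each axis (hypothalamus-pituitary-adrenocortical and -gonadal) is condensed
into one activity variable on a 0-100 scale, e.g. proxied by plasma
cortisol (HPA) and progesterone (HPG).  Each axis is inhibited by the other
(a decreasing Hill curve f, significant at high hormone levels) and limits
itself (a state-dependent decay factor k):

    tau * dHPA/dt = f(HPG) - k(HPA) * HPA
    tau * dHPG/dt = f(HPA) - k(HPG) * HPG

with f(x) = 100/(1 + (x/e_x)^h_x) in (0, 100] and k(x) = 1 +
4/(1 + (alpha*x/e_k)^h_k) in (1, 5].  Both axes share identical parameters,
so the vector field commutes with coordinate exchange.  At the default
parameters the system is tristable: a symmetric low-low state (both axes at
modest circadian activity) and an asymmetric pair where one axis dominates
and suppresses the other — the high-HPA/low-HPG member being the putative
pathogenic condition.

Equilibria are found by a scalar root scan on the diagonal plus multi-start
2-D root finding, and basins of attraction by labelling a grid of initial
conditions with the equilibrium each trajectory reaches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .dynamics import SolverConfig, Trajectory, integrate, settle
from .errors import ConvergenceError, DomainError, ParameterError
from .hill import shifted_self_limit
from .stability import Equilibrium, classify_stability, numerical_jacobian

__all__ = [
    "EndocrineParams",
    "EndocrineState",
    "BasinMap",
    "endocrine_rhs",
    "find_equilibria_endocrine",
    "simulate_endocrine",
    "basin_map",
]


@dataclass(frozen=True)
class EndocrineParams:
    """Constants of the HPG-HPA loop equations (identical for both axes).

    e_x, h_x : half-saturation (activity units) and Hill coefficient of the
    mutual inhibition.  e_k, h_k, alpha : half-saturation, Hill coefficient
    and modulation factor (in (0,1)) of the self-limiting term.  tau : time
    constant in minutes.
    """

    e_x: float = 28.0
    h_x: float = 4.2
    e_k: float = 25.57
    h_k: float = 6.6
    alpha: float = 0.48
    tau: float = 30.0

    def __post_init__(self) -> None:
        for name in ("e_x", "h_x", "e_k", "h_k", "tau"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must lie strictly inside (0, 1)")

    def f(self, x):
        """Mutual-inhibition response, decreasing from 100 toward 0."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise DomainError("axis activity must be nonnegative")
        out = 100.0 / (1.0 + (x / self.e_x) ** self.h_x)
        return out if out.ndim else float(out)

    def k(self, x):
        """Self-limiting decay factor, decreasing from 5 toward 1."""
        return shifted_self_limit(x, self.e_k, self.h_k, self.alpha)


@dataclass(frozen=True)
class EndocrineState:
    """Activities of the two axes on a 0-100 scale."""

    HPA: float
    HPG: float

    def __post_init__(self) -> None:
        if self.HPA < 0 or self.HPG < 0:
            raise DomainError("axis activities must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.HPA, self.HPG], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "EndocrineState":
        return cls(*(float(v) for v in arr))


def _rhs_array(y: np.ndarray, p: EndocrineParams) -> np.ndarray:
    hpa, hpg = y
    return np.array(
        [
            (p.f(hpg) - p.k(hpa) * hpa) / p.tau,
            (p.f(hpa) - p.k(hpg) * hpg) / p.tau,
        ]
    )


def endocrine_rhs(state: EndocrineState, params: EndocrineParams) -> np.ndarray:
    """Time derivative (activity units per minute) of (HPA, HPG)."""
    return _rhs_array(state.as_array(), params)


def find_equilibria_endocrine(
    params: EndocrineParams | None = None,
    grid_points: int = 25,
    diag_points: int = 2001,
    dedup_tol: float = 1e-4,
    residual_tol: float = 1e-8,
    box: float = 100.0,
) -> list[Equilibrium]:
    """Enumerate steady states of the endocrine loop, classified by stability.

    Two complementary searches: (i) on the diagonal HPA = HPG = x the
    problem reduces to the scalar equation f(x) = k(x)*x, scanned densely
    and bracketed; (ii) a multi-start 2-D Newton-type root search from a
    grid over [0, box]^2 picks up the asymmetric states.  Results are
    deduplicated within ``dedup_tol`` and classified by Jacobian
    eigenvalues.  The equilibrium set is closed under coordinate exchange
    by construction of the symmetric vector field; any root found has its
    mirror added explicitly so round-off cannot break the pairing.
    """
    p = params or EndocrineParams()
    rhs = lambda y: _rhs_array(y, p)

    roots: list[np.ndarray] = []

    def push(y: np.ndarray) -> None:
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        if np.max(np.abs(rhs(y))) > residual_tol:
            return
        for known in roots:
            if np.max(np.abs(known - y)) <= dedup_tol:
                return
        roots.append(y)

    # (i) diagonal scan: f(x) - k(x)*x = 0
    def diag_res(x):
        return p.f(x) - p.k(x) * x

    xs = np.linspace(0.0, box, diag_points)
    rs = np.array([diag_res(x) for x in xs])
    for i in range(len(xs) - 1):
        if rs[i] == 0.0:
            push(np.array([xs[i], xs[i]]))
        elif rs[i] * rs[i + 1] < 0:
            x0 = brentq(diag_res, xs[i], xs[i + 1], xtol=1e-13)
            push(np.array([x0, x0]))

    # (ii) multi-start 2-D root finding off the diagonal; the search may
    # probe outside the orthant, so it sees the field on the projection
    search_rhs = lambda y: _rhs_array(np.maximum(y, 0.0), p)
    starts = np.linspace(0.0, box, grid_points)
    for u in starts:
        for v in starts:
            sol = root(search_rhs, np.array([u, v]), method="hybr", tol=1e-12)
            if sol.success and np.all(sol.x > -dedup_tol):
                push(sol.x)
                push(sol.x[::-1])  # exchange symmetry: mirror must be a root too

    out: list[Equilibrium] = []
    for y in sorted(roots, key=lambda r: (r[0], r[1])):
        residual = float(np.max(np.abs(rhs(y))))
        eig = np.linalg.eigvals(numerical_jacobian(rhs, y))
        out.append(
            Equilibrium(
                state=tuple(float(c) for c in y),
                eigenvalues=tuple(eig),
                stability=classify_stability(eig),
                residual=residual,
            )
        )
    return out


def simulate_endocrine(
    initial: EndocrineState,
    params: EndocrineParams | None = None,
    horizon: float = 2000.0,
    config: SolverConfig | None = None,
    n_points: int = 400,
    capture_radius: float = 0.5,
    equilibria: Sequence[Equilibrium] | None = None,
) -> tuple[Trajectory, int | None]:
    """Integrate the loop for ``horizon`` minutes and identify the attractor.

    Returns the trajectory and the index (into the stable members of
    ``equilibria``, or of a fresh enumeration) of the equilibrium whose
    capture radius contains the endpoint; ``None`` if unresolved.
    """
    p = params or EndocrineParams()
    traj = integrate(
        lambda y: _rhs_array(y, p),
        initial.as_array(),
        horizon,
        columns=("HPA", "HPG"),
        config=config,
        n_points=n_points,
    )
    eqs = list(equilibria) if equilibria is not None else find_equilibria_endocrine(p)
    stable = [eq for eq in eqs if eq.is_stable]
    label = _nearest_label(traj.final_state, stable, capture_radius)
    return traj, label


def _nearest_label(
    y: np.ndarray, stable: Sequence[Equilibrium], capture_radius: float
) -> int | None:
    best, best_d = None, np.inf
    for i, eq in enumerate(stable):
        d = float(np.linalg.norm(y - np.asarray(eq.state)))
        if d < best_d:
            best, best_d = i, d
    return best if best_d <= capture_radius else None


@dataclass
class BasinMap:
    """Grid labelling of basins of attraction.

    ``labels[i, j]`` is the index into ``stable_equilibria`` of the
    attractor reached from initial condition (hpa_grid[i], hpg_grid[j]), or
    -1 for unresolved points.  ``fractions`` are basin areas as grid
    fractions.
    """

    hpa_grid: np.ndarray
    hpg_grid: np.ndarray
    labels: np.ndarray
    stable_equilibria: list[Equilibrium]
    fractions: dict[int, float]
    unresolved_fraction: float

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(
            range(len(self.hpa_grid)), range(len(self.hpg_grid)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "HPA0": self.hpa_grid[ii.ravel()],
                "HPG0": self.hpg_grid[jj.ravel()],
                "label": self.labels.ravel(),
            }
        )


def basin_map(
    params: EndocrineParams | None = None,
    resolution: int = 101,
    horizon: float = 1e4,
    config: SolverConfig | None = None,
    capture_radius: float = 0.5,
    box: float = 100.0,
) -> BasinMap:
    """Label a ``resolution x resolution`` grid over [0, box]^2 by attractor.

    Each grid point is integrated (endpoint only, in convergence-checked
    chunks) until its trajectory settles, then assigned to the stable
    equilibrium within ``capture_radius`` of the endpoint; points that do
    not resolve within ``horizon`` minutes are labelled -1.
    """
    p = params or EndocrineParams()
    eqs = find_equilibria_endocrine(p)
    stable = [eq for eq in eqs if eq.is_stable]
    if not stable:
        raise ConvergenceError("no stable equilibria: nothing to map")
    grid = np.linspace(0.0, box, resolution)
    labels = np.full((resolution, resolution), -1, dtype=int)
    cfg = config or SolverConfig()
    for i, hpa0 in enumerate(grid):
        for j, hpg0 in enumerate(grid):
            y, ok = settle(
                lambda y: _rhs_array(y, p),
                np.array([hpa0, hpg0]),
                horizon,
                config=cfg,
                chunk=20.0 * p.tau,
            )
            if ok:
                lab = _nearest_label(y, stable, capture_radius)
                labels[i, j] = -1 if lab is None else lab
    n = labels.size
    fractions = {
        k: float(np.count_nonzero(labels == k)) / n for k in range(len(stable))
    }
    return BasinMap(
        hpa_grid=grid,
        hpg_grid=grid,
        labels=labels,
        stable_equilibria=stable,
        fractions=fractions,
        unresolved_fraction=float(np.count_nonzero(labels < 0)) / n,
    )
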