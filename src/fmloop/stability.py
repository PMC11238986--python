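"""Equilibrium bookkeeping shared by the dynamical-system modules.

Houses the ``Equilibrium`` container, finite-difference Jacobians and the
eigenvalue-based stability classification used by both the thalamocortical
and the endocrine loop models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "Equilibrium",
    "numerical_jacobian",
    "classify_stability",
    "STABILITY_EIG_TOL",
]

# An eigenvalue real part within +/- this band is treated as "marginal":
# neither stable nor unstable.  Keeps bisection on stable-equilibrium counts
# from flickering right at a fold.
STABILITY_EIG_TOL = 1e-6

Stability = Literal["stable", "saddle", "unstable", "marginal"]


@dataclass(frozen=True)
class Equilibrium:
    """A located steady state of an ODE system.

    Attributes
    ----------
    state : tuple of float
        The steady-state vector.
    eigenvalues : tuple of complex
        Spectrum of the Jacobian at the state.
    stability : {"stable", "saddle", "unstable", "marginal"}
        Classification from the eigenvalue real parts.
    residual : float
        Max-norm of the right-hand side at the state.
    """

    state: tuple[float, ...]
    eigenvalues: tuple[complex, ...]
    stability: Stability
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    def to_dict(self) -> dict:
        return {
            "state": list(self.state),
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "stability": self.stability,
            "residual": self.residual,
        }


def numerical_jacobian(
    rhs: Callable[[np.ndarray], np.ndarray],
    state: Sequence[float],
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central-difference Jacobian of ``rhs`` at ``state``.

    Steps are kept inside the nonnegative orthant (a one-sided forward
    difference is used where a centered step would go negative), since the
    model right-hand sides reject negative components.
    """
    state = np.asarray(state, dtype=float)
    n = state.size
    J = np.empty((n, n))
    for j in range(n):
        dx = rel_step * max(1.0, abs(state[j]))
        hi = state.copy()
        lo = state.copy()
        hi[j] += dx
        lo[j] -= dx
        if lo[j] < 0.0:
            lo = state.copy()  # forward difference at the boundary
        J[:, j] = (rhs(hi) - rhs(lo)) / (hi[j] - lo[j])
    return J


def classify_stability(
    eigenvalues: np.ndarray, eig_tol: float = STABILITY_EIG_TOL
) -> Stability:
    """Label a steady state from the real parts of its eigenvalues.

    stable: all real parts < -eig_tol; unstable: all > +eig_tol; saddle:
    mixed signs; marginal: any real part within the +/- eig_tol band
    (excluded from stable counts to avoid flicker at bifurcations).
    """
    re = np.real(np.asarray(eigenvalues))
    if np.any(np.abs(re) <= eig_tol):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"
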