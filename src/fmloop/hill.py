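"""Hill-function primitives, dose-response normalization and fitting.

The Hill equation is the saturating input-output law used throughout this
package for neuronal input-output curves, neurosteroid dose-response data
and endocrine interactions alike:

    increasing form:  y = offset + m * x**h / (e**h + x**h)
    decreasing form:  y = offset + m / (1 + (x/e)**h)

with ``m`` the response span, ``e`` the half-saturation constant (EC50),
``h`` the Hill coefficient (cooperativity) and an optional additive
``offset``.  At ``x = e`` both forms return ``offset + m/2``.

The module also provides the shifted self-limiting form ``1 + 4/(1 +
(alpha*x/e)**h)`` used by the endocrine feedback model, bounded in (1, 5],
a bounded multi-start least-squares fitter for noisy dose-response tables,
and per-field median aggregation of fitted parameter records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, FitError, ParameterError

Direction = Literal["increasing", "decreasing"]

__all__ = [
    "HillSpec",
    "DoseResponseTable",
    "HillFit",
    "hill_increasing",
    "hill_decreasing",
    "shifted_self_limit",
    "normalize_columns",
    "fit_hill",
    "aggregate_medians",
]


@dataclass(frozen=True)
class HillSpec:
    """Parameters of one Hill response curve.

    Attributes
    ----------
    direction : {"increasing", "decreasing"}
        Whether the response rises or falls with the input.
    m : float
        Maximal response span (units of the response), > 0.
    e : float
        Half-saturation constant (units of the input), > 0.
    h : float
        Hill coefficient, dimensionless, > 0.
    offset : float
        Constant added to the response, >= 0 (default 0).
    """

    direction: Direction
    m: float
    e: float
    h: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing"):
            raise ParameterError(f"unknown direction {self.direction!r}")
        if not (self.m > 0 and self.e > 0 and self.h > 0):
            raise ParameterError("m, e and h must all be strictly positive")
        if self.offset < 0:
            raise ParameterError("offset must be nonnegative")

    def __call__(self, x):
        if self.direction == "increasing":
            return hill_increasing(x, self)
        return hill_decreasing(x, self)


@dataclass
class DoseResponseTable:
    """A dose-response data table: rows of (input, output) observations.

    ``inputs`` are concentrations or standardized 0-100 levels; ``outputs``
    are responses, standardized 0-100 when normalized.  Carries unit and
    source metadata so fitted parameters stay traceable.
    """

    inputs: np.ndarray
    outputs: np.ndarray
    input_units: str = ""
    output_units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.inputs.shape != self.outputs.shape or self.inputs.ndim != 1:
            raise DomainError("inputs and outputs must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.inputs)) or not np.all(np.isfinite(self.outputs)):
            raise DomainError("dose-response values must be finite")
        if np.any(self.inputs < 0):
            raise DomainError("dose-response inputs must be nonnegative")

    def __len__(self) -> int:
        return len(self.inputs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"input": self.inputs, "output": self.outputs, "label": self.label}
        )

    @classmethod
    def from_csv(cls, path) -> "DoseResponseTable":
        df = pd.read_csv(path)
        label = str(df["label"].iloc[0]) if "label" in df and len(df) else ""
        return cls(df["input"].to_numpy(), df["output"].to_numpy(), label=label)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_nonnegative(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DomainError("Hill functions are defined for nonnegative inputs only")
    return arr


def hill_increasing(x, spec: HillSpec):
    """Evaluate the increasing Hill form ``offset + m*x^h/(e^h + x^h)``.

    ``0**h`` is taken as 0 for every ``h > 0`` (the continuous limit), so the
    curve passes through ``offset`` at the origin without producing NaN.
    """
    arr = _as_nonnegative(x)
    with np.errstate(divide="ignore"):
        ratio = (arr / spec.e) ** spec.h
    out = spec.offset + spec.m * np.where(arr > 0, ratio / (1.0 + ratio), 0.0)
    return out if out.ndim else float(out)


def hill_decreasing(x, spec: HillSpec):
    """Evaluate the decreasing Hill form ``offset + m/(1 + (x/e)^h)``."""
    arr = _as_nonnegative(x)
    out = spec.offset + spec.m / (1.0 + (arr / spec.e) ** spec.h)
    return out if out.ndim else float(out)


def shifted_self_limit(x, e_k: float, h_k: float, alpha: float):
    """Shifted decreasing Hill form ``1 + 4/(1 + (alpha*x/e_k)^h_k)``.

    Models a state-dependent decay factor: approaches 5 as ``x`` tends to
    zero (self-limitation dominates) and 1 as ``x`` tends to infinity
    (mutual inhibition dominates).  ``alpha`` in (0, 1) modulates how fast
    the transition happens.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must lie strictly inside (0, 1)")
    if e_k <= 0 or h_k <= 0:
        raise ParameterError("e_k and h_k must be strictly positive")
    arr = _as_nonnegative(x)
    out = 1.0 + 4.0 / (1.0 + (alpha * arr / e_k) ** h_k)
    return out if out.ndim else float(out)


def normalize_columns(table: DoseResponseTable) -> DoseResponseTable:
    """Rescale inputs and outputs so each column spans 0-100 (min->0, max->100).

    A constant column cannot be rescaled; that is reported as a fit failure
    rather than silently passed through.
    """
    lo_x, hi_x = table.inputs.min(), table.inputs.max()
    lo_y, hi_y = table.outputs.min(), table.outputs.max()
    if hi_x == lo_x or hi_y == lo_y:
        raise FitError("cannot normalize a constant column to the 0-100 scale")
    return DoseResponseTable(
        100.0 * (table.inputs - lo_x) / (hi_x - lo_x),
        100.0 * (table.outputs - lo_y) / (hi_y - lo_y),
        input_units="% of range",
        output_units="% of range",
        label=table.label,
    )


@dataclass(frozen=True)
class HillFit:
    """Result of a least-squares Hill fit with diagnostics."""

    spec: HillSpec
    rss: float
    n: int
    n_free: int
    p_monotone: float
    normalized: bool
    starts_tried: int = 0

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.rss / self.n))


def _hill_model(x, direction: Direction, m, e, h, offset):
    spec = HillSpec(direction=direction, m=m, e=e, h=h, offset=offset)
    return spec(x)


def fit_hill(
    table: DoseResponseTable,
    direction: Direction,
    normalize: bool = True,
    fix_m: float | None = None,
    fix_offset: float | None = 0.0,
    h_bounds: tuple[float, float] = (0.5, 20.0),
) -> HillFit:
    """Fit a Hill curve to a dose-response table by bounded least squares.

    The fit is run from a grid of starting values (``e`` at the data
    quartiles, ``h`` in {1, 2, 4, 8}); the start with the smallest residual
    sum of squares wins, ties broken by the smaller Hill coefficient.  By
    default the offset is fixed at 0 and ``m`` is free; either can be fixed
    via ``fix_m`` / ``fix_offset`` (pass ``None`` to free the offset).

    Returns a :class:`HillFit` whose diagnostics include the residual sum
    of squares and the Spearman rank-correlation p-value of the monotone
    association (reported, never used as a gate).

    Raises
    ------
    FitError
        If the table has fewer rows than free parameters, the outputs are
        constant, or the data trend contradicts the requested direction.
    """
    if len(table) < 3:
        raise FitError("at least 3 rows are required to fit a Hill curve")
    if normalize:
        table = normalize_columns(table)
    x, y = table.inputs, table.outputs

    if np.allclose(y, y[0]):
        raise FitError("outputs are constant; no dose-response relation to fit")

    rho, p_monotone = stats.spearmanr(x, y)
    want = 1.0 if direction == "increasing" else -1.0
    if np.isfinite(rho) and rho * want < 0:
        raise FitError(
            f"data trend (spearman rho={rho:.3f}) contradicts the requested "
            f"{direction} direction"
        )

    free = ["e", "h"]
    if fix_m is None:
        free.append("m")
    if fix_offset is None:
        free.append("offset")
    if len(table) < len(free):
        raise FitError(
            f"{len(table)} rows cannot constrain {len(free)} free parameters"
        )

    span = float(y.max() - y.min())
    m0 = fix_m if fix_m is not None else max(span, 1e-12)
    off0 = fix_offset if fix_offset is not None else float(y.min())
    x_pos = x[x > 0]
    if x_pos.size == 0:
        raise FitError("all inputs are zero; half-saturation is unidentifiable")
    e_starts = np.unique(np.quantile(x_pos, [0.25, 0.5, 0.75]))
    h_starts = (1.0, 2.0, 4.0, 8.0)

    lb, ub = [], []
    for name in free:
        if name == "e":
            lb.append(x_pos.min() * 1e-3)
            ub.append(x.max() * 1e3)
        elif name == "h":
            lb.append(h_bounds[0])
            ub.append(h_bounds[1])
        elif name == "m":
            lb.append(1e-9)
            ub.append(10.0 * max(abs(y).max(), 1.0))
        else:  # offset
            lb.append(0.0)
            ub.append(max(abs(y).max(), 1.0))

    def unpack(theta) -> dict:
        vals = {"m": m0, "offset": off0}
        for name, v in zip(free, theta):
            vals[name] = v
        return vals

    def residuals(theta):
        v = unpack(theta)
        return _hill_model(x, direction, v["m"], v["e"], v["h"], v["offset"]) - y

    best = None
    tried = 0
    for e0 in e_starts:
        for h0 in h_starts:
            theta0 = []
            for name in free:
                theta0.append(
                    {"e": e0, "h": h0, "m": m0, "offset": off0}[name]
                )
            theta0 = np.clip(theta0, lb, ub)
            try:
                sol = optimize.least_squares(
                    residuals, theta0, bounds=(lb, ub), method="trf", xtol=1e-14,
                    ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            tried += 1
            rss = float(2.0 * sol.cost)
            v = unpack(sol.x)
            if (
                best is None
                or rss < best[0] - 1e-12
                or (abs(rss - best[0]) <= 1e-12 and v["h"] < best[1]["h"])
            ):
                best = (rss, v)
    if best is None:
        raise FitError("no least-squares start converged")

    rss, v = best
    spec = HillSpec(
        direction=direction, m=v["m"], e=v["e"], h=v["h"], offset=v["offset"]
    )
    return HillFit(
        spec=spec,
        rss=rss,
        n=len(table),
        n_free=len(free),
        p_monotone=float(p_monotone),
        normalized=normalize,
        starts_tried=tried,
    )


def aggregate_medians(records: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Per-field sample medians over a sequence of parameter records.

    Missing fields (absent keys or NaN values) are skipped per field; the
    median of an even count is the midpoint of the two central order
    statistics.  Raises on empty input.
    """
    if len(records) == 0:
        raise ParameterError("cannot aggregate an empty sequence of records")
    keys: list[str] = []
    for rec in records:
        for k in rec:
            if k not in keys:
                keys.append(k)
    out: dict[str, float] = {}
    for k in keys:
        vals = [
            float(rec[k])
            for rec in records
            if k in rec and rec[k] is not None and np.isfinite(float(rec[k]))
        ]
        if vals:
            out[k] = float(np.median(vals))
    return out
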