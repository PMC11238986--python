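"""Packaged reference tables and a synthetic dose-response generator.

The small literature-derived tables that parameterize the models (steroid
concentration anchors, Hill-fit parameter collections, endocrine-loop
constants) ship inside the package as plain CSV, with a JSON sidecar for
column units, so every module is testable offline.  A seeded generator
produces synthetic Hill-curve dose-response tables with Gaussian noise for
fit-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hill import DoseResponseTable, HillSpec

__all__ = ["ReferenceTable", "available_tables", "load_table", "synth_dose_response"]

_TABLE_IDS = ("t002", "t003", "t004", "t005", "t006")


@dataclass(frozen=True)
class ReferenceTable:
    """A packaged literature-derived table: rows as published, plus column units."""

    table_id: str
    data: pd.DataFrame
    units: dict[str, str]

    def experimental(self) -> pd.DataFrame:
        """Rows excluding any summary/median row, where the table has one."""
        if "is_median" in self.data.columns:
            return self.data[~self.data["is_median"]].drop(columns="is_median")
        return self.data

    def median_row(self) -> pd.Series:
        if "is_median" not in self.data.columns:
            raise ParameterError(f"table {self.table_id} has no median row")
        return self.data[self.data["is_median"]].iloc[0]


def available_tables() -> tuple[str, ...]:
    return _TABLE_IDS


def load_table(table_id: str) -> ReferenceTable:
    """Load a packaged table by id (see :func:`available_tables`)."""
    if table_id not in _TABLE_IDS:
        raise ParameterError(
            f"unknown table {table_id!r}; available: {', '.join(_TABLE_IDS)}"
        )
    pkg = resources.files("fmloop.data")
    with resources.as_file(pkg / f"{table_id}.csv") as path:
        df = pd.read_csv(path)
    with resources.as_file(pkg / "units.json") as path:
        units = json.loads(path.read_text())
    return ReferenceTable(table_id=table_id, data=df, units=units.get(table_id, {}))


def synth_dose_response(
    spec: HillSpec,
    n: int = 12,
    noise_sd: float = 0.0,
    seed: int | None = None,
    x_range: tuple[float, float] | None = None,
) -> DoseResponseTable:
    """Generate a synthetic dose-response table from a Hill curve.

    Inputs are log-spaced over ``[e/10, 10e]`` (overridable); outputs are
    the Hill response plus i.i.d. Gaussian noise with standard deviation
    ``noise_sd`` in response units.  The seed is recorded in the table
    label so the fixture is reproducible.
    """
    if n < 3:
        raise ParameterError("at least 3 points are required")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")
    lo, hi = x_range if x_range is not None else (spec.e / 10.0, 10.0 * spec.e)
    x = np.logspace(np.log10(lo), np.log10(hi), n)
    y = np.asarray(spec(x), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return DoseResponseTable(
        x,
        y,
        label=(
            f"synthetic {spec.direction} Hill e={spec.e:g} h={spec.h:g} "
            f"m={spec.m:g} sd={noise_sd:g} seed={seed}"
        ),
    )
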