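"""From station-level daily readings to normalized 5-week supervised windows.

Stations are averaged into a national daily value (missing readings
excluded), days are averaged into epidemiological weeks, features are
min-max normalized on a stated fit range, and the weekly table is framed
into sliding windows of ``time_steps`` weeks whose target is the count at
the window's final week — so each sample sees the current week's exposures
plus four weeks of history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .columns import INPUT_COLUMNS
from .epiweeks import week_of_year

__all__ = [
    "aggregate_stations",
    "daily_to_weekly",
    "ScalerState",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
    "WindowSet",
    "make_windows",
]


def aggregate_stations(daily: pd.DataFrame) -> pd.DataFrame:
    """Average station readings into one national value per (date, variable).

    Missing readings are excluded from the mean. A (date, variable) pair with
    no non-missing reading at all is an error naming the offending pairs.
    Returns a wide table: one row per date, one column per variable.
    """
    grouped = daily.groupby(["date", "variable"])["value"]
    counts = grouped.count()
    empty = counts[counts == 0]
    if len(empty):
        missing = ", ".join(f"{d}/{v}" for d, v in empty.index[:5])
        raise ValueError(f"no non-missing reading for (date, variable): {missing}")
    national = grouped.mean().unstack("variable")
    national.index.name = "date"
    return national


def daily_to_weekly(national: pd.DataFrame) -> pd.DataFrame:
    """Average daily national values into epidemiological weeks.

    Each day is assigned to its week by the first-Wednesday rule; the weekly
    value is the mean of the available daily values (fewer than 7 at the
    simulated range's edges). Returns columns year, week_of_year + variables.
    """
    weeks = [week_of_year(d) for d in national.index]
    keyed = national.copy()
    keyed["year"] = [w.year for w in weeks]
    keyed["week_of_year"] = [w.week_index for w in weeks]
    weekly = keyed.groupby(["year", "week_of_year"], as_index=False).mean()
    return weekly


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalerState:
    """Per-column min/max learned from a stated fit range (row labels)."""

    columns: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    fit_rows: tuple[int, int]  # [first, last] row position of the fit range

    def to_json(self) -> str:
        return json.dumps(
            {"columns": list(self.columns), "mins": list(self.mins),
             "maxs": list(self.maxs), "fit_rows": list(self.fit_rows)}
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalerState":
        d = json.loads(text)
        return cls(tuple(d["columns"]), tuple(d["mins"]), tuple(d["maxs"]),
                   tuple(d["fit_rows"]))


def minmax_fit(table: pd.DataFrame, columns: list[str] | None = None) -> ScalerState:
    """Learn per-column min and max from the given rows."""
    if len(table) == 0:
        raise ValueError("fit range is empty")
    cols = list(columns) if columns is not None else list(table.columns)
    sub = table[cols].astype(float)
    return ScalerState(
        columns=tuple(cols),
        mins=tuple(sub.min().to_numpy()),
        maxs=tuple(sub.max().to_numpy()),
        fit_rows=(int(table.index[0]), int(table.index[-1])),
    )


def minmax_apply(state: ScalerState, table: pd.DataFrame) -> pd.DataFrame:
    """x' = (x - min) / (max - min), column-wise; a constant column maps to 0.

    Values outside the fit range extrapolate beyond [0, 1] — no clamping.
    Columns not covered by the scaler pass through unchanged.
    """
    out = table.copy()
    for col, lo, hi in zip(state.columns, state.mins, state.maxs):
        span = hi - lo
        out[col] = 0.0 if span == 0 else (table[col].astype(float) - lo) / span
    return out


def minmax_invert(state: ScalerState, column: str, values: np.ndarray) -> np.ndarray:
    """Map normalized values of one column back to the original scale."""
    i = state.columns.index(column)
    span = state.maxs[i] - state.mins[i]
    return np.asarray(values, dtype=float) * span + state.mins[i]


# ---------------------------------------------------------------------------
# supervised windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSet:
    """Sliding 5-week windows: X (n, time_steps, n_features), y aligned to
    each window's final week, and that week's (year, week) identifier."""

    X: np.ndarray
    y: np.ndarray
    week_ids: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.y)


def make_windows(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    target_column: str = "outpatient",
    time_steps: int = 5,
    ids: list[tuple[int, int]] | None = None,
) -> WindowSet:
    """Frame a contiguous weekly table into stride-1 supervised windows.

    Sample t covers weeks t-4..t and its target is ``target_column`` at week
    t, so n_samples = n_rows - time_steps + 1. ``ids`` optionally supplies
    the (year, week) identifier of each row (useful when the table's own
    week columns have been normalized); by default they are read from the
    table's ``year``/``week_of_year`` columns.
    """
    cols = feature_columns if feature_columns is not None else INPUT_COLUMNS
    n = len(table)
    if n < time_steps:
        raise ValueError(f"need at least {time_steps} rows, got {n}")
    if ids is None:
        ids = [
            (int(r.year), int(r.week_of_year))
            for r in table[["year", "week_of_year"]].itertuples()
        ]
    elif len(ids) != n:
        raise ValueError("ids must align with table rows")
    F = table[cols].to_numpy(dtype=float)
    X = np.stack([F[t - time_steps + 1 : t + 1] for t in range(time_steps - 1, n)])
    y = table[target_column].to_numpy(dtype=float)[time_steps - 1 :]
    return WindowSet(X=X, y=y, week_ids=tuple(ids[time_steps - 1 :]))
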