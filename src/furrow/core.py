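"""Shared domain types and the cell-table schema.

One nucleus is one :class:`CellRecord`; one imaged disc is one
:class:`DiscSample` holding a cell table (a pandas DataFrame in the schema
below) plus, once computed, its furrow calibration.

Cell-type vocabulary: pairs of photoreceptors that commit concurrently
(R2/R5, R3/R4, R1/R6) and cone-cell pairs (C1/C2, C3/C4) are pooled into one
label each, since their trajectories are statistically indistinguishable and
pooling doubles the cells per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Allowed values of the ``cell_type`` column.
CELL_TYPES = ("progenitor", "R8", "R2R5", "R3R4", "R1R6", "R7", "C1C2", "C3C4")

#: Cell-type labels that denote differentiating (non-progenitor, non-R8) cells.
DIFFERENTIATING_TYPES = ("R2R5", "R3R4", "R1R6", "R7", "C1C2", "C3C4")

#: Required columns of the shared CSV cell-table schema, in canonical order.
CELL_TABLE_COLUMNS = (
    "disc_id",
    "cell_id",
    "x_px",
    "y_px",
    "section",
    "cell_type",
    "yfp_mean",
    "rfp_mean",
    "nuclear_size_px",
)


class SchemaError(ValueError):
    """A cell table violates the shared schema (missing column / bad value)."""


@dataclass
class CellRecord:
    """One segmented nucleus with raw measurements and derived quantities.

    ``normalized_level`` is always ``yfp_mean / rfp_mean``; ``time_hr`` is
    filled by the timeline stage and is ``nan`` until then.
    """

    disc_id: str
    cell_id: int
    x_px: float
    y_px: float
    section: int
    cell_type: str
    yfp_mean: float
    rfp_mean: float
    nuclear_size_px: float
    normalized_level: float = float("nan")
    time_hr: float = float("nan")

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise SchemaError(f"unknown cell_type {self.cell_type!r}")
        if self.rfp_mean > 0 and np.isnan(self.normalized_level):
            self.normalized_level = self.yfp_mean / self.rfp_mean


@dataclass
class DiscSample:
    """All cells of one disc plus its derived furrow geometry.

    ``cells`` follows the shared schema (extra columns allowed and
    preserved).  ``calibration`` is set by the timeline stage.
    """

    disc_id: str
    cells: pd.DataFrame
    calibration: Optional[object] = None  # timeline.FurrowCalibration once computed
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_cell_table(self.cells)

    @property
    def r8_positions(self) -> np.ndarray:
        """(n, 2) array of R8 centroid (x, y) in pixels."""
        r8 = self.cells[self.cells["cell_type"] == "R8"]
        return r8[["x_px", "y_px"]].to_numpy(dtype=float)

    def of_type(self, *cell_types: str) -> pd.DataFrame:
        return self.cells[self.cells["cell_type"].isin(cell_types)]

    def __len__(self) -> int:
        return len(self.cells)


def validate_cell_table(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming the offending column or row."""
    for col in CELL_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    bad = ~df["cell_type"].isin(CELL_TYPES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unknown cell_type {df['cell_type'].iloc[row]!r} at row {row}"
        )


def ensure_normalized_level(df: pd.DataFrame) -> pd.DataFrame:
    """Add the ``normalized_level = yfp_mean / rfp_mean`` column if absent."""
    if "normalized_level" not in df.columns:
        df = df.copy()
        df["normalized_level"] = df["yfp_mean"] / df["rfp_mean"]
    return df
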