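"""Snapshot, field and metrics file formats (all plain text).

Cell snapshot CSV columns (exact order):
time_h, id, x_um, y_um, radius_um, biomass_fg, color, strain,
growth_rate_per_h, active(0/1).

Field files are delimited grids: a header line ``nx ny spacing`` followed
by row-major node values (row 0 = bottom).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import CellGroup
from .solute import Grid2D, SoluteField

SNAPSHOT_COLUMNS = [
    "time_h", "id", "x_um", "y_um", "radius_um", "biomass_fg",
    "color", "strain", "growth_rate_per_h", "active",
]


def cells_to_frame(cells: CellGroup, time_h: float, strain_names) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_h": np.full(cells.n, time_h),
            "id": cells.ids,
            "x_um": cells.x,
            "y_um": cells.y,
            "radius_um": cells.radius,
            "biomass_fg": cells.biomass,
            "color": [cells.color_names[c] for c in cells.color],
            "strain": [strain_names[s] for s in cells.strain],
            "growth_rate_per_h": cells.growth_rate,
            "active": cells.active.astype(int),
        },
        columns=SNAPSHOT_COLUMNS,
    )


def write_snapshot(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_snapshot(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(SNAPSHOT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"snapshot file lacks columns: {sorted(missing)}")
    return frame


def frame_to_cells(frame: pd.DataFrame, rho_area: float) -> CellGroup:
    """Rebuild a CellGroup from a snapshot table (for re-analysis)."""
    color_names = tuple(dict.fromkeys(frame["color"]))
    strain_names = list(dict.fromkeys(frame["strain"]))
    return CellGroup(
        x=frame["x_um"].to_numpy(float),
        y=frame["y_um"].to_numpy(float),
        biomass=frame["biomass_fg"].to_numpy(float),
        color=np.array([color_names.index(c) for c in frame["color"]], np.int64),
        strain=np.array([strain_names.index(s) for s in frame["strain"]], np.int64),
        ids=frame["id"].to_numpy(np.int64),
        growth_rate=frame["growth_rate_per_h"].to_numpy(float),
        active=frame["active"].to_numpy(bool),
        rho_area=rho_area,
        color_names=color_names,
        next_id=int(frame["id"].max()) + 1,
    )


def write_field(field: SoluteField, grid: Grid2D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{grid.nx} {grid.ny} {grid.spacing}\n")
        np.savetxt(fh, field.values, fmt="%.10g")


def read_field(path, kind: str = "SUBSTRATE", bulk_value: float = 0.0):
    with open(path) as fh:
        nx, ny, spacing = fh.readline().split()
        values = np.loadtxt(fh, ndmin=2)
    grid = Grid2D(int(nx), int(ny), float(spacing))
    if values.shape != grid.shape:
        raise ValueError("field file shape does not match its header")
    field = SoluteField(kind, values, bulk_value, np.zeros(grid.shape, bool))
    return field, grid


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")
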