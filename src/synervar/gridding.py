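"""Build the analysis cell table: terrestrial masking, rasterization of
species range boxes into per-cell presence, and richness transforms.

The cell table is the spine joining every stage: one row per grid cell with
its centroid (planar km), terrestrial fraction, inclusion flag and richness
columns.  Species ranges are axis-aligned boxes; a species is present in a
cell when its box intersects the cell's closed square footprint (the
``any-overlap`` rule, boundary touching counts) or, alternatively, when the
box contains the cell centroid (``centroid`` rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "mask_cells",
    "presence_matrix",
    "rasterize_richness",
    "transform_richness",
]

CELL_COLUMNS = ("cell_id", "x_km", "y_km", "terrestrial_frac")
RANGE_COLUMNS = ("species_id", "xmin", "ymin", "xmax", "ymax")


def _check_cells(cells: pd.DataFrame) -> None:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise InputError(f"cell table missing columns: {missing}")
    if cells["cell_id"].duplicated().any():
        raise InputError("cell_id values must be unique")


def mask_cells(cells: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Flag cells with terrestrial fraction >= threshold as included.

    Cells below the threshold (coastal cells dominated by water) are kept in
    the table for traceability but excluded from every downstream matrix.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InputError("threshold must be in [0, 1]")
    _check_cells(cells)
    out = cells.copy()
    out["included"] = out["terrestrial_frac"].to_numpy() >= threshold
    if not out["included"].any():
        raise InputError("no cells survive mask")
    return out


def presence_matrix(
    cells: pd.DataFrame,
    ranges: pd.DataFrame,
    cell_size: float,
    rule: str = "any-overlap",
) -> np.ndarray:
    """Boolean cells x species presence matrix from range boxes.

    ``any-overlap``: the box intersects the closed square footprint
    (centroid +/- cell_size/2); touching an edge counts as present.
    ``centroid``: the box contains the cell centroid.
    """
    _check_cells(cells)
    missing = [c for c in RANGE_COLUMNS if c not in ranges.columns]
    if missing:
        raise InputError(f"range table missing columns: {missing}")
    bad = ranges[(ranges["xmin"] > ranges["xmax"]) | (ranges["ymin"] > ranges["ymax"])]
    if len(bad):
        raise InputError(f"malformed range box for species_id(s): {bad['species_id'].tolist()}")
    if rule not in ("any-overlap", "centroid"):
        raise InputError(f"unknown overlap rule {rule!r}")

    cx = cells["x_km"].to_numpy()[:, None]
    cy = cells["y_km"].to_numpy()[:, None]
    xmin = ranges["xmin"].to_numpy()[None, :]
    xmax = ranges["xmax"].to_numpy()[None, :]
    ymin = ranges["ymin"].to_numpy()[None, :]
    ymax = ranges["ymax"].to_numpy()[None, :]
    if rule == "any-overlap":
        h = cell_size / 2.0
        return (
            (xmin <= cx + h) & (xmax >= cx - h) & (ymin <= cy + h) & (ymax >= cy - h)
        )
    return (xmin <= cx) & (xmax >= cx) & (ymin <= cy) & (ymax >= cy)


def rasterize_richness(
    cells: pd.DataFrame,
    ranges: pd.DataFrame,
    cell_size: float,
    rule: str = "any-overlap",
) -> np.ndarray:
    """Per-cell species richness: count of boxes present under ``rule``.

    Cells with zero richness are retained; adding a species can never
    decrease a count.
    """
    return presence_matrix(cells, ranges, cell_size, rule=rule).sum(axis=1).astype(np.int64)


def transform_richness(richness) -> np.ndarray:
    """Natural log of (richness + 1); richness must be non-negative."""
    r = np.asarray(richness, dtype=float)
    if np.any(r < 0):
        raise InputError("richness must be non-negative")
    return np.log1p(r)
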