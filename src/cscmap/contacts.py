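"""Macrophage density and cell–macrophage contact calls.

Density is the fraction of the field covered by the macrophage mask
(the voxel/pixel coverage measure). "Direct physical contact" is
operationalized as the minimum distance from a cell's boundary to the
mask being at most ``max_gap`` (default 0.5 µm, about one pixel at the
default scale); distance is read off a Euclidean distance transform of
the mask, which is exact to pixel resolution and independent of cell
count.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import RegionMask
from .synthgen import CELL_DIAMETER_UM

__all__ = ["macrophage_density", "contact_fraction", "cell_mask_distances"]


def macrophage_density(mask: RegionMask) -> float:
    """Fraction of the field covered by the mask, in [0, 1]."""
    return float(mask.mask.mean())


def cell_mask_distances(
    cells: pd.DataFrame,
    mask: RegionMask,
    cell_radius_um: float = CELL_DIAMETER_UM / 2.0,
) -> np.ndarray:
    """Boundary-to-mask distance (µm) per cell; 0 when overlapping."""
    edt = ndimage.distance_transform_edt(~mask.mask) * mask.pixel_size
    h, w = mask.mask.shape
    col = np.clip(
        np.round(cells["x_um"].to_numpy(float) / mask.pixel_size).astype(int),
        0, w - 1,
    )
    row = np.clip(
        np.round(cells["y_um"].to_numpy(float) / mask.pixel_size).astype(int),
        0, h - 1,
    )
    return np.maximum(0.0, edt[row, col] - cell_radius_um)


def contact_fraction(
    cells: pd.DataFrame,
    mask: RegionMask,
    max_gap_um: float = 0.5,
    cell_radius_um: float = CELL_DIAMETER_UM / 2.0,
    class_col: str = "cls",
) -> dict:
    """Per-class fraction of cells in direct contact with the mask.

    A cell is "in contact" iff the minimum distance from its boundary
    (disk of ``cell_radius_um``) to the mask is ≤ ``max_gap_um``.
    Returns a dict with per-cell flags, per-class fractions (NaN when a
    class has no cells, flagged in ``missing_classes``) and a 2x2
    class-by-contact count table suitable for an exact test (the test
    itself is delegated to standard statistics routines).
    """
    if class_col not in cells.columns:
        raise KeyError(f"cells table has no class column {class_col!r}")
    if max_gap_um < 0:
        raise ValueError("max_gap must be >= 0")
    d = cell_mask_distances(cells, mask, cell_radius_um)
    in_contact = d <= max_gap_um

    classes = pd.unique(cells[class_col])
    fractions: dict[str, float] = {}
    missing: list[str] = []
    table_rows = []
    for c in classes:
        sel = (cells[class_col] == c).to_numpy()
        n = int(sel.sum())
        k = int(in_contact[sel].sum())
        if n == 0:
            fractions[str(c)] = float("nan")
            missing.append(str(c))
        else:
            fractions[str(c)] = k / n
        table_rows.append({"cls": c, "contact": k, "no_contact": n - k})
    table = pd.DataFrame(
        table_rows, columns=["cls", "contact", "no_contact"]
    ).set_index("cls")
    return {
        "in_contact": pd.Series(in_contact, index=cells.index, name="in_contact"),
        "fractions": fractions,
        "missing_classes": missing,
        "table": table,
        "max_gap_um": max_gap_um,
    }
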