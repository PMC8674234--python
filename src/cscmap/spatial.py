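"""Distance-to-doorway enrichment statistics.

The central statistic of this package: cells are binned by the distance
from their centroid to the nearest TMEM doorway (modeled as a circle,
default 60 µm diameter) or to the nearest vessel mask, in 40 µm contour
intervals. Cells inside or touching the reference structure fall in a
dedicated 0 µm bin; cells beyond the cap (default 300 µm) fall in an
open terminal bin. Per-bin CSC counts are normalized by all-cell
(nuclear stain) counts at the same distance, which controls for the
non-uniform distribution of tumor tissue around vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import RegionMask

__all__ = [
    "DoorwaySite",
    "DistanceProfile",
    "bin_edges",
    "bin_labels",
    "n_bins",
    "assign_bins",
    "distance_to_nearest_doorway",
    "distance_to_nearest_vessel",
    "profile",
    "enrichment_vs_tumor_average",
    "doorway_csc_occupancy",
]


@dataclass(frozen=True)
class DoorwaySite:
    """A TMEM doorway (or vessel-segment reference) as a circular ROI."""

    x_um: float
    y_um: float
    diameter_um: float = 60.0
    kind: str = "tmem"

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("doorway diameter must be > 0")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


# ---------------------------------------------------------------- binning

def bin_edges(bin_width: float = 40.0, cap: float = 300.0) -> np.ndarray:
    """Inner contour edges ``[0, w, 2w, ..., cap]``.

    Bins are: {0}, (0, w], (w, 2w], ..., (last_edge, cap], plus an open
    terminal bin (> cap). If ``cap`` is not a multiple of ``bin_width``
    the last closed bin is a partial interval ending at ``cap``.
    """
    if bin_width <= 0 or cap <= 0:
        raise ValueError("bin_width and cap must be > 0")
    edges = list(np.arange(0.0, cap, bin_width))
    edges.append(float(cap))
    return np.asarray(edges)


def bin_labels(bin_width: float = 40.0, cap: float = 300.0) -> list[str]:
    edges = bin_edges(bin_width, cap)
    labels = ["0"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{lo:g}-{hi:g}")
    labels.append(f">{cap:g}")
    return labels


def n_bins(bin_width: float = 40.0, cap: float = 300.0) -> int:
    return len(bin_labels(bin_width, cap))


def assign_bins(
    distances: np.ndarray, bin_width: float = 40.0, cap: float = 300.0
) -> np.ndarray:
    """Bin index per distance: 0 for d == 0, half-open (lo, hi] otherwise."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    edges = bin_edges(bin_width, cap)
    # searchsorted with side="left" maps d in (edges[i-1], edges[i]] to i
    idx = np.searchsorted(edges, d, side="left")
    idx = np.where(d == 0, 0, idx)
    return idx.astype(int)


# ------------------------------------------------------------- distances

def _site_arrays(
    sites: Union[Sequence[DoorwaySite], pd.DataFrame]
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sites, pd.DataFrame):
        centers = sites[["x_um", "y_um"]].to_numpy(float)
        radii = sites["diameter_um"].to_numpy(float) / 2.0
    else:
        centers = np.array([[s.x_um, s.y_um] for s in sites], dtype=float)
        radii = np.array([s.radius_um for s in sites], dtype=float)
    if len(centers) == 0:
        raise ValueError("at least one doorway site is required")
    return centers, radii


def distance_to_nearest_doorway(
    cells: Union[pd.DataFrame, np.ndarray],
    sites: Union[Sequence[DoorwaySite], pd.DataFrame],
) -> np.ndarray:
    """Distance (µm) from each cell centroid to the nearest doorway circle.

    Distance is measured to the circle *edge*: ``max(0, ||c - center|| - r)``,
    so cells inside or touching the circle score 0 and land in the 0 µm bin.
    """
    if isinstance(cells, pd.DataFrame):
        xy = cells[["x_um", "y_um"]].to_numpy(float)
    else:
        xy = np.asarray(cells, dtype=float)
    centers, radii = _site_arrays(sites)
    diff = xy[:, None, :] - centers[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2)) - radii[None, :]
    return np.maximum(0.0, d.min(axis=1))


def distance_to_nearest_vessel(
    cells: Union[pd.DataFrame, np.ndarray], vessel_mask: RegionMask
) -> np.ndarray:
    """Distance (µm) from cell centroids to the nearest vessel pixel.

    The vessel mask must already have vessels containing TMEM doorways
    removed when the reference is "vessels without TMEM". Computed on a
    Euclidean distance transform of the mask; centroids on a vessel
    pixel score 0.
    """
    if not vessel_mask.mask.any():
        raise ValueError("vessel mask is empty")
    if isinstance(cells, pd.DataFrame):
        xy = cells[["x_um", "y_um"]].to_numpy(float)
    else:
        xy = np.asarray(cells, dtype=float)
    edt = ndimage.distance_transform_edt(~vessel_mask.mask)
    h, w = vessel_mask.mask.shape
    col = np.clip(np.round(xy[:, 0] / vessel_mask.pixel_size).astype(int), 0, w - 1)
    row = np.clip(np.round(xy[:, 1] / vessel_mask.pixel_size).astype(int), 0, h - 1)
    return edt[row, col] * vessel_mask.pixel_size


# --------------------------------------------------------------- profile

@dataclass
class DistanceProfile:
    """Per-contour-bin CSC counts normalized by all-cell counts."""

    labels: list[str]
    csc_count: np.ndarray
    allcell_count: np.ndarray
    bin_width: float
    cap: float
    reference: str = "tmem"
    pct_csc: np.ndarray = field(init=False)
    enrichment_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.csc_count = np.asarray(self.csc_count, dtype=float)
        self.allcell_count = np.asarray(self.allcell_count, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * self.csc_count / self.allcell_count
        # empty all-cell bins are flagged as missing, not reported as 0
        pct[self.allcell_count == 0] = np.nan
        self.pct_csc = pct
        p0, pend = self.pct_csc[0], self.pct_csc[-1]
        if np.isnan(p0) or np.isnan(pend) or pend == 0:
            self.enrichment_ratio = float("nan")
        else:
            self.enrichment_ratio = float(p0 / pend)

    @property
    def total_csc(self) -> float:
        return float(self.csc_count.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.labels,
                "csc": self.csc_count,
                "allcell": self.allcell_count,
                "pct_csc": self.pct_csc,
            }
        )


def profile(
    csc_distances: np.ndarray,
    allcell_distances: np.ndarray,
    bin_width: float = 40.0,
    cap: float = 300.0,
    reference: str = "tmem",
) -> DistanceProfile:
    """Build the contour-bin distance profile.

    ``allcell_distances`` are the distances of *all* tumor cells
    (nuclear stain) to the same reference; they normalize the CSC
    histogram into a per-bin %CSC. The enrichment ratio is
    ``pct_csc(0 µm bin) / pct_csc(>cap bin)``; it is NaN (flagged) when
    either bin is empty.
    """
    labels = bin_labels(bin_width, cap)
    k = len(labels)
    csc_idx = assign_bins(csc_distances, bin_width, cap)
    all_idx = assign_bins(allcell_distances, bin_width, cap)
    csc_count = np.bincount(csc_idx, minlength=k).astype(float)
    all_count = np.bincount(all_idx, minlength=k).astype(float)
    return DistanceProfile(labels, csc_count, all_count, bin_width, cap, reference)


def enrichment_vs_tumor_average(prof: DistanceProfile) -> float:
    """0 µm bin %CSC relative to the overall %CSC across the whole field."""
    total_all = prof.allcell_count.sum()
    total_csc = prof.csc_count.sum()
    if total_all == 0 or total_csc == 0:
        return float("nan")
    overall = 100.0 * total_csc / total_all
    p0 = prof.pct_csc[0]
    if np.isnan(p0):
        return float("nan")
    return float(p0 / overall)


def doorway_csc_occupancy(
    sites: Union[Sequence[DoorwaySite], pd.DataFrame],
    csc_cells: Union[pd.DataFrame, np.ndarray],
) -> float:
    """Proportion of doorways with at least one CSC inside/touching the circle."""
    centers, radii = _site_arrays(sites)
    if isinstance(csc_cells, pd.DataFrame):
        xy = csc_cells[["x_um", "y_um"]].to_numpy(float)
    else:
        xy = np.asarray(csc_cells, dtype=float)
    if len(xy) == 0:
        return 0.0
    diff = centers[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    occupied = (d <= radii[:, None]).any(axis=1)
    return float(occupied.mean())
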