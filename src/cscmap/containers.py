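"""Shared in-memory containers for images, masks, and ground truth.

All spatial quantities are expressed in micrometres (µm); time in minutes
unless a name says hours. Images are numpy arrays indexed ``[row, col]``
(y, x) for single planes and ``[frame, row, col]`` for movies; the
``pixel_size`` attribute converts between pixel and µm coordinates
(``x_px = x_um / pixel_size``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ChannelStack", "RegionMask", "SceneTruth", "MovieTruth", "Track"]


@dataclass
class ChannelStack:
    """A named multi-channel image or time-lapse.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``nuclei``, ``volume``, ``sensor``,
        ``macrophage``, ``vessel``) to a 2-D plane ``(H, W)`` or a movie
        ``(T, H, W)``. All channels must share one shape.
    pixel_size
        Lateral sampling in µm per pixel.
    frame_interval
        Time between frames in minutes; ``None`` for still images.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    frame_interval: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def is_movie(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3

    @property
    def n_frames(self) -> int:
        return self.shape[0] if self.is_movie else 1

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class RegionMask:
    """Binary region (macrophage, vessel, degradation, ...) on a pixel grid."""

    mask: np.ndarray
    pixel_size: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mask.size == 0:
            raise ValueError("mask grid is empty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2

    def translated(self, dy_px: int, dx_px: int) -> "RegionMask":
        """Mask rolled by whole pixels (used for invariance checks)."""
        return RegionMask(
            np.roll(self.mask, (dy_px, dx_px), axis=(0, 1)),
            self.pixel_size,
            self.label,
        )


@dataclass
class SceneTruth:
    """Ground truth paired with a generated scene.

    ``cells`` always carries one row per cell with at least
    ``cell_id, x_um, y_um, cls`` (``cls`` in ``{"CSC", "nonCSC"}``) and a
    ``sensor_intensity`` column; generators add scenario-specific columns
    (``contact``, ``distance_um``, ``lesion_id`` ...).
    """

    cells: pd.DataFrame
    config: dict
    masks: dict[str, RegionMask] = field(default_factory=dict)
    sites: Optional[pd.DataFrame] = None
    control_intensities: Optional[np.ndarray] = None
    puncta: Optional[pd.DataFrame] = None
    events: Optional[pd.DataFrame] = None


@dataclass
class MovieTruth:
    """Ground truth for a generated time-lapse.

    ``tracks`` has one row per (cell, frame): ``cell_id, frame, t_min,
    x_um, y_um`` (true drift-free position), ``x_obs, y_obs`` (position
    after drift and localization jitter, i.e. what the rendered movie
    shows) and ``sensor_intensity``. ``cells`` has one row per cell:
    ``cell_id, cls, speed_truth, contacted, contact_frame, converted,
    conversion_frame``.
    """

    tracks: pd.DataFrame
    cells: pd.DataFrame
    drift_um: np.ndarray  # (T, 2) cumulative (dx, dy) drift in µm
    frame_interval: float
    config: dict


@dataclass
class Track:
    """A linked single-cell trajectory."""

    cell_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    frame_interval: float
    sensor: Optional[np.ndarray] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if len(np.unique(self.frames)) != len(self.frames):
            raise ValueError("track has duplicate frames")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t_min(self) -> np.ndarray:
        return self.frames * self.frame_interval

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(np.sort(self.frames)) > 1))
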