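"""Puncta detection, colocalization, and invadopodia/degradation scoring.

Invadopodia in fixed tissue are identified as cortactin + Tks5
colocalized puncta. The field is partitioned into stem-cell areas
(36 µm diameter ROIs around gated stem cells — three single-cell
diameters, wide enough to capture extending protrusions) and the
non-stem remainder; the invadopodia score is the colocalized puncta
density per class area, and degradation is the positive-area fraction
of the cleaved-collagen channel per class (or, for the in vitro
fluorescent-gelatin variant, the fraction of *lost* signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import blob_log

from .containers import ChannelStack, RegionMask

__all__ = [
    "AreaPartition",
    "detect_puncta",
    "colocalize",
    "partition_areas",
    "partition_from_mask",
    "invadopodia_score",
    "degradation_fraction",
]

MAX_PUNCTUM_RADIUS_UM = 2.0  # diffraction-scale spot cap


def detect_puncta(
    channel: np.ndarray,
    pixel_size: float,
    min_sigma_um: float = 0.15,
    max_sigma_um: float = 0.6,
    threshold: float = 20.0,
) -> pd.DataFrame:
    """Blob (Laplacian-of-Gaussian) puncta detection on a single channel.

    Returns a table with ``x_um, y_um, radius_um, intensity``;
    deterministic for fixed input. Radii are capped at the
    diffraction-scale limit of 2 µm.
    """
    if channel.ndim != 2:
        raise ValueError("detect_puncta expects a single 2-D channel")
    img = np.asarray(channel, dtype=float)
    blobs = blob_log(
        img,
        min_sigma=min_sigma_um / pixel_size,
        max_sigma=max_sigma_um / pixel_size,
        num_sigma=5,
        threshold=threshold,
    )
    rows = []
    h, w = img.shape
    for y, x, sigma in blobs:
        radius = min(float(sigma) * np.sqrt(2.0) * pixel_size,
                     MAX_PUNCTUM_RADIUS_UM)
        rows.append(
            dict(
                x_um=x * pixel_size,
                y_um=y * pixel_size,
                radius_um=radius,
                intensity=float(img[int(round(y)), int(round(x))]),
            )
        )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "radius_um", "intensity"])


_EXHAUSTIVE_LIMIT = 400  # |A| x |B| below which optimal assignment is used


def colocalize(
    puncta_a: pd.DataFrame,
    puncta_b: pd.DataFrame,
    radius_um: float = 0.5,
) -> pd.DataFrame:
    """One-to-one nearest-pair matching of two puncta sets within a radius.

    Small instances are solved exactly (maximum-cardinality,
    minimum-distance assignment); larger ones greedily over candidate
    pairs in ascending distance, which is deterministic and near
    optimal at puncta densities where matches are unambiguous. Each
    punctum is used at most once, so the matched count never exceeds
    ``min(|A|, |B|)`` and is symmetric in A and B. Returns a table of
    matched pairs (indices into the input frames, coordinates of the A
    member, pair distance).
    """
    cols = ["index_a", "index_b", "x_um", "y_um", "distance_um"]
    if len(puncta_a) == 0 or len(puncta_b) == 0:
        return pd.DataFrame(columns=cols)
    a = puncta_a[["x_um", "y_um"]].to_numpy(float)
    b = puncta_b[["x_um", "y_um"]].to_numpy(float)

    matched: list[tuple[float, int, int]] = []
    if len(a) * len(b) <= _EXHAUSTIVE_LIMIT:
        from scipy.optimize import linear_sum_assignment

        dist = np.hypot(
            *(a[:, None, :] - b[None, :, :]).transpose(2, 0, 1)
        )
        big = 1e9
        cost = np.where(dist <= radius_um, dist, big)
        rows_i, cols_j = linear_sum_assignment(
            np.pad(cost, ((0, max(0, len(b) - len(a))),
                          (0, max(0, len(a) - len(b)))),
                   constant_values=big)
        )
        for i, j in zip(rows_i, cols_j):
            if i < len(a) and j < len(b) and dist[i, j] <= radius_um:
                matched.append((float(dist[i, j]), i, j))
    else:
        pairs = cKDTree(a).query_ball_tree(cKDTree(b), r=radius_um)
        cand = [
            (float(np.hypot(*(a[i] - b[j]))), i, j)
            for i, js in enumerate(pairs)
            for j in js
        ]
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, i, j in cand:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            matched.append((d, i, j))

    rows = [
        dict(
            index_a=puncta_a.index[i],
            index_b=puncta_b.index[j],
            x_um=a[i, 0],
            y_um=a[i, 1],
            distance_um=d,
        )
        for d, i, j in sorted(matched)
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class AreaPartition:
    """Disjoint stem / non-stem area masks over the analyzed field."""

    stem: RegionMask
    nonstem: RegionMask

    def __post_init__(self) -> None:
        if self.stem.mask.shape != self.nonstem.mask.shape:
            raise ValueError("partition masks disagree on shape")
        if np.any(self.stem.mask & self.nonstem.mask):
            raise ValueError("partition masks overlap")

    @property
    def areas_um2(self) -> dict[str, float]:
        return {"stem": self.stem.area_um2, "nonstem": self.nonstem.area_um2}


def partition_areas(
    stem_cells: pd.DataFrame,
    field_shape_px: tuple[int, int],
    pixel_size: float,
    roi_diameter_um: float = 36.0,
    field_mask: Optional[np.ndarray] = None,
) -> AreaPartition:
    """Partition the field into stem-cell ROIs and the remainder.

    The stem mask is the union of ``roi_diameter_um`` disks centered on
    the gated stem cells; the non-stem mask is the (tissue) field minus
    the stem mask. With zero stem cells the stem mask is empty and
    scoring remains defined on the non-stem area.
    """
    stem = np.zeros(field_shape_px, dtype=bool)
    r_px = roi_diameter_um / 2.0 / pixel_size
    h, w = field_shape_px
    yy, xx = None, None
    for _, cell in stem_cells.iterrows():
        cx = cell.x_um / pixel_size
        cy = cell.y_um / pixel_size
        lo_r = max(0, int(np.floor(cy - r_px - 1)))
        hi_r = min(h, int(np.ceil(cy + r_px + 1)) + 1)
        lo_c = max(0, int(np.floor(cx - r_px - 1)))
        hi_c = min(w, int(np.ceil(cx + r_px + 1)) + 1)
        rr = np.arange(lo_r, hi_r)[:, None]
        cc = np.arange(lo_c, hi_c)[None, :]
        stem[lo_r:hi_r, lo_c:hi_c] |= (
            (rr - cy) ** 2 + (cc - cx) ** 2 <= r_px**2
        )
    field = (
        np.ones(field_shape_px, dtype=bool)
        if field_mask is None
        else np.asarray(field_mask, dtype=bool)
    )
    stem &= field
    return AreaPartition(
        RegionMask(stem, pixel_size, "stem_area"),
        RegionMask(field & ~stem, pixel_size, "nonstem_area"),
    )


def partition_from_mask(
    stem_mask: np.ndarray,
    pixel_size: float,
    field_mask: Optional[np.ndarray] = None,
) -> AreaPartition:
    """Partition from a manually drawn stem-cell boundary mask."""
    stem = np.asarray(stem_mask, dtype=bool)
    field = (
        np.ones_like(stem) if field_mask is None
        else np.asarray(field_mask, dtype=bool)
    )
    return AreaPartition(
        RegionMask(stem & field, pixel_size, "stem_area"),
        RegionMask(field & ~stem, pixel_size, "nonstem_area"),
    )


def _puncta_in(puncta: pd.DataFrame, mask: RegionMask) -> int:
    if len(puncta) == 0:
        return 0
    h, w = mask.mask.shape
    col = np.clip(
        np.round(puncta["x_um"].to_numpy(float) / mask.pixel_size).astype(int),
        0, w - 1,
    )
    row = np.clip(
        np.round(puncta["y_um"].to_numpy(float) / mask.pixel_size).astype(int),
        0, h - 1,
    )
    return int(mask.mask[row, col].sum())


def invadopodia_score(
    coloc_puncta: pd.DataFrame, partition: AreaPartition
) -> dict:
    """Colocalized-puncta density (count/µm²) per class area and their ratio.

    Densities are undefined (NaN, flagged) for a zero-area class; the
    ratio is stem density over non-stem density.
    """
    out: dict = {"counts": {}, "density_per_um2": {}, "flags": []}
    for name, mask in (("stem", partition.stem), ("nonstem", partition.nonstem)):
        k = _puncta_in(coloc_puncta, mask)
        area = mask.area_um2
        out["counts"][name] = k
        if area == 0:
            out["density_per_um2"][name] = float("nan")
            out["flags"].append(f"zero-area class: {name}")
        else:
            out["density_per_um2"][name] = k / area
    ds, dn = out["density_per_um2"]["stem"], out["density_per_um2"]["nonstem"]
    out["ratio"] = ds / dn if dn not in (0.0,) and not np.isnan(dn) and not np.isnan(ds) else float("nan")
    return out


def degradation_fraction(
    degradation_channel: np.ndarray,
    partition: AreaPartition,
    threshold: float,
    mode: str = "tissue",
) -> dict:
    """Percent positive degradation area per class.

    ``mode="tissue"``: positive means signal above ``threshold``
    (cleaved-collagen stain). ``mode="gelatin"``: degradation appears
    as holes in a fluorescent gelatin layer, so positive means signal
    *below* the threshold.
    """
    if mode not in ("tissue", "gelatin"):
        raise ValueError("mode must be 'tissue' or 'gelatin'")
    img = np.asarray(degradation_channel, dtype=float)
    positive = img < threshold if mode == "gelatin" else img > threshold
    out: dict = {"pct_area": {}, "mode": mode, "threshold": threshold}
    for name, mask in (("stem", partition.stem), ("nonstem", partition.nonstem)):
        n = mask.mask.sum()
        out["pct_area"][name] = (
            float("nan") if n == 0 else 100.0 * positive[mask.mask].mean()
        )
    return out


def negative_control_threshold(
    control_region: np.ndarray, k_sd: float = 3.0
) -> float:
    """Default degradation threshold: mean + k·SD of a negative-control region."""
    x = np.asarray(control_region, dtype=float)
    return float(x.mean() + k_sd * x.std())
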