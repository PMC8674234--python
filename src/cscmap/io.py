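"""Reading and writing the package's on-disk formats.

Images go to multi-channel (OME-)TIFF with channel names in the
metadata; tables (cell records, tracks, sites, profiles, take tables)
to CSV; thresholds, summaries and configuration echoes to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .containers import ChannelStack, RegionMask

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]


def write_stack(path: Union[str, Path], stack: ChannelStack) -> None:
    """Write a ChannelStack as an OME-TIFF with named channels."""
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names])
    axes = "CTYX" if stack.is_movie else "CYX"
    meta = {
        "axes": axes,
        "Channel": {"Name": names},
        "PhysicalSizeX": stack.pixel_size,
        "PhysicalSizeY": stack.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeYUnit": "µm",
    }
    if stack.frame_interval is not None:
        meta["TimeIncrement"] = stack.frame_interval
        meta["TimeIncrementUnit"] = "min"
    extra = dict(stack.metadata)
    tifffile.imwrite(
        str(path), data.astype(np.float32), ome=True, metadata=meta,
        description=json.dumps(extra) if extra else None,
    )


def read_stack(path: Union[str, Path]) -> ChannelStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    names = [c.get("Name") for c in pixels.findall("ome:Channel", ns)]
    px = float(pixels.get("PhysicalSizeX", "1"))
    dt = pixels.get("TimeIncrement")
    h = int(pixels.get("SizeY"))
    w = int(pixels.get("SizeX"))
    t = int(pixels.get("SizeT", "1"))
    shape = (len(names), t, h, w) if t > 1 else (len(names), h, w)
    data = data.reshape(shape)
    channels = {n: data[i] for i, n in enumerate(names)}
    return ChannelStack(
        channels, px, frame_interval=float(dt) if dt else None
    )


def write_mask(path: Union[str, Path], mask: RegionMask) -> None:
    tifffile.imwrite(
        str(path), mask.mask.astype(np.uint8) * 255,
        metadata={"pixel_size_um": mask.pixel_size, "label": mask.label},
    )


def read_mask(path: Union[str, Path], pixel_size: float,
              label: str = "") -> RegionMask:
    return RegionMask(tifffile.imread(str(path)) > 0, pixel_size, label)


def write_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path: Union[str, Path], obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def read_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
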