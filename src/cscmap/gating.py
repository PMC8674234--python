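"""Sensor-positive cell gating.

Sensor-positive (stem) cells are defined by thresholding per-cell mean
sensor intensity against a threshold set from a matched control
construct lacking the response elements (the background construct), or
— for surrogate markers without a control construct — by selecting the
top fraction of the intensity distribution and reusing the resulting
fixed range on comparison tissue. Gating uses a strict ``>``, so ties
at the threshold are negative, and raising the threshold can never
increase the positive count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "GateThreshold",
    "fit_control_threshold",
    "gate_cells",
    "top_fraction_threshold",
]


@dataclass(frozen=True)
class GateThreshold:
    """A gating threshold with provenance.

    ``method`` records how the value was obtained (``control_quantile``,
    ``top_fraction`` or ``fixed_range``); the numeric ``value`` is what
    gets reused verbatim when the same gate is applied to comparison
    tissue.
    """

    value: float
    method: str
    source_n: int
    quantile_or_fraction: Optional[float] = None
    fixed_range: Optional[tuple[float, float]] = None

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "method": self.method,
            "source_n": self.source_n,
            "quantile_or_fraction": self.quantile_or_fraction,
            "fixed_range": self.fixed_range,
        }


def fit_control_threshold(
    control_intensities: np.ndarray, quantile: float = 0.995
) -> GateThreshold:
    """Threshold at a high quantile of the control-construct intensities.

    The default 0.995 quantile tolerates rare control outliers while
    keeping the false-positive rate below 0.5%.
    """
    x = np.asarray(control_intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("control intensity set is empty")
    if x.size < 30:
        raise ValueError(
            f"need at least 30 control measurements, got {x.size}"
        )
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    value = float(np.quantile(x, quantile))
    return GateThreshold(value, "control_quantile", int(x.size), quantile)


def gate_cells(
    cells: pd.DataFrame,
    threshold: GateThreshold,
    channel: str = "sensor_intensity",
) -> tuple[pd.DataFrame, dict]:
    """Label cells sensor-positive iff intensity strictly exceeds the gate.

    Returns a copy of ``cells`` with a ``sensor_label`` column
    (``"pos"``/``"neg"``) and a summary dict with counts and percent
    positive.
    """
    if channel not in cells.columns:
        raise KeyError(f"cells table has no channel column {channel!r}")
    out = cells.copy()
    pos = out[channel].to_numpy(float) > threshold.value
    out["sensor_label"] = np.where(pos, "pos", "neg")
    n = len(out)
    summary = {
        "n_cells": n,
        "n_positive": int(pos.sum()),
        "pct_positive": 100.0 * pos.mean() if n else float("nan"),
        "threshold": threshold.value,
        "method": threshold.method,
    }
    return out, summary


def top_fraction_threshold(
    intensities: np.ndarray,
    fraction: float = 0.05,
    scale_max: float = 255.0,
) -> GateThreshold:
    """Threshold selecting the top ``fraction`` highest-intensity cells.

    Used for surrogate stemness markers (e.g. a high-expression gate on
    a transcription factor stain) where no control construct exists:
    the gate is the ``1 - fraction`` quantile, and the resulting fixed
    range ``(value, scale_max)`` is reported for verbatim reuse on
    comparison tissue imaged under identical settings.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 20:
        raise ValueError(f"need at least 20 intensities, got {x.size}")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    value = float(np.quantile(x, 1.0 - fraction))
    return GateThreshold(
        value, "top_fraction", int(x.size), fraction,
        fixed_range=(value, float(scale_max)),
    )
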