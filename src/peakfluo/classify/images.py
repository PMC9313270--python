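"""Deterministic rasterization of amplification curves.

Curves are drawn as 1-pixel polylines on a fixed-axes grayscale canvas.  The
axes ranges are shared across a whole dataset so that per-curve scale never
leaks calibration information into the pixels: rescaling the fluorescence of
every trace moves the drawn line (the axes do not adapt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from ..trace import FluorescenceTrace

DEFAULT_SIZE = 32


@dataclass(frozen=True)
class AxesSpec:
    """Fixed plotting window shared by every image in a dataset."""

    cycle_range: tuple[float, float]
    fluorescence_range: tuple[float, float]
    width: int = DEFAULT_SIZE
    height: int = DEFAULT_SIZE

    def __post_init__(self) -> None:
        if self.cycle_range[1] <= self.cycle_range[0]:
            raise ValueError("empty cycle range")
        if self.fluorescence_range[1] <= self.fluorescence_range[0]:
            raise ValueError("empty fluorescence range")
        if self.width < 4 or self.height < 4:
            raise ValueError("image too small")


@dataclass(frozen=True)
class CurveImage:
    pixels: np.ndarray  # (height, width), float in [0, 1]; 1 = curve
    well_id: str
    label: Optional[Literal["high", "low"]] = None
    concentration: Optional[float] = None


def render_curve_image(
    trace: FluorescenceTrace,
    axes: AxesSpec,
    label: Optional[Literal["high", "low"]] = None,
    concentration: Optional[float] = None,
) -> CurveImage:
    """Rasterize one trace onto the fixed axes.  Same trace, same pixels.

    Points outside the axes window are clipped to the border with a warning.
    """
    c = trace.cycles.astype(float)
    f = trace.fluorescence
    c_lo, c_hi = axes.cycle_range
    f_lo, f_hi = axes.fluorescence_range
    if (f < f_lo).any() or (f > f_hi).any() or c[0] < c_lo or c[-1] > c_hi:
        warnings.warn(
            f"trace {trace.well_id!r} exceeds the axes window; clipping",
            stacklevel=2,
        )
    x = (np.clip(c, c_lo, c_hi) - c_lo) / (c_hi - c_lo) * (axes.width - 1)
    y = (np.clip(f, f_lo, f_hi) - f_lo) / (f_hi - f_lo) * (axes.height - 1)
    row = (axes.height - 1) - y  # image row 0 at the top
    pixels = np.zeros((axes.height, axes.width), dtype=np.float32)
    for i in range(len(x) - 1):
        n = int(max(abs(x[i + 1] - x[i]), abs(row[i + 1] - row[i]))) * 2 + 2
        t = np.linspace(0.0, 1.0, n)
        xs = np.rint(x[i] + t * (x[i + 1] - x[i])).astype(int)
        rs = np.rint(row[i] + t * (row[i + 1] - row[i])).astype(int)
        pixels[rs, xs] = 1.0
    if len(x) == 1:
        pixels[int(round(row[0])), int(round(x[0]))] = 1.0
    return CurveImage(pixels, trace.well_id, label, concentration)
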