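"""Dose-image formation: apply the PSM to a flood-field corrected image.

The flood-field correction flattens the pixel response but also washes
the true beam profile out of the stored image; multiplying by the PSM
restores it.  With the conversion constant c fixed at 1 the result is a
relative dose image:

    D = IM_EPID * G * c

When the PSM was computed on grouped pixels it is first brought back to
the acquisition resolution by 2D bilinear interpolation on the grouped
cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import ConfigError, DataError, GainMap

__all__ = ["DoseImage", "compute_dose_image", "upsample_psm"]


@dataclass
class DoseImage:
    """Relative dose matrix with its pixel pitch and conversion constant."""

    values: np.ndarray
    resolution: float  # mm at the isocenter plane
    scale_c: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("dose image contains non-finite values")

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.values, dtype=dtype)


def upsample_psm(
    gains: GainMap | np.ndarray,
    target_shape: tuple[int, int],
    *,
    scale: float | tuple[float, float] | None = None,
    source_pitch: float | None = None,
    target_pitch: float | None = None,
) -> np.ndarray:
    """Bilinearly interpolate a grouped PSM onto a finer grid.

    The grouped cell centres are placed at their physical positions on
    the target grid (source cell i covers ``scale`` target pixels, so its
    centre sits at (i + 1/2) * scale - 1/2 in target-pixel coordinates).
    ``scale`` = source pitch / target pitch; it is taken from the pitches
    when given, otherwise from the shape ratio.  Target cells outside the
    span of the source centres take the nearest edge value; a target grid
    extending beyond the physical source coverage is rejected.
    """
    g = np.asarray(gains.values if isinstance(gains, GainMap) else gains, float)
    n0, n1 = g.shape
    t0, t1 = target_shape
    if scale is None:
        if source_pitch is not None and target_pitch is not None:
            scale = source_pitch / target_pitch
        else:
            scale = (t0 / n0, t1 / n1)
    if np.isscalar(scale):
        scale = (float(scale), float(scale))
    s0, s1 = scale
    if s0 < 1 or s1 < 1:
        raise ConfigError("target grid must be finer than the source")
    over0 = t0 - n0 * s0
    over1 = t1 - n1 * s1
    if over0 > 1e-9 or over1 > 1e-9:
        raise ConfigError(
            "target grid extends beyond the source coverage by "
            f"({max(over0, 0):.2f}, {max(over1, 0):.2f}) target pixels"
        )
    centres0 = (np.arange(n0) + 0.5) * s0 - 0.5
    centres1 = (np.arange(n1) + 0.5) * s1 - 0.5
    interp = RegularGridInterpolator(
        (centres0, centres1), g, method="linear", bounds_error=False
    )
    # clamping target coordinates to the centre span extends edge cells
    # by their nearest value
    y = np.clip(np.arange(t0, dtype=float), centres0[0], centres0[-1])
    x = np.clip(np.arange(t1, dtype=float), centres1[0], centres1[-1])
    Y, X = np.meshgrid(y, x, indexing="ij")
    return interp(np.stack([Y.ravel(), X.ravel()], axis=-1)).reshape(t0, t1)


def compute_dose_image(
    im_epid: np.ndarray,
    gains: GainMap | np.ndarray,
    c: float = 1.0,
    *,
    resolution: float = 0.25,
    allow_upsample: bool = True,
    source_pitch: float | None = None,
) -> DoseImage:
    """Element-wise D = IM_EPID * G * c.

    If the PSM grid is coarser than the image and ``allow_upsample`` is
    set, the PSM is bilinearly interpolated to the image resolution
    first (using ``source_pitch``/``resolution`` when both are known).
    """
    im = np.asarray(im_epid, float)
    g = np.asarray(gains.values if isinstance(gains, GainMap) else gains, float)
    if np.any(g <= 0):
        raise DataError("gain map must be strictly positive")
    if g.shape != im.shape:
        if not allow_upsample:
            raise ConfigError(
                f"PSM shape {g.shape} does not match image shape {im.shape}"
            )
        kw = {}
        if source_pitch is not None:
            kw = {"source_pitch": source_pitch, "target_pitch": resolution}
        g = upsample_psm(g, im.shape, **kw)
    return DoseImage(im * g * c, resolution, c)
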