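"""Raw-image preparation: flood-field correction, pixel grouping, ROI
cropping and alignment of shifted acquisitions to the central grid.

The acquisition software already applies the dark-field / flood-field
correction to exported images, so in routine use only grouping and
cropping run here; the explicit correction is provided for raw exports.
The pipeline never rescales individual acquisitions: the absolute counts
of the five images carry the inter-acquisition information the solver
uses, so any normalisation would destroy it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AcquisitionImage, ConfigError, DataError


@dataclass
class RawImageTriplet:
    """Raw export plus its dark-field and flood-field companions."""

    raw: np.ndarray
    dark: np.ndarray
    flood: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, float)
        self.dark = np.asarray(self.dark, float)
        self.flood = np.asarray(self.flood, float)
        if not (self.raw.shape == self.dark.shape == self.flood.shape):
            raise ConfigError("raw, dark and flood images must share a shape")


@dataclass
class GroupedImage:
    """Image after square block averaging.

    ``trimmed`` records the native rows/columns dropped per side
    ((top, bottom), (left, right)) so border loss is never silent.
    """

    values: np.ndarray
    group_factor: int
    pixel_pitch: float  # mm at the isocenter plane
    trimmed: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))


def apply_ff_correction(
    triplet: RawImageTriplet, roi: tuple[slice, slice] | None = None
) -> np.ndarray:
    """Flood-field correct a raw image:

        IM_EPID = (raw - dark) / flood * mean(flood)

    ``roi`` restricts the flood mean (and the positivity check) to a
    region of interest; the correction itself is applied everywhere.
    The result is invariant to rescaling the flood by a constant.
    """
    region = roi if roi is not None else (slice(None), slice(None))
    flood_roi = triplet.flood[region]
    bad = np.argwhere(flood_roi <= 0)
    if bad.size:
        r, c = bad[0]
        r += region[0].start or 0
        c += region[1].start or 0
        raise DataError(f"flood field non-positive at pixel ({r}, {c})")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (triplet.raw - triplet.dark) / triplet.flood
    return out * flood_roi.mean()


def group_pixels(
    image: np.ndarray, group_factor: int, native_pitch: float = 0.25
) -> GroupedImage:
    """Average ``group_factor`` x ``group_factor`` blocks into one grouped
    pixel; excess border rows/columns are trimmed symmetrically.

    The arithmetic mean (not the sum) keeps grouped counts on the counts
    scale of the fluence relation F = C * G, and preserves the global mean
    over the trimmed region exactly.
    """
    image = np.asarray(image, float)
    f = int(group_factor)
    if f < 1:
        raise ConfigError("group_factor must be >= 1")
    n0, n1 = image.shape
    if f > min(n0, n1):
        raise ConfigError(
            f"group_factor {f} exceeds image dimensions {image.shape}"
        )
    b0, b1 = n0 // f, n1 // f
    t0, t1 = (n0 - b0 * f) // 2, (n1 - b1 * f) // 2
    trimmed = image[t0:t0 + b0 * f, t1:t1 + b1 * f]
    values = trimmed.reshape(b0, f, b1, f).mean(axis=(1, 3))
    lost = ((t0, n0 - b0 * f - t0), (t1, n1 - b1 * f - t1))
    return GroupedImage(values, f, native_pitch * f, lost)


def crop_center(image: np.ndarray, size: int) -> np.ndarray:
    """Central ``size`` x ``size`` crop (the working ROI)."""
    image = np.asarray(image)
    n0, n1 = image.shape
    if size > min(n0, n1):
        raise ConfigError(f"crop size {size} exceeds image shape {image.shape}")
    t0, t1 = (n0 - size) // 2, (n1 - size) // 2
    return image[t0:t0 + size, t1:t1 + size]


def translate(image: np.ndarray, displacement: tuple[int, int]) -> np.ndarray:
    """Shift image content by integer (dx, dy); vacated border cells are
    NaN-flagged."""
    image = np.asarray(image, float)
    dx, dy = int(displacement[0]), int(displacement[1])
    n0, n1 = image.shape
    out = np.full_like(image, np.nan)
    rdst = slice(max(dy, 0), n0 + min(dy, 0))
    cdst = slice(max(dx, 0), n1 + min(dx, 0))
    rsrc = slice(max(-dy, 0), n0 + min(-dy, 0))
    csrc = slice(max(-dx, 0), n1 + min(-dx, 0))
    out[rdst, cdst] = image[rsrc, csrc]
    return out


def align_to_central_grid(acq: AcquisitionImage) -> np.ndarray:
    """Re-index a shifted acquisition onto the central acquisition's lab
    grid: detector pixel (r, c) of an acquisition displaced by (dx, dy)
    images lab cell (r + dy, c + dx), so the content is translated by the
    nominal displacement.  The border row/column with no data is NaN."""
    return translate(acq.counts, acq.displacement())


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read a single-page 16-bit grayscale TIFF or a CSV matrix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
        if data.ndim != 2:
            raise DataError(f"{path}: expected a single-page 2D image")
        return data.astype(float)
    return np.loadtxt(path, delimiter=",", dtype=float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a matrix as 16-bit TIFF (rounded) or CSV, by extension."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = np.round(image)
        if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
            raise DataError("image values outside the uint16 range")
        tifffile.imwrite(path, data.astype(np.uint16))
    else:
        np.savetxt(path, image, delimiter=",")
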