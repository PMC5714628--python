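"""Shared domain types for the shift-based EPID intercalibration pipeline.

Conventions used throughout the package
---------------------------------------
* Images are 2D numpy arrays indexed ``[row, col]``; the column index runs
  along the machine left-right axis (x) and the row index along the
  gantry-table axis (y).
* Acquisitions are labelled ``A`` (detector centred on the beam) and
  ``B, C, D, E`` (detector displaced by exactly one grouped pixel along
  +x, -x, +y, -y respectively, in the lab frame).
* The reference pixel of an N x N grid (N even) is the 0-based cell
  ``(N//2, N//2)``; every gain map is normalised to 1 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Nominal lab-frame displacement (dx, dy) of each acquisition, in grouped
#: pixel units.  A detector pixel (row r, col c) of acquisition P images the
#: lab cell (r + dy, c + dx).
SHIFT_VECTORS: dict[str, tuple[int, int]] = {
    "A": (0, 0),
    "B": (1, 0),
    "C": (-1, 0),
    "D": (0, 1),
    "E": (0, -1),
}

POSITIONS = tuple(SHIFT_VECTORS)


class ConfigError(ValueError):
    """Invalid configuration or inconsistent inputs (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid data content, e.g. non-positive counts (CLI exit code 3)."""


def reference_pixel(grid_size: int) -> tuple[int, int]:
    """Default reference pixel of an even ``grid_size`` grid: the cell
    just past the geometric centre, ``(N//2, N//2)``."""
    if grid_size % 2:
        raise ConfigError(f"grid size must be even, got {grid_size}")
    return (grid_size // 2, grid_size // 2)


@dataclass(frozen=True)
class ShiftPlan:
    """The displacement plan of one calibration run.

    Parameters
    ----------
    labels:
        Ordered acquisition labels, exactly one of which must be the
        central (0, 0) entry.
    displacements:
        Lab-frame integer (dx, dy) per label; every shifted entry must have
        unit magnitude (the shift equals the grouped pixel width).
    pixel_size:
        Grouped pixel pitch at the isocenter plane, mm.
    """

    labels: tuple[str, ...]
    displacements: Mapping[str, tuple[int, int]]
    pixel_size: float = 5.0

    def __post_init__(self) -> None:
        centres = [l for l in self.labels if self.displacements[l] == (0, 0)]
        if len(centres) != 1:
            raise ConfigError("shift plan needs exactly one central (0,0) entry")
        for l in self.labels:
            dx, dy = self.displacements[l]
            if l == centres[0]:
                continue
            if abs(dx) + abs(dy) != 1:
                raise ConfigError(
                    f"shifted acquisition {l!r} must be displaced by exactly "
                    f"one pixel along one axis, got {(dx, dy)}"
                )

    @property
    def central_label(self) -> str:
        return next(l for l in self.labels if self.displacements[l] == (0, 0))

    @property
    def horizontal_labels(self) -> tuple[str, ...]:
        """Shifted labels along x, +x first."""
        hs = [l for l in self.labels if self.displacements[l][0] != 0]
        return tuple(sorted(hs, key=lambda l: -self.displacements[l][0]))

    @property
    def vertical_labels(self) -> tuple[str, ...]:
        """Shifted labels along y, +y first."""
        vs = [l for l in self.labels if self.displacements[l][1] != 0]
        return tuple(sorted(vs, key=lambda l: -self.displacements[l][1]))


def default_plan(pixel_size: float = 5.0) -> ShiftPlan:
    """The standard five-acquisition plan A, B, C, D, E."""
    return ShiftPlan(POSITIONS, dict(SHIFT_VECTORS), pixel_size)


def three_acquisition_plan(pixel_size: float = 5.0) -> ShiftPlan:
    """Minimal plan: one central plus one shift per axis (A, B, D)."""
    labels = ("A", "B", "D")
    return ShiftPlan(labels, {l: SHIFT_VECTORS[l] for l in labels}, pixel_size)


@dataclass
class GainMap:
    """A pixel sensitivity map: relative gains normalised to 1 at the
    reference pixel."""

    values: np.ndarray
    ref_pixel: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("gain map must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def normalized(self) -> "GainMap":
        """Return a copy rescaled to exactly 1 at the reference pixel."""
        ref = self.values[self.ref_pixel]
        if ref <= 0:
            raise DataError("gain at reference pixel must be positive")
        return GainMap(self.values / ref, self.ref_pixel)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.values, dtype=dtype)


@dataclass
class AcquisitionImage:
    """One count image plus its shift-position metadata."""

    counts: np.ndarray
    position: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ConfigError("acquisition image must be 2D")

    def displacement(self, plan: ShiftPlan | None = None) -> tuple[int, int]:
        if plan is not None:
            return tuple(plan.displacements[self.position])
        try:
            return SHIFT_VECTORS[self.position]
        except KeyError:
            raise ConfigError(f"unknown position label {self.position!r}") from None


@dataclass
class AcquisitionSet:
    """The collection of acquisitions consumed by one calibration run."""

    images: dict[str, AcquisitionImage]
    plan: ShiftPlan
    truth: dict | None = None  # simulator ground truth, never read by solvers

    def __post_init__(self) -> None:
        shapes = {img.counts.shape for img in self.images.values()}
        if len(shapes) > 1:
            raise ConfigError(f"inconsistent image shapes: {sorted(shapes)}")

    def __getitem__(self, label: str) -> AcquisitionImage:
        try:
            return self.images[label]
        except KeyError:
            raise ConfigError(f"acquisition {label!r} missing from set") from None

    def __contains__(self, label: str) -> bool:
        return label in self.images

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.images)

    @property
    def grid_size(self) -> int:
        shape = next(iter(self.images.values())).counts.shape
        return shape[0]

    def with_counts(self, counts: Mapping[str, np.ndarray]) -> "AcquisitionSet":
        """Copy of the set with some images' counts replaced."""
        images = {
            label: AcquisitionImage(
                counts.get(label, img.counts).copy(), label, dict(img.meta)
            )
            for label, img in self.images.items()
        }
        return AcquisitionSet(images, self.plan, self.truth)
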