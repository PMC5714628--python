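"""Quality-assurance statistics: spread of the eight chained PSMs,
PSM-vs-PSM differences and dose-map comparisons.

Because every gain map is near 1, element-wise differences between maps
are already in relative units; summaries report sample moments of those
differences.  The residuals of a calibration (each chained set minus the
per-pixel mean) quantify the internal consistency of one run: they pool
statistical count fluctuations with any systematic left uncorrected
(positioning error, beam-shape drift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ConfigError, DataError, GainMap
from .doseimage import DoseImage
from .intercalib import CalibrationResult

__all__ = [
    "DiffStats",
    "residual_summary",
    "compare_psm",
    "compare_dose_maps",
    "plot_histogram",
]


@dataclass
class DiffStats:
    """Sample moments and histogram of a difference distribution."""

    mean: float
    std: float
    max_abs: float
    n: int
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)

    def to_dict(self) -> dict:
        counts, edges = self.histogram
        return {
            "mean": self.mean,
            "std": self.std,
            "max_abs": self.max_abs,
            "n": self.n,
            "histogram": {
                "counts": counts.tolist(),
                "bin_edges": edges.tolist(),
            },
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _stats(values: np.ndarray, bins: int = 41) -> DiffStats:
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DataError("no finite values to summarise")
    std = float(v.std(ddof=1)) if v.size > 1 else 0.0
    counts, edges = np.histogram(v, bins=bins)
    return DiffStats(
        mean=float(v.mean()),
        std=std,
        max_abs=float(np.max(np.abs(v))),
        n=int(v.size),
        histogram=(counts, edges),
    )


def residual_summary(result: CalibrationResult, bins: int = 41) -> DiffStats:
    """Pooled distribution of the calibration residuals (one value per
    pixel per chained set; their mean is zero by construction)."""
    return _stats(result.residuals, bins=bins)


def std_map_summary(result: CalibrationResult, bins: int = 41) -> DiffStats:
    """Distribution of the per-pixel standard deviations over the chained
    sets (the calibration's per-pixel uncertainty map)."""
    return _stats(result.psm_std, bins=bins)


def compare_psm(g1: GainMap | np.ndarray, g2: GainMap | np.ndarray,
                bins: int = 41) -> DiffStats:
    """Element-wise difference statistics g1 - g2 of two same-shape gain
    maps (relative units; the maps are ~1)."""
    a = np.asarray(g1.values if isinstance(g1, GainMap) else g1, float)
    b = np.asarray(g2.values if isinstance(g2, GainMap) else g2, float)
    if a.shape != b.shape:
        raise ConfigError(f"shape mismatch: {a.shape} vs {b.shape}")
    return _stats(a - b, bins=bins)


def compare_dose_maps(
    d1: DoseImage | np.ndarray,
    d2: DoseImage | np.ndarray,
    roi: tuple[slice, slice] | None = None,
    norm_region: tuple[slice, slice] | None = None,
    bins: int = 41,
) -> DiffStats:
    """Difference statistics of two relative dose maps on a common grid.

    Both maps are first normalised to their mean over ``norm_region``
    (default: a small central block, the analogue of a 1 x 1 cm reference
    region), making the comparison invariant to a global rescale of
    either map; differences are then evaluated over ``roi`` (default: the
    interior excluding a one-pixel border, keeping clear of edge
    gradients).
    """
    a = np.asarray(d1.values if isinstance(d1, DoseImage) else d1, float)
    b = np.asarray(d2.values if isinstance(d2, DoseImage) else d2, float)
    if a.shape != b.shape:
        raise ConfigError(f"shape mismatch: {a.shape} vs {b.shape}")
    n0, n1 = a.shape
    if roi is None:
        roi = (slice(1, n0 - 1), slice(1, n1 - 1))
    if norm_region is None:
        c0, c1 = n0 // 2, n1 // 2
        h = max(1, min(n0, n1) // 46)  # ~2 grouped pixels on the default grid
        norm_region = (slice(c0 - h, c0 + h), slice(c1 - h, c1 + h))
    if a[roi].size == 0:
        raise ConfigError("empty ROI")
    na, nb = a[norm_region].mean(), b[norm_region].mean()
    if na == 0 or nb == 0:
        raise DataError("normalisation region averages to zero")
    return _stats(a[roi] / na - b[roi] / nb, bins=bins)


def plot_histogram(stats: DiffStats, path: str | Path, title: str = "",
                   xlabel: str = "difference") -> None:
    """Optional PNG histogram of a difference distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, edges = stats.histogram
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.stairs(counts, edges, fill=True, alpha=0.7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("pixels")
    if title:
        ax.set_title(title)
    ax.axvline(stats.mean, color="k", lw=0.8, ls="--")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
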