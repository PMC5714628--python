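"""Shift-based intercalibration: recover the pixel sensitivity map (PSM)
from a five-acquisition set.

Principle
---------
If the beam fluence F is identical across deliveries, a detector pixel
displaced by one pixel pitch sees the lab cell its neighbour saw in the
central acquisition, so the fluence relation F = C * G links neighbouring
gains through count ratios:

    C_A(i+1, j) * G(i+1, j) = C_B(i, j) * G(i, j)

Chaining that relation outward from a reference pixel (fixed at gain 1)
calibrates an entire row or column; a second, orthogonal shift then
extends the single calibrated line to the full matrix.  With four shifted
acquisitions (+x, -x, +y, -y) there are two shifts per axis and two stage
orders per pair, giving eight chained PSMs whose per-pixel mean is the
final map and whose spread measures its uncertainty.

Internally the grid is 0-based and contiguous; the conventional
zero-skipping detector index i in {-M..-1, 1..M} maps to column M-1+i for
i > 0 and M+i for i < 0, placing the reference pixel (1, 1) at (M, M)
with M = N/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AcquisitionSet,
    ConfigError,
    DataError,
    GainMap,
    ShiftPlan,
    reference_pixel,
)

__all__ = [
    "CalibrationResult",
    "chain_gains_1d",
    "chain_gains_1d_closed_form",
    "chain_pms_2d",
    "enumerate_orderings",
    "compute_psm",
]

#: Default floor below which chained counts abort, as a fraction of the
#: line median: chain products through near-zero counts produce wild gains.
DEFAULT_COUNT_FLOOR = 0.01


def _check_line(line: np.ndarray, name: str, count_floor: float) -> None:
    if np.any(line <= 0):
        idx = int(np.argmax(line <= 0))
        raise DataError(f"{name} line has non-positive count at index {idx}")
    floor = count_floor * float(np.median(line))
    low = line < floor
    if np.any(low):
        idx = int(np.argmax(low))
        raise DataError(
            f"{name} line count at index {idx} is below {count_floor:.0%} of "
            "the line median; gains would be unreliable"
        )


def chain_gains_1d(
    central_line: np.ndarray,
    shifted_line: np.ndarray,
    shift_sign: int,
    ref_index: int,
    ref_value: float = 1.0,
    count_floor: float = DEFAULT_COUNT_FLOOR,
) -> np.ndarray:
    """Step-by-step gain recursion along one line.

    ``shift_sign`` is the detector displacement along the line's axis:
    +1 means detector pixel t of the shifted acquisition images lab cell
    t+1 (B/D type), -1 the mirror case (C/E type).  The recursions,
    anchored at ``gain[ref_index] = ref_value``, are

        +1:  gain[t+1] = shifted[t]   / central[t+1] * gain[t]
             gain[t-1] = central[t]   / shifted[t-1] * gain[t]
        -1:  gain[t+1] = central[t]   / shifted[t+1] * gain[t]
             gain[t-1] = shifted[t]   / central[t-1] * gain[t]
    """
    c = np.asarray(central_line, float)
    s = np.asarray(shifted_line, float)
    if c.shape != s.shape or c.ndim != 1:
        raise ConfigError("central and shifted lines must be equal-length 1D")
    n = c.size
    if not 0 <= ref_index < n:
        raise ConfigError(f"ref_index {ref_index} outside line of length {n}")
    if shift_sign not in (1, -1):
        raise ConfigError("shift_sign must be +1 or -1")
    _check_line(c, "central", count_floor)
    _check_line(s, "shifted", count_floor)

    g = np.empty(n)
    g[ref_index] = ref_value
    if shift_sign == 1:
        for t in range(ref_index, n - 1):
            g[t + 1] = s[t] / c[t + 1] * g[t]
        for t in range(ref_index, 0, -1):
            g[t - 1] = c[t] / s[t - 1] * g[t]
    else:
        for t in range(ref_index, n - 1):
            g[t + 1] = c[t] / s[t + 1] * g[t]
        for t in range(ref_index, 0, -1):
            g[t - 1] = s[t] / c[t - 1] * g[t]
    return g


def chain_gains_1d_closed_form(
    central_line: np.ndarray,
    shifted_line: np.ndarray,
    shift_sign: int,
    ref_index: int,
    ref_value: float = 1.0,
    count_floor: float = DEFAULT_COUNT_FLOOR,
) -> np.ndarray:
    """Closed-form chain: the same gains as :func:`chain_gains_1d`,
    computed as cumulative products of count ratios.  Kept as an
    independent route for cross-checks."""
    c = np.asarray(central_line, float)
    s = np.asarray(shifted_line, float)
    if c.shape != s.shape or c.ndim != 1:
        raise ConfigError("central and shifted lines must be equal-length 1D")
    n = c.size
    if not 0 <= ref_index < n:
        raise ConfigError(f"ref_index {ref_index} outside line of length {n}")
    if shift_sign not in (1, -1):
        raise ConfigError("shift_sign must be +1 or -1")
    _check_line(c, "central", count_floor)
    _check_line(s, "shifted", count_floor)

    g = np.empty(n)
    g[ref_index] = ref_value
    t_up = np.arange(ref_index, n - 1)       # step t -> t+1
    t_down = np.arange(ref_index, 0, -1)     # step t -> t-1
    if shift_sign == 1:
        up = s[t_up] / c[t_up + 1]
        down = c[t_down] / s[t_down - 1]
    else:
        up = c[t_up] / s[t_up + 1]
        down = s[t_down] / c[t_down - 1]
    g[ref_index + 1:] = ref_value * np.cumprod(up)
    if ref_index > 0:
        g[ref_index - 1::-1] = ref_value * np.cumprod(down)
    return g


def _axis_sign(plan: ShiftPlan, label: str, axis: int) -> int:
    d = plan.displacements[label][axis]
    if d == 0:
        raise ConfigError(
            f"acquisition {label!r} has no displacement along axis {axis}"
        )
    return 1 if d > 0 else -1


def chain_pms_2d(
    aset: AcquisitionSet,
    horizontal: str,
    vertical: str,
    order: str,
    ref: tuple[int, int] | None = None,
    count_floor: float = DEFAULT_COUNT_FLOOR,
) -> GainMap:
    """One globally chained PSM from a (horizontal, vertical) shift pair.

    ``order`` selects the stage sequence: ``"HV"`` calibrates the
    reference row with the horizontal acquisition and then every column
    with the vertical one, anchored on that row; ``"VH"`` is the
    transpose-order analogue.  The output is normalised to 1 at ``ref``.
    """
    if order not in ("HV", "VH"):
        raise ConfigError("order must be 'HV' or 'VH'")
    central = aset[aset.plan.central_label].counts
    h_img = aset[horizontal].counts
    v_img = aset[vertical].counts
    n = central.shape[0]
    if ref is None:
        ref = reference_pixel(n)
    ref_r, ref_c = ref
    hsign = _axis_sign(aset.plan, horizontal, 0)
    vsign = _axis_sign(aset.plan, vertical, 1)

    g = np.empty((n, n))
    if order == "HV":
        row = chain_gains_1d(central[ref_r, :], h_img[ref_r, :], hsign,
                             ref_c, 1.0, count_floor)
        for c in range(n):
            g[:, c] = chain_gains_1d(central[:, c], v_img[:, c], vsign,
                                     ref_r, row[c], count_floor)
    else:
        col = chain_gains_1d(central[:, ref_c], v_img[:, ref_c], vsign,
                             ref_r, 1.0, count_floor)
        for r in range(n):
            g[r, :] = chain_gains_1d(central[r, :], h_img[r, :], hsign,
                                     ref_c, col[r], count_floor)
    return GainMap(g, ref).normalized()


def enumerate_orderings(plan: ShiftPlan) -> list[tuple[str, str, str]]:
    """All (horizontal, vertical, order) triples the plan supports.

    The standard five-acquisition plan yields eight; a three-acquisition
    plan (one shift per axis) yields two.  Order is deterministic:
    +x before -x, +y before -y, HV before VH.
    """
    hs = plan.horizontal_labels
    vs = plan.vertical_labels
    if not hs or not vs:
        raise ConfigError("plan needs at least one shift along each axis")
    return [(h, v, order) for h in hs for v in vs for order in ("HV", "VH")]


def ordering_label(h: str, v: str, order: str) -> str:
    """Conventional key of one chained set: first-stage label first
    (e.g. (B, D, HV) -> 'BD', (B, D, VH) -> 'DB')."""
    return h + v if order == "HV" else v + h


@dataclass
class CalibrationResult:
    """Eight chained PSMs plus their per-pixel mean, spread and residuals.

    ``psm_std`` is the per-pixel sample (n-1) standard deviation over the
    chained sets; ``residuals[k]`` is set k minus the mean map, so the
    residuals at each pixel sum to zero by construction.
    """

    psm_sets: dict[str, GainMap]
    psm_mean: GainMap
    psm_std: np.ndarray
    residuals: np.ndarray
    orderings: list[tuple[str, str, str]]
    output_factors: dict[str, float] | None = None

    @property
    def n_sets(self) -> int:
        return len(self.psm_sets)


def compute_psm(
    aset: AcquisitionSet,
    *,
    output_correction: bool = True,
    k: int | None = None,
    ref: tuple[int, int] | None = None,
    count_floor: float = DEFAULT_COUNT_FLOOR,
) -> CalibrationResult:
    """Full calibration of one acquisition set.

    When ``output_correction`` is enabled, each shifted acquisition is
    first rescaled by its beam-output factor f relative to the central
    one; the chained PSMs are then computed for every ordering the plan
    supports, averaged per pixel (arithmetic mean, renormalised to 1 at
    the reference pixel) and summarised by their sample spread.
    """
    factors = None
    if output_correction:
        from .corrections import apply_output_corrections

        aset, factors = apply_output_corrections(aset, k=k)

    n = aset.grid_size
    if ref is None:
        ref = reference_pixel(n)
    orderings = enumerate_orderings(aset.plan)
    sets: dict[str, GainMap] = {}
    for h, v, order in orderings:
        sets[ordering_label(h, v, order)] = chain_pms_2d(
            aset, h, v, order, ref, count_floor
        )
    stack = np.stack([g.values for g in sets.values()])
    mean = stack.mean(axis=0)
    mean /= mean[ref]  # exact normalisation at the reference pixel
    std = stack.std(axis=0, ddof=1) if len(sets) > 1 else np.zeros_like(mean)
    residuals = stack - mean
    return CalibrationResult(
        psm_sets=sets,
        psm_mean=GainMap(mean, ref),
        psm_std=std,
        residuals=residuals,
        orderings=orderings,
        output_factors=factors,
    )
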