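"""Inter-acquisition beam corrections.

Two perturbations violate the constant-beam assumption behind the chained
calibration and are corrected here:

* **Output variation** — the delivered fluence drifts between consecutive
  irradiations (monitor-chamber non-linearity, order +/-0.2%).  The error is
  systematic: an uncorrected scale factor s multiplies every count ratio,
  so the chained gain error grows with distance from the reference pixel.
  The factor f that rescales a shifted acquisition back onto the central
  one follows from matching products of counts over aligned windows on the
  central profile, exploiting the near-symmetry of the flood-field
  calibrated gains about the beam axis.

* **Symmetry variation** — the beam profile occasionally tilts between
  deliveries (observed in the gantry-table direction, up to +/-0.15%),
  modelled as a single-lobe sine, pert(y) = u * sin(pi * y / length).  The
  amplitude is estimated from the relative difference between calibrated
  central and shifted images and removed iteratively: calibrate, fit u per
  shifted acquisition, divide its counts by (1 + pert), recompute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    AcquisitionImage,
    AcquisitionSet,
    ConfigError,
    DataError,
)
from .imageprep import align_to_central_grid
from .intercalib import CalibrationResult, compute_psm

__all__ = [
    "OutputCorrection",
    "SymmetryCorrection",
    "SymmetryLoopResult",
    "output_factor",
    "apply_output_correction",
    "apply_output_corrections",
    "fit_symmetry_u",
    "symmetry_loop",
]


@dataclass(frozen=True)
class OutputCorrection:
    """Beam-output factor of one shifted acquisition."""

    f: float
    k: int

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise DataError("output factor must be positive")
        if self.k < 1:
            raise ConfigError("window half-width k must be >= 1")


@dataclass
class SymmetryCorrection:
    """Fitted sine-tilt amplitude of one shifted acquisition."""

    u: float
    axis: str
    length: float
    iterations_used: int

    def __post_init__(self) -> None:
        if abs(self.u) >= 0.05:
            raise DataError(f"|u| = {abs(self.u):.3g} outside model validity")
        if self.length <= 0:
            raise ConfigError("profile length must be positive")


# --------------------------------------------------------------------------
# Output variation
# --------------------------------------------------------------------------

def output_factor(
    central_line: np.ndarray,
    shifted_line: np.ndarray,
    shift_sign: int,
    k: int | None = None,
) -> float:
    """Beam-output correction factor of a shifted acquisition.

    Matching the windowed count products of the central and shifted
    profiles along the shifting direction gives

        f = (prod central window / prod shifted window) ** (1 / 2k)

    where each window holds 2k pixels centred on the reference pixel,
    the shifted window being the central one displaced by one pixel
    against the shift so that both windows sample the same lab cells.
    The residual gain ratio G(ref-k)/G(ref+k) cancels for gains symmetric
    about the beam axis (the flood-field calibration guarantees this to
    good approximation).  The default k = N/2 - 3 excludes the external
    three pixels per side.  Computed in log space: the raw 40-term count
    products overflow float64.
    """
    c = np.asarray(central_line, float)
    s = np.asarray(shifted_line, float)
    if c.shape != s.shape or c.ndim != 1:
        raise ConfigError("central and shifted lines must be equal-length 1D")
    if shift_sign not in (1, -1):
        raise ConfigError("shift_sign must be +1 or -1")
    n = c.size
    m = n // 2
    if k is None:
        k = m - 3
    else:
        k = int(k)
        if k != m - 3:
            warnings.warn(
                f"output-factor window k={k} differs from the default "
                f"N/2-3={m - 3}", stacklevel=2,
            )
    if k < 1:
        raise ConfigError("window half-width k must be >= 1")
    if shift_sign == 1:
        c_sl = slice(m - k + 1, m + k + 1)
        s_sl = slice(m - k, m + k)
    else:
        c_sl = slice(m - k, m + k)
        s_sl = slice(m - k + 1, m + k + 1)
    if c_sl.start < 0 or c_sl.stop > n or s_sl.start < 0 or s_sl.stop > n:
        raise ConfigError(f"window k={k} exceeds the profile of length {n}")
    cw, sw = c[c_sl], s[s_sl]
    if np.any(cw <= 0) or np.any(sw <= 0):
        raise DataError("non-positive count inside the output-factor window")
    return float(np.exp((np.log(cw).sum() - np.log(sw).sum()) / (2 * k)))


def apply_output_correction(acq: AcquisitionImage, f: float) -> AcquisitionImage:
    """Multiply every count by f; the factor is recorded in the metadata."""
    if f <= 0:
        raise DataError("output factor must be positive")
    meta = dict(acq.meta)
    meta["output_factor_applied"] = f
    return AcquisitionImage(acq.counts * f, acq.position, meta)


def apply_output_corrections(
    aset: AcquisitionSet, k: int | None = None
) -> tuple[AcquisitionSet, dict[str, float]]:
    """Correct every shifted acquisition of a set against the central one.

    The profile used is the one lying on the shifting direction: the
    central row through the reference pixel for x-shifts, the central
    column for y-shifts.
    """
    n = aset.grid_size
    ref_r = ref_c = n // 2
    central = aset[aset.plan.central_label].counts
    factors: dict[str, float] = {}
    images = {}
    for label, img in aset.images.items():
        dx, dy = img.displacement(aset.plan)
        if (dx, dy) == (0, 0):
            images[label] = img
            continue
        if dx != 0:
            f = output_factor(central[ref_r, :], img.counts[ref_r, :],
                              1 if dx > 0 else -1, k)
        else:
            f = output_factor(central[:, ref_c], img.counts[:, ref_c],
                              1 if dy > 0 else -1, k)
        factors[label] = f
        images[label] = apply_output_correction(img, f)
    return AcquisitionSet(images, aset.plan, aset.truth), factors


# --------------------------------------------------------------------------
# Symmetry variation
# --------------------------------------------------------------------------

def fit_symmetry_u(
    diff_profile: np.ndarray,
    length: float,
    positions: np.ndarray | None = None,
) -> float:
    """Least-squares amplitude of u * sin(pi * y / length) fitted to a
    relative-difference profile.

    ``positions`` are the sample coordinates y measured from the profile
    centre (the beam axis), so the basis is the odd tilt whose sign sets
    the slope of the asymmetry; by default the samples sit at pixel
    centres i - (n-1)/2.  The single-basis least-squares solution is
    closed form: u = sum(d * s) / sum(s^2).
    """
    d = np.asarray(diff_profile, float)
    if d.ndim != 1:
        raise ConfigError("difference profile must be 1D")
    if not np.all(np.isfinite(d)):
        raise DataError("difference profile contains non-finite values")
    if positions is None:
        positions = np.arange(d.size) - (d.size - 1) / 2.0
    s = np.sin(np.pi * np.asarray(positions, float) / length)
    denom = float(np.sum(s * s))
    if denom <= 0:
        raise ConfigError("degenerate sine basis (check length/positions)")
    return float(np.sum(d * s) / denom)


def _pert_factor(
    n: int, u: float, displacement: tuple[int, int], axis: str
) -> np.ndarray:
    """Multiplicative (1 + pert) matrix at the lab coordinates a displaced
    detector images; y is measured from the beam axis (odd tilt)."""
    dx, dy = displacement
    half = (n - 1) / 2.0
    idx = np.arange(n, dtype=float)
    if axis == "y":
        fac = 1.0 + u * np.sin(np.pi * (idx + dy - half) / n)
        return np.repeat(fac[:, None], n, axis=1)
    fac = 1.0 + u * np.sin(np.pi * (idx + dx - half) / n)
    return np.repeat(fac[None, :], n, axis=0)


@dataclass
class SymmetryLoopResult:
    """Outcome of the iterative symmetry correction."""

    corrected_set: AcquisitionSet
    calibration: CalibrationResult
    corrections: dict[str, SymmetryCorrection]
    iterations: int
    converged: bool


def symmetry_loop(
    aset: AcquisitionSet,
    *,
    max_iter: int = 5,
    tol: float = 1e-5,
    axis: str = "y",
    margin: int = 3,
    ref: tuple[int, int] | None = None,
    count_floor: float | None = None,
) -> SymmetryLoopResult:
    """Iteratively remove the beam-symmetry perturbation from a set.

    The beam-output correction is assumed already applied.  Each pass:

    1. compute the mean PSM of the current set;
    2. calibrate all acquisitions (counts x PSM) and align each shifted
       one to the central lab grid;
    3. average the relative difference to the calibrated central image
       over the transverse direction inside the ROI (``margin`` pixels
       excluded per side) to get one profile per shifted acquisition;
    4. fit the sine amplitude of each profile, attribute the correction
       (see below) and divide the *original* shifted counts by
       (1 + u sin(pi y / N)) evaluated at each acquisition's lab rows.

    Attribution.  A tilt pair (+d, -d) on the two opposite-shift
    acquisitions of one axis is, to first order, indistinguishable from a
    smooth redefinition of the gain map and the beam: only the pair's
    summed amplitude is observable, and the chained-PSM bias it creates
    feeds half of it into *both* members' difference profiles.  The loop
    therefore corrects per axis pair: the summed fitted amplitude is
    assigned entirely to one member, chosen by tentatively applying
    either attribution and keeping the one that leaves the smaller
    residual fitted amplitudes (a second-order observable that does
    separate the members).  Under the operating assumption that symmetry
    excursions affect one delivery at a time, this recovers the full
    amplitude on the perturbed acquisition.

    The loop stops when every fitted |u| falls below ``tol`` or after
    ``max_iter`` passes (flagged, never silent).
    """
    if axis not in ("x", "y"):
        raise ConfigError("axis must be 'x' or 'y'")
    n = aset.grid_size
    if margin < 1 or 2 * margin >= n - 2:
        raise ConfigError(f"margin {margin} incompatible with grid size {n}")
    floor_kw = {} if count_floor is None else {"count_floor": count_floor}
    plan = aset.plan
    central_label = plan.central_label
    shifted = [l for l in aset.labels if l != central_label]
    # opposite-displacement pairs share one gauge freedom each
    pairs = [p for p in (plan.horizontal_labels, plan.vertical_labels) if p]
    originals = {l: aset[l].counts.copy() for l in aset.labels}
    u_total = {l: 0.0 for l in shifted}

    interior = slice(margin, n - margin)
    trans_axis = 1 if axis == "y" else 0
    positions = np.arange(margin, n - margin) - (n - 1) / 2.0

    def corrected_set(u: dict[str, float]) -> AcquisitionSet:
        counts = {central_label: originals[central_label]}
        for l in shifted:
            d = aset[l].displacement(plan)
            counts[l] = originals[l] / _pert_factor(n, u[l], d, axis)
        return aset.with_counts(counts)

    def fit_amplitudes(
        current: AcquisitionSet,
    ) -> tuple[CalibrationResult, dict[str, float]]:
        result = compute_psm(current, output_correction=False, ref=ref,
                             **floor_kw)
        psm = result.psm_mean.values
        cal_central = current[central_label].counts * psm
        fits = {}
        for l in shifted:
            cal = AcquisitionImage(current[l].counts * psm, l)
            aligned = align_to_central_grid(cal)
            rel = (aligned - cal_central) / cal_central
            profile = np.nanmean(rel[interior, interior], axis=trans_axis)
            fits[l] = fit_symmetry_u(profile, float(n), positions)
        return result, fits

    if max_iter < 1:
        raise ConfigError("max_iter must be >= 1")
    converged = False
    iterations = 0
    fits: dict[str, float] = {}
    for iterations in range(1, max_iter + 1):
        result, fits = fit_amplitudes(corrected_set(u_total))
        # convergence is judged on the observable (each pair's summed
        # amplitude): an equal-and-opposite residual within a pair is the
        # gauge mode, invisible to first order and not correctable
        if max(abs(sum(fits[l] for l in pair)) for pair in pairs) < tol:
            converged = True
            break
        for pair in pairs:
            total = sum(fits[l] for l in pair)
            if abs(total) < tol:
                continue
            if len(pair) == 1:
                u_total[pair[0]] += total
                continue
            best = None
            for candidate in pair:
                trial = dict(u_total)
                trial[candidate] += total
                _, trial_fits = fit_amplitudes(corrected_set(trial))
                score = sum(v * v for v in trial_fits.values())
                if best is None or score < best[0]:
                    best = (score, trial)
            u_total = best[1]

    final_set = corrected_set(u_total)
    final_result = compute_psm(final_set, output_correction=False, ref=ref,
                               **floor_kw)
    if not converged:
        warnings.warn(
            f"symmetry correction did not converge in {max_iter} iterations "
            f"(last fitted amplitudes: {fits})", stacklevel=2,
        )
    corrections = {
        l: SymmetryCorrection(u_total[l], axis, float(n), iterations)
        for l in shifted
    }
    return SymmetryLoopResult(final_set, final_result, corrections,
                              iterations, converged)
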