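"""Synthetic acquisition generator with known ground truth.

The intercalibration solver never sees the true beam fluence or the true
gain map; this module builds both, together with the perturbations a real
linac run exhibits (output drift between deliveries, a sine-shaped symmetry
tilt, sub-pixel positioning error and multiplicative count noise), so every
solver stage can be checked against an exact oracle.

The count model inverts the fluence relation F = C * G: an acquisition at
displacement d produces, at detector pixel (r, c),

    C(r, c) = s * (1 + u * sin(pi * (y_lab + 1/2) / N)) * F(lab cell) / G(r, c)

where the lab cell is the detector index plus the nominal shift plus any
shift error, s is the per-delivery output scale and u the symmetry-tilt
amplitude of that delivery.  Counts are generated at the flood-field
corrected level: the gain map G sits on top of the corrections already
applied by the acquisition software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .core import (
    SHIFT_VECTORS,
    AcquisitionImage,
    AcquisitionSet,
    ConfigError,
    DataError,
    GainMap,
    ShiftPlan,
    default_plan,
    reference_pixel,
)

__all__ = [
    "BeamModel",
    "TrueGainMapSpec",
    "PerturbationSpec",
    "make_beam_fluence",
    "make_true_gain_map",
    "simulate_acquisition",
    "simulate_calibration_set",
    "simulate_raw_triplet",
    "write_acquisition_set",
    "read_acquisition_set",
]


# --------------------------------------------------------------------------
# Beam model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamModel:
    """Radially symmetric open-field fluence model.

    The profile is a low-order polynomial in the scaled radius r/r0
    (r0 = field_width / 2) rolled off by a sigmoid penumbra:

        F(r) = bg + (F0 - bg) * (1 + c2 (r/r0)^2 + c4 (r/r0)^4) * sigmoid((r0 - r)/p)

    All lengths are in grouped-pixel units at the isocenter plane.  The
    form is a simulator choice: the solver only requires a smooth,
    reproducible, non-flat field, and the model is evaluable at any
    real-valued lab coordinate (needed for sub-pixel shift errors).
    """

    field_width: float = 70.0
    central_fluence: float = 30000.0
    radial_coeffs: tuple[float, float] = (-0.03, 0.0)
    penumbra_width: float = 2.0
    background: float = 300.0

    def __post_init__(self) -> None:
        if self.central_fluence <= 0:
            raise ConfigError("central_fluence must be positive")
        if self.field_width <= 0:
            raise ConfigError("field_width must be positive")
        if self.penumbra_width <= 0:
            raise ConfigError("penumbra_width must be positive")

    def fluence(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Fluence at lab coordinates (x, y), grouped-pixel units from the
        beam axis."""
        c2, c4 = self.radial_coeffs
        r0 = self.field_width / 2.0
        r = np.hypot(np.asarray(x, float), np.asarray(y, float))
        rho2 = (r / r0) ** 2
        shape = 1.0 + c2 * rho2 + c4 * rho2**2
        edge = expit((r0 - r) / self.penumbra_width)
        return self.background + (self.central_fluence - self.background) * shape * edge


def make_beam_fluence(
    beam: BeamModel, grid_size: int, offset: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Evaluate the beam on an N x N grid of lab cell centres displaced by
    ``offset`` (dx, dy).

    The grid centre coincides with the beam axis at zero offset; cell (r, c)
    sits at lab coordinates (c - (N-1)/2 + dx, r - (N-1)/2 + dy).
    """
    if grid_size % 2:
        raise ConfigError("grid_size must be even")
    half = (grid_size - 1) / 2.0
    dx, dy = offset
    x = np.arange(grid_size) - half + dx
    y = np.arange(grid_size) - half + dy
    f = beam.fluence(x[np.newaxis, :], y[:, np.newaxis])
    if np.any(f <= 0):
        raise DataError("beam model produced non-positive fluence on the grid")
    return f


# --------------------------------------------------------------------------
# True gain map
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueGainMapSpec:
    """Ground-truth gain map: smooth low-frequency structure plus an iid
    per-pixel spread, all near unity.

    ``symmetrize`` mirrors the smooth component about the reference row and
    column, emulating the near-symmetry that the flood-field calibration
    leaves in a real panel (the assumption behind the output-factor
    correction).
    """

    grid_size: int = 46
    smooth_amplitude: float = 0.02
    pixel_sigma: float = 0.005
    seed: int = 0
    symmetrize: bool = False

    def __post_init__(self) -> None:
        if self.pixel_sigma < 0:
            raise ConfigError("pixel_sigma must be >= 0")
        if self.grid_size % 2:
            raise ConfigError("grid_size must be even")


def _smooth_field(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude smooth random field from a handful of low-order
    cosine modes."""
    half = (n - 1) / 2.0
    x = (np.arange(n) - half) / half  # [-1, 1]
    X, Y = np.meshgrid(x, x)
    modes = [(1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2)]
    out = np.zeros((n, n))
    for kx, ky in modes:
        amp = rng.normal()
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(0.5 * np.pi * (kx * X + ky * Y) + phase)
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def _mirror(a: np.ndarray, axis: int) -> np.ndarray:
    # reflection c -> 2M - c (mod N): symmetric about the reference index M
    return np.roll(np.flip(a, axis=axis), 1, axis=axis)


def make_true_gain_map(spec: TrueGainMapSpec) -> GainMap:
    """Build the ground-truth gain map; reproducible under a fixed seed,
    exactly 1 at the reference pixel."""
    n = spec.grid_size
    ref = reference_pixel(n)
    rng = np.random.default_rng(spec.seed)
    smooth = _smooth_field(n, rng)
    if spec.symmetrize:
        smooth = (
            smooth
            + _mirror(smooth, 0)
            + _mirror(smooth, 1)
            + _mirror(_mirror(smooth, 0), 1)
        ) / 4.0
    g = 1.0 + spec.smooth_amplitude * smooth
    if spec.pixel_sigma > 0:
        g = g + rng.normal(0.0, spec.pixel_sigma, size=(n, n))
    if np.any(g <= 0):
        raise DataError("gain map has non-positive entries; reduce amplitudes")
    return GainMap(g, ref).normalized()


# --------------------------------------------------------------------------
# Perturbations
# --------------------------------------------------------------------------

_SHIFTED = ("B", "C", "D", "E")


@dataclass(frozen=True)
class PerturbationSpec:
    """Per-acquisition beam perturbations injected by the simulator.

    Fields
    ------
    output_scales:
        Output multiplier s per acquisition (run-to-run drift of the
        delivered fluence; observed range order 1 +/- 0.002).
    symmetry_u:
        Sine-tilt amplitude u per acquisition along ``symmetry_axis``
        (observed only in the gantry-table direction, order +/- 0.0015).
    shift_error:
        Real-valued (dx, dy) displacement error per acquisition in
        grouped-pixel units (|.| < 0.5).
    noise_sigma:
        Relative multiplicative Gaussian count noise (frame-averaged counts
        are high, so Poisson is well approximated).
    """

    output_scales: dict[str, float] = field(default_factory=dict)
    symmetry_u: dict[str, float] = field(default_factory=dict)
    symmetry_axis: str = "y"
    shift_error: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_sigma: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.output_scales.values():
            if s <= 0:
                raise ConfigError("output scales must be positive")
        for u in self.symmetry_u.values():
            if abs(u) >= 0.05:
                raise ConfigError("|symmetry_u| must be < 0.05 (model validity)")
        for dx, dy in self.shift_error.values():
            if max(abs(dx), abs(dy)) >= 0.5:
                raise ConfigError("shift error must stay below half a pixel")
        if self.symmetry_axis not in ("x", "y"):
            raise ConfigError("symmetry_axis must be 'x' or 'y'")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")

    @classmethod
    def none(cls, seed: int = 0) -> "PerturbationSpec":
        """No perturbation of any kind."""
        return cls(noise_sigma=0.0, seed=seed)

    @classmethod
    def sampled(
        cls,
        seed: int = 0,
        *,
        output_range: float = 0.002,
        symmetry_range: float = 0.0015,
        noise_sigma: float = 0.001,
        symmetry_axis: str = "y",
    ) -> "PerturbationSpec":
        """Draw realistic per-acquisition perturbations: output scales
        uniform in 1 +/- output_range, symmetry tilt uniform in
        +/- symmetry_range on the shifted acquisitions."""
        rng = np.random.default_rng(seed)
        scales = {
            l: float(rng.uniform(1 - output_range, 1 + output_range))
            for l in _SHIFTED
        }
        u = {
            l: float(rng.uniform(-symmetry_range, symmetry_range))
            for l in _SHIFTED
        }
        return cls(
            output_scales=scales,
            symmetry_u=u,
            symmetry_axis=symmetry_axis,
            noise_sigma=noise_sigma,
            seed=seed,
        )


def symmetry_factor(
    grid_size: int, u: float, displacement: tuple[int, int], axis: str = "y"
) -> np.ndarray:
    """Per-pixel multiplicative symmetry perturbation 1 + u sin(pi y / length),
    evaluated at the lab coordinates the displaced detector images.

    ``y`` is measured from the beam axis (the centre of the central grid)
    and ``length`` is the profile extent N, so the perturbation is an odd
    tilt: zero on the central axis, approaching +/-u at the profile ends,
    with the sign of u setting the slope of the asymmetry.
    """
    dx, dy = displacement
    half = (grid_size - 1) / 2.0
    idx = np.arange(grid_size, dtype=float)
    if axis == "y":
        lab = idx + dy - half
        fac = 1.0 + u * np.sin(np.pi * lab / grid_size)
        return fac[:, np.newaxis] * np.ones((1, grid_size))
    if axis == "x":
        lab = idx + dx - half
        fac = 1.0 + u * np.sin(np.pi * lab / grid_size)
        return np.ones((grid_size, 1)) * fac[np.newaxis, :]
    raise ConfigError("axis must be 'x' or 'y'")


# --------------------------------------------------------------------------
# Acquisition synthesis
# --------------------------------------------------------------------------

def simulate_acquisition(
    beam: BeamModel,
    gains: GainMap,
    position: str,
    pert: PerturbationSpec | None = None,
) -> AcquisitionImage:
    """Synthesise the count image of one acquisition at ``position``."""
    if position not in SHIFT_VECTORS:
        raise ConfigError(f"unknown position label {position!r}")
    if np.any(gains.values == 0):
        raise DataError("gain map contains zeros")
    pert = pert if pert is not None else PerturbationSpec()
    n = gains.shape[0]
    dx, dy = SHIFT_VECTORS[position]
    edx, edy = pert.shift_error.get(position, (0.0, 0.0))
    fluence = make_beam_fluence(beam, n, (dx + edx, dy + edy))
    scale = pert.output_scales.get(position, 1.0)
    u = pert.symmetry_u.get(position, 0.0)
    counts = scale * fluence / gains.values
    if u:
        counts = counts * symmetry_factor(n, u, (dx, dy), pert.symmetry_axis)
    if pert.noise_sigma > 0:
        # independent stream per position so single acquisitions are
        # reproducible regardless of simulation order
        rng = np.random.default_rng([pert.seed, ord(position)])
        counts = counts * (1.0 + rng.normal(0.0, pert.noise_sigma, counts.shape))
    counts = np.clip(counts, 0.0, None)
    meta = {"output_scale": scale, "symmetry_u": u, "shift_error": (edx, edy)}
    return AcquisitionImage(counts, position, meta)


def simulate_calibration_set(
    beam: BeamModel | None = None,
    gains: GainMap | TrueGainMapSpec | None = None,
    pert: PerturbationSpec | None = None,
    plan: ShiftPlan | None = None,
) -> AcquisitionSet:
    """Synthesise a full five-acquisition calibration set (A, B, C, D, E).

    Ground truth (beam, gain map, perturbation spec) is stored on the
    returned set for test harnesses; solvers must not read it.
    """
    beam = beam or BeamModel()
    if gains is None:
        gains = make_true_gain_map(TrueGainMapSpec())
    elif isinstance(gains, TrueGainMapSpec):
        gains = make_true_gain_map(gains)
    pert = pert if pert is not None else PerturbationSpec()
    plan = plan or default_plan()
    images = {
        label: simulate_acquisition(beam, gains, label, pert)
        for label in plan.labels
    }
    truth = {"beam": beam, "gains": gains, "pert": pert}
    return AcquisitionSet(images, plan, truth)


def simulate_raw_triplet(
    im_epid: np.ndarray,
    seed: int = 0,
    *,
    dark_level: float = 120.0,
    flood_shape_amp: float = 0.15,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose a flood-field corrected image into a consistent
    (raw, dark, flood) triplet for exercising the image-prep path.

    The flood carries a smooth bowl shape (the beam profile it absorbed)
    and the dark field a constant offset; by construction
    (raw - dark) / flood * mean(flood) equals ``im_epid`` exactly up to
    rounding-free float arithmetic.
    """
    im = np.asarray(im_epid, float)
    n0, n1 = im.shape
    rng = np.random.default_rng(seed)
    y = np.linspace(-1, 1, n0)[:, None]
    x = np.linspace(-1, 1, n1)[None, :]
    flood = 1.0 - flood_shape_amp * (x**2 + y**2) / 2.0
    flood = flood * (1.0 + 0.01 * rng.standard_normal((n0, n1)))
    if np.any(flood <= 0):
        raise DataError("generated flood field not strictly positive")
    dark = np.full_like(im, dark_level)
    raw = im * flood / flood.mean() + dark
    return raw, dark, flood


# --------------------------------------------------------------------------
# Disk round-trip (16-bit TIFF + manifest)
# --------------------------------------------------------------------------

def write_acquisition_set(aset: AcquisitionSet, outdir: str | Path) -> Path:
    """Write the set as five 16-bit TIFFs plus a JSON manifest; the truth
    gain map (if present) goes to a CSV alongside."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak = max(float(img.counts.max()) for img in aset.images.values())
    # headroom so perturbed acquisitions never clip at the uint16 ceiling
    scale = 60000.0 / peak if peak > 0 else 1.0
    manifest: dict = {
        "pixel_size_mm": aset.plan.pixel_size,
        "count_scale": scale,
        "acquisitions": {},
    }
    for label, img in aset.images.items():
        fname = f"acq_{label}.tif"
        data = np.round(img.counts * scale).astype(np.uint16)
        tifffile.imwrite(outdir / fname, data)
        manifest["acquisitions"][label] = {
            "file": fname,
            "displacement": list(img.displacement(aset.plan)),
            "meta": {k: v for k, v in img.meta.items() if k != "shift_error"},
        }
    if aset.truth is not None:
        np.savetxt(outdir / "truth_gains.csv", aset.truth["gains"].values,
                   delimiter=",")
        manifest["truth_gains"] = "truth_gains.csv"
        manifest["seed"] = aset.truth["pert"].seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def read_acquisition_set(manifest_path: str | Path) -> AcquisitionSet:
    """Load a set written by :func:`write_acquisition_set`."""
    import tifffile

    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    scale = float(manifest.get("count_scale", 1.0))
    images = {}
    displacements = {}
    for label, entry in manifest["acquisitions"].items():
        data = tifffile.imread(root / entry["file"]).astype(float) / scale
        images[label] = AcquisitionImage(data, label, dict(entry.get("meta", {})))
        displacements[label] = tuple(entry["displacement"])
    plan = ShiftPlan(tuple(images), displacements,
                     float(manifest.get("pixel_size_mm", 5.0)))
    truth = None
    if "truth_gains" in manifest:
        g = np.loadtxt(root / manifest["truth_gains"], delimiter=",")
        truth = {"gains": GainMap(g, reference_pixel(g.shape[0]))}
    return AcquisitionSet(images, plan, truth)
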