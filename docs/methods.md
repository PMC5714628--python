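# Methods

This note documents the model behind `epidcal`, the numerical choices,
the design decisions that were genuinely open, and what the synthetic
test bed does and does not establish about real detector data.

## 1. The intercalibration model

The detector is an N x N matrix of grouped pixels (N even); each pixel has
an unknown relative gain `G(r, c)` near 1, and an acquisition delivers a
smooth fluence `F` such that counts obey `F = C * G`. A calibration run
consists of one central acquisition `A` and four acquisitions with the
detector displaced by exactly one grouped-pixel pitch: `B` (+x), `C` (−x),
`D` (+y), `E` (−y), lab frame, x = left-right, y = gantry-table. The
working assumption is that the integrated fluence and the beam shape are
identical across the five deliveries; everything else in the method exists
to enforce or relax that assumption.

Because pixel `(r, c)` of a +x-shifted acquisition images the lab cell
`(r, c+1)`, the fluence-match identity

    C_A(r, c+1) G(r, c+1) = C_B(r, c) G(r, c)

links neighbouring gains through measured count ratios. Fixing `G = 1`
at the reference pixel — the 0-based cell `(N/2, N/2)`, i.e. the
conventional centre pixel of the panel — and applying the identity
recursively calibrates the full reference row (with `B` or `C`) or the
full reference column (with `D` or `E`). A second stage with the
orthogonal shift then chains every column (or row) off the calibrated
line. Each (horizontal shift, vertical shift, stage order) triple gives
one complete PSM; the standard plan yields the eight orderings
BD, DB, BE, EB, CD, DC, CE, EC. The final PSM is their per-pixel
arithmetic mean, renormalised to exactly 1 at the reference pixel, and
the per-pixel sample (n−1) standard deviation over the eight maps is the
uncertainty estimate. A three-acquisition plan (A plus one shift per
axis) is supported and yields two orderings, with no error averaging.

Indexing: the conventional detector index skips zero
(i in {−M..−1, 1..M}, M = N/2); internally the grid is 0-based and
contiguous, with i > 0 mapping to column M−1+i and i < 0 to M+i, so the
reference pixel (1, 1) sits at (M, M). The chains are implemented as the
step-by-step recursion; an algebraically identical cumulative-product
(closed-form) implementation is kept solely as an independent cross-check
and agrees to better than 1e−12 on random positive inputs.

Error structure: the gain of a pixel m steps from the reference is a
product of m count ratios, so iid relative count noise sigma grows like
sigma*sqrt(m) along a chain and any systematic per-acquisition factor
grows like m times the factor. This is why the spread map rises towards
the detector corners and why the two corrections below matter.

## 2. Beam-output correction

The delivered fluence drifts between consecutive deliveries (monitor
chamber non-linearity; observed range ±0.2%). For each shifted
acquisition a factor `f` is recovered from the profile through the
reference pixel along the shifting direction: writing the fluence-match
identity for a window of 2k pixels centred on the reference and
cancelling the gains under the assumption that the flood-field calibrated
gain profile is symmetric about the beam axis (`G(−k) ≈ G(k+1)`),

    f = (prod central window / prod shifted window)^(1/(2k)),  k = N/2 − 3,

where the shifted window is the central one displaced by one pixel
against the shift so both windows sample the same lab cells, and the
outermost three pixels are excluded. The factor multiplies every count of
the shifted acquisition. Numerically the products are evaluated in log
space: forty counts of order 3e4 overflow float64 as a raw product.

With exactly symmetric gains the recovery is exact to machine precision;
a gain asymmetry delta across the window ends biases f by roughly
delta/(2k), and the bias propagates n-fold along the chains. This is a
genuine limitation inherited from the method's symmetry assumption, and
it sets the accuracy floor of a run whose gain map is appreciably
asymmetric (an iid pixel spread of 0.5% alone gives a floor of a few
tenths of a percent at the map edges).

## 3. Beam-symmetry correction

Occasionally a delivery arrives with a slightly tilted profile, modelled
as a multiplicative perturbation

    pert(y) = u * sin(pi * y / length)

with y measured from the profile centre — an odd function whose sign sets
the slope of the asymmetry, |u| of order 0.15%, observed in the
gantry-table direction. The correction loop: compute the mean PSM;
calibrate all five images (counts x PSM); align each shifted image onto
the central lab grid; average the relative difference to the calibrated
central image over the transverse direction inside the ROI (3-pixel
margins); fit u per acquisition by closed-form least squares on the
single sine basis; divide the original shifted counts by (1 + pert)
evaluated at that acquisition's lab rows; repeat until converged.

**Identifiability.** A tilt pair (+d, −d) on the two opposite-shift
acquisitions of one axis is exactly absorbed by redefining the gain map
and the fluence by a smooth profile h with dln h = d*sin: to first order
it is invisible to any within-run observable. Concretely, only the pair
sum u_+ + u_− is measurable; the bias the tilt creates in the mean PSM
feeds half the sum back into both members' difference profiles, so each
member individually fits (u_+ + u_−)/2. A per-image update would drive
the observable sum to zero while freezing the antisymmetric (gauge)
component — and with it the PSM error. The loop therefore corrects per
axis pair: the summed fitted amplitude is attributed entirely to one
member, chosen by tentatively applying either attribution and keeping
the one that minimises the residual fitted amplitudes. The tie-break
works because the gauge equivalence is only first-order exact; the
second-order residuals do separate the members on noiseless data. Under
the operating assumption that symmetry excursions affect one delivery at
a time, this recovers the full amplitude on the perturbed acquisition
(to ~0.1% noiseless); if both members of a pair are genuinely and
unequally perturbed, the symmetric part is still fully removed and the
antisymmetric remainder is intrinsically unknowable from the run itself.
Convergence is judged on the observable — the pair sums — with default
tolerance 1e−5 and at most 5 passes; non-convergence returns the best
result with a warning, never silently. The correction divides rather
than subtracts: at |u| ≤ 0.15% the difference is second-order, and the
perturbation is physically multiplicative.

## 4. Image preparation and dose image

Raw exports are flood-field corrected as
`IM_EPID = (raw − dark)/flood × mean(flood)` (invariant to rescaling the
flood; a non-positive flood pixel is an error naming the pixel), then
grouped by block averaging — the mean, not the sum, keeps grouped counts
on the counts scale of `F = C * G` and preserves the trimmed-region mean
exactly. The default geometry is a 1024-pixel panel at 0.25 mm isocenter
pitch, factor 20 → 5 mm grouped pixels, working ROI the central 46 x 46
(23 cm field side, matching the jaw setting that keeps the panel
electronics out of the beam). Grouping order is FF-correct → group;
acquisitions are never normalised individually, since the absolute
inter-acquisition count scale carries the calibration information.

The relative dose image is `D = IM_EPID × G × c` with c = 1 (a single
multiplicative hook is kept for absolute conversion). When the PSM lives
on the grouped grid it is bilinearly interpolated to the image grid on
the grouped-cell centres, with nearest-value extension in the half-cell
edge band. On a smooth quadratic field the full 0.25 mm → 5 mm → 0.25 mm
round trip is accurate to ~0.04% (interior), comfortably inside the 0.2%
budget adopted for the resolution chain.

## 5. The synthetic test bed

The simulator inverts `F = C * G` with every ground-truth ingredient
known:

* **Beam**: radially symmetric polynomial `1 + c2 (r/r0)^2 + c4 (r/r0)^4`
  with a sigmoid penumbra and a small background, evaluable at any real
  lab coordinate (needed for sub-pixel shift error). Defaults: field
  width 70 grouped pixels, central level 3e4 counts, c2 = −0.03,
  penumbra 2 pixels, background 1% — a smooth, non-flat field that keeps
  all counts positive over the 46 x 46 ROI. The method is exactly
  gauge-invariant under a global fluence rescale, and the true profile
  shape only enters the results through smoothness, so the specific
  polynomial is a modelling convenience, not a claim about any
  particular machine.
* **Gains**: 1 + (2% low-order cosine structure) + iid N(0, 0.5%) pixel
  spread, renormalised to exactly 1 at the reference pixel; an optional
  symmetrised variant mirrors the smooth component about the reference
  row/column to emulate the near-symmetry a flood-field calibration
  leaves in a real panel.
* **Perturbations** (per acquisition): output scale (default sampled
  uniformly in 1 ± 0.002), symmetry tilt (uniform in ± 0.0015 on the
  gantry-table axis), optional sub-pixel shift error (< 0.5 pixel), and
  multiplicative Gaussian count noise (default sigma = 0.001 — frame
  averaging makes counts high enough that Poisson ≈ Gaussian). All
  draws are reproducible from a single seed, with an independent
  substream per acquisition.

What the simulator does **not** model: the panel's energy response (Gadox
over-response to low-energy scatter), optical glare, image lag, bad
pixels, MU-to-dose conversion, or film/scanner behaviour. Passing tests
therefore establish the *algorithmic* properties of the calibration —
exactness on clean data, correct removal of the modelled perturbations,
the predicted error topology under count noise — not the dosimetric
accuracy of any physical EPID, which additionally depends on the effects
listed above.

## 6. Problem sizes and defaults

All shipped analyses run on the 46 x 46 grouped grid of the default
geometry (the native-resolution chain check uses a 460-pixel profile with
factor 20). A full five-acquisition calibration is ~400 chains of ≤ 46
steps and completes in tens of milliseconds; the complete test suite and
the acceptance script each run in seconds on one CPU. Key defaults:
reference pixel (23, 23); chain count floor 1% of the line median (counts
below it abort with a diagnostic rather than produce wild gains); output
window k = N/2 − 3 (overridable with a warning); symmetry fit margins
3 pixels, tolerance 1e−5, max 5 passes; sample (n−1) statistics
throughout; histogram summaries use 41 bins.

## 7. Known limitations

* The output factor inherits the gain end-symmetry assumption; asymmetric
  gain maps bias it (Section 2), which dominates the error budget of
  noiseless asymmetric scenarios.
* The antisymmetric component of a same-axis tilt pair is unobservable
  within one run (Section 3); the attribution rule is a prior, not an
  inference, whenever both members of a pair are perturbed.
* Sub-pixel shift errors are simulated but not corrected; like the real
  procedure, the method treats them as a reproducibility term.
* The symmetry fit assumes the single-lobe sine shape; other profile
  changes (e.g. flatness changes symmetric about the axis) are partially
  absorbed by the output factor and otherwise propagate into the spread
  maps, where the QA statistics are designed to expose them.
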