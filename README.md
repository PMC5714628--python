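# epidcal

Shift-based intercalibration of the pixel sensitivity map (PSM) of a 2D
imaging detector, built for electronic portal imaging devices (EPIDs) used
in radiotherapy dosimetry.

## The problem

An amorphous-silicon EPID stores flood-field (FF) corrected images: dividing
by the FF image flattens the pixel-to-pixel response, but the true beam
profile is present in both the raw and the FF image, so it is washed out of
everything the detector exports. Before an EPID image can be read as a
(relative) dose map, the per-pixel relative gains `G(i,j)` — the PSM — must
be recovered and multiplied back in. Standard recipes need an external
dosimeter (film, ionisation chamber) or a Monte-Carlo response model, and
inherit the reference detector's energy dependence.

`epidcal` implements an intercalibration alternative that needs nothing but
the detector itself: five consecutive open-field deliveries with the panel
at its central position and at single-pixel displacements along the two
in-plane axes (`A` centre, `B/C` = ±x, `D/E` = ±y). If the beam is the same
for all deliveries, fluence and counts are linked by `F = C · G`, so two
acquisitions shifted by one pixel chain neighbouring gains through count
ratios:

```
C_A(i+1, j) · G(i+1, j) = C_B(i, j) · G(i, j)
```

Anchoring `G = 1` at a central reference pixel and applying the relation
recursively calibrates a full row or column; a second, orthogonal shift
extends the calibrated line to the whole matrix. Two shifts per axis and
two stage orders per shift pair give **eight** chained PSMs; their per-pixel
mean is the final map and their spread is its uncertainty. Because the
chains multiply count ratios, two inter-delivery beam perturbations are
corrected explicitly:

* **output drift** — a per-delivery scale factor `f` recovered from matched
  windowed count products along the shifting direction,
  `f = (Π C_A / Π C_shifted)^(1/2k)` with `k = N/2 − 3`;
* **symmetry tilt** — a profile change `pert(y) = u·sin(π·y/length)` fitted
  to the difference between calibrated central and shifted images and
  divided out iteratively.

The package also contains a synthetic-acquisition simulator with known
ground truth (beam model, gain map, injected perturbations), the
flood-field/grouping image preparation step, dose-image formation
`D = IM_EPID · G · c` with bilinear PSM upsampling back to native
resolution, and QA statistics mirroring the method's internal consistency
checks.

## Worked example

```python
import numpy as np
import epidcal as ec

# ground truth: 2% smooth gain structure + 0.5% pixel-to-pixel spread
gains = ec.make_true_gain_map(ec.TrueGainMapSpec(grid_size=46, seed=11))

# five noiseless acquisitions of a smooth non-flat beam
aset = ec.simulate_calibration_set(ec.BeamModel(), gains,
                                   ec.PerturbationSpec.none())
res = ec.compute_psm(aset, output_correction=False)
print(res.n_sets)                                                 # 8
print(np.abs(res.psm_mean.values / gains.values - 1).max())       # ~6.7e-16
print(res.psm_std.max())                                          # ~8.1e-16

# 0.1% count noise: spread grows away from the reference pixel
noisy = ec.simulate_calibration_set(ec.BeamModel(), gains,
                                    ec.PerturbationSpec(noise_sigma=0.001,
                                                        seed=2))
nres = ec.compute_psm(noisy, output_correction=False)
print(round(100 * ec.residual_summary(nres).std, 2))              # 0.63 (%)
```

On clean data every one of the eight chained maps reproduces the true
normalised gain map to machine precision and their spread vanishes; with
0.1% multiplicative count noise the pooled residual spread is ~0.6%, and
the per-pixel spread map peaks at the detector corners, where the chains
are longest.

The same workflow is available from the shell:

```
epidcal simulate --seed 1 --out run/acq
epidcal calibrate --manifest run/acq --out run/psm
epidcal run --out run/full        # end-to-end with corrections and QA report
```

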