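# Methods

## Model and assumptions

The package implements a closed-form model of the peripheral photon dose
(PPD) per monitor unit outside the treatment field of a coplanar isocentric
photon treatment.  In an isocenter-origin frame (x anterior–posterior,
y left–right, z caudal–cranial, cm), with r the distance to the isocenter:

- **Scatter branch (r ≤ 40 cm).**
  `ε·F·(A₁ − A₂|z|)·e^(−A₃r)/r² + (L_u − L_r)`, clamped below at zero.  The
  1/r² kernel treats the linac head and irradiated volume as an effective
  point source; the exponential is an effective attenuation (A₃ behaves
  like a linear attenuation coefficient of the scattered photons); the
  linear |z| term captures the craniocaudal asymmetry of the dose left by a
  coplanar beam arrangement.  The dose depends only on r and |z| — it is
  rotationally symmetric about the craniocaudal axis and mirror-symmetric
  in z.  No tissue-density information enters: the patient is treated as
  homogeneous.
- **Leakage branch (r > 40 cm).**  The dose is the constant head leakage
  L_u per MU.  The piecewise form is applied exactly as defined, with its
  discontinuity at r = 40 cm; no blending is attempted, because the scatter
  branch was only ever calibrated inside that radius.
- **Validity region.**  The model applies only outside the 5 % isodose
  surface; in-field dose is the treatment planning system's job.  As an
  additional guard, point queries closer than r_min = 1 cm to the isocenter
  raise an out-of-validity error instead of returning the (divergent) 1/r²
  value.  Whole-grid evaluation marks such voxels, and any voxels in a
  caller-supplied in-field exclusion mask, with a NaN sentinel plus a
  companion validity mask — silent zeros would corrupt organ statistics.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| A₁ | scatter amplitude | mGy·cm²/MU | 37.890 |
| A₂ | craniocaudal gradient | mGy·cm/MU | 0.679 |
| A₃ | effective attenuation | cm⁻¹ | 0.007 |
| E_R | reference treatment efficiency | mGy/MU | 2000/278 (≈7.2) |
| F_R | reference field area | cm² | 149.2 |
| L_r | reference leakage | mGy/MU | 0.001 |
| r_cut | leakage-only radius | cm | 40 |
| isodose_exclusion | in-field isodose fraction | – | 0.05 |

ε = E_U/E_R and F = F_U/F_R are carried at full floating precision
everywhere; the conventionally quoted values (7.2, 0.35, 0.36, 0.48, 1.04)
are display roundings — indeed two of them (0.35 for 53.2/149.2 = 0.3566 and
0.48 for 3.6/7.2 = 0.50) are not even the rounded quotients, so this package
always computes the quotient and treats printed figures as presentation.
E_R defaults to the exact ratio 2000/278 rather than the rounded 7.2.
When the user's leakage is unmeasured, L_u defaults to L_r so the
(L_u − L_r) term vanishes.

The coefficient container enforces A₁ > 0, A₂, A₃ ≥ 0 and A₁ − 40·A₂ > 0;
the last condition guarantees the scatter bracket stays positive everywhere
the scatter branch applies (|z| ≤ r ≤ 40 cm).

## Field-size extraction

F_U is the arithmetic mean of the areas inside the 50 % isodose on the
coronal and sagittal planes through the isocenter.  Areas are pixel counts
with an inclusive (≥) threshold times the pixel area — no sub-pixel
contouring, which keeps the measure reproducible at a cost of roughly one
pixel row of discretization error.  The plane is the voxel slab nearest the
isocenter coordinate (a known half-voxel positioning bias).  The reference
dose for the threshold is the trilinear interpolation of the cube at the
isocenter, since the isocenter rarely coincides with a voxel center.  An
alternative 1D recipe — the product of the full widths at half maximum of
the two in-plane profiles through the isocenter, averaged over both planes
— is available as `method="profile"`; the area method is the default.

## Calibration

A₁, A₂, A₃ are fitted to a reference 3D dose cube (mGy/MU) with ε = F = 1
and L_u = L_r, using the Nelder–Mead simplex (derivative-free, matching the
procedure the model was originally built with).  Fitted voxels are
restricted to: the body interior (the one-voxel surface shell is eroded
away with 6-connectivity, because surface voxels carry electron
contamination the model ignores), outside the in-field isodose region, and
1 cm ≤ r ≤ 40 cm.

Open choices, decided here and fixed:

- **Objective**: sum of squared *relative* residuals ((model−ref)/ref)².
  Peripheral dose spans ~2 orders of magnitude across the fitted region;
  absolute least squares would be dominated by the near-field voxels.
  Absolute squared error is available as `loss="absolute"`.
- **Start and stopping**: simplex start (20, 0.3, 0.02), parameter and
  objective tolerances 1e-8, at most 5000 iterations.  Fixed defaults make
  the fit bit-for-bit deterministic.
- **Weights**: uniform by default.  The `.3ddose` relative-error array can
  optionally weight residuals by 1/σ² (`weight_by_rel_error=True`).
- **5 % isodose referent**: the threshold is relative to the dose
  interpolated at the isocenter (not the global maximum); the fraction is a
  configurable constant.

Approximate standard errors are computed post hoc from a Gauss–Newton
linearisation (cov = s²(JᵀJ)⁻¹ with a forward-difference residual
Jacobian).  They quantify the fit's sensitivity to the data, not a full
error propagation.

Agreement diagnostics report the per-voxel absolute percentage difference
relative to the reference (mean and 95th percentile) and the maximum
absolute difference in dose units; the same statistics serve for paired
point-dose comparisons against measurements.

## Synthetic data

The generator emulates the three external inputs so the whole pipeline is
testable self-contained:

- **Phantom**: a trunk-sized body ellipsoid (semiaxes 10 × 15 × 35 cm) with
  a few ellipsoidal organs, voxelised on a 2 cm isotropic grid by default,
  isocenter mid-body as for an abdominal plan.
- **Reference cube**: the analytical model itself evaluated per voxel,
  times multiplicative Gaussian noise `1 + cv·N(0,1)` (Monte Carlo dose
  uncertainty is reported as *relative* error, so relative noise is the
  faithful stand-in; default cv = 0.05), plus an in-field Gaussian blob
  centred at the isocenter (amplitude 2000/278 mGy/MU — the isocenter dose
  per MU of the reference plan — σ = 2 cm) so a 5 % isodose region exists
  to exclude.  The σ is deliberately narrow: a real in-field profile falls
  off over a penumbra of millimetres, and the stand-in's tail must be
  negligible just outside its own 5 % isodose or it would contaminate the
  calibration region, which no real out-of-field dataset does.
- **Point dosimeters**: n points uniform per volume in a spherical annulus
  (default 8–45 cm), with true model values and noisy "measurements".

What the synthetic data does *not* emulate: anatomical heterogeneity,
density effects, spatially correlated Monte Carlo noise, detector energy
dependence, and any asymmetric beam arrangement.  Passing the recovery and
agreement tests therefore demonstrates the correctness of the fitting and
analysis machinery, not the model's physical accuracy on real patients —
the latter rests on the original experimental validation and on whatever
reference data a user calibrates against.

All randomness flows through one seeded `numpy` generator per artifact;
seeds are recorded in provenance records.

## Numerical choices and degenerate inputs

- Grids are uniform-spacing rectilinear; geometry is normalised to cm on
  read (DICOM/NIfTI/MetaImage speak mm; `.3ddose` boundaries are cm by the
  EGSnrc convention, with a `units_mm` override).  `.3ddose` files with
  non-uniform voxel widths are rejected rather than silently resampled.
- The internal canonical frame is (AP, LR, craniocaudal) with the isocenter
  at the origin; format-specific axis orders are converted on read, and a
  signed axis permutation maps grid axes to anatomical axes.
- DVH: cumulative, V(d) = % of organ voxels with dose ≥ d at bin left
  edges; default bin width 0.1 mGy (peripheral doses are small, fine bins
  are cheap); bins span [0, d_max + one bin] so curves start at 100 % and
  end at 0 %.  Organ voxels without a computed dose (in-field sentinel) are
  excluded and their fraction reported, with a warning above 10 %.
- Dose cannot be negative: the scatter branch is clamped at zero (reachable
  only when L_u < L_r).
- Empty masks, non-positive reference doses, zero isocenter dose,
  truncated or non-monotone files all raise typed errors early.

## Problem sizes

The shipped tests and the acceptance script run the calibration recovery on
a 41³ voxel grid (2 cm isotropic, ±40 cm), about 33 000 fitted voxels, and
the end-to-end phantom pipeline on up to ~33 000 voxels; both complete in
seconds.  The same code paths scale to clinical CT-resolution grids — the
model evaluation is a single vectorised expression per cube.

## Known limitations

- No in-field dose, no skin/surface dose (electron contamination), no
  neutron component, no beam-energy dependence.
- The 40 cm discontinuity is inherited from the model's construction.
- F_U from pixel counting carries a one-pixel-row discretization error and
  a half-voxel slab-selection bias.
- The fitted-coefficient standard errors assume independent homoscedastic
  relative residuals.
- DICOM support is read-only and axis-aligned; oblique volumes are
  rejected; RT-Struct contours are out of scope (organ masks are consumed
  as label volumes).
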