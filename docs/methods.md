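# Methods

## Scope and model

`scoutdose` implements the quantitative safety dosimetry used in
holmium-166 (¹⁶⁶Ho) microsphere scout-dose imaging before liver
radioembolisation. Three quantities are computed:

1. **Lung shunt fraction (LSF).** From anterior/posterior planar count
   images, the lung and liver ROI sums are combined through the geometric
   mean:

       LSF = √(Lₐ·Lₚ) / ( √(Lₐ·Lₚ) + √(Hₐ·Hₚ) )

   with `L` the lung and `H` the liver ROI counts. For a source at depth
   `d` in a body of thickness `T`, single-exponential attenuation
   contributes `e^(−μd)` anteriorly and `e^(−μ(T−d))` posteriorly; the
   geometric mean collapses both to `e^(−μT/2)`, a factor common to lungs
   and liver that cancels in the ratio. The LSF is therefore insensitive
   to source depth under this attenuation model. One organ with zero
   counts is a valid (degenerate) input giving LSF 0 or 1; both zero is
   undefined and raises.

2. **Extrahepatic deposition quantification.** Inside a generously drawn
   margin ROI around the deposition (excluding intrahepatic activity):
   - *activity* `A` is the plain sum of voxel values (Bq → MBq), with no
     threshold, so displaced counts (breathing, motion, partial-volume
     spill) are never lost;
   - *volume* `V` counts the in-margin voxels whose value is ≥ a stated
     fraction of the in-margin maximum (ties at the threshold are
     included), times the voxel volume. The maximum is taken inside the
     margin only, so hepatic activity can never set the threshold. No
     connected-component filtering is applied.

3. **Absorbed dose.**

       D (Gy) = 15.87 (mJ/MBq) · A (MBq) / ( V (cm³) · 1.06 (g/cm³) )

   15.87 mJ/MBq is the total beta energy absorbed in tissue per MBq of
   ¹⁶⁶Ho; 1.06 g/cm³ is soft-tissue density. mJ/g = J/kg = Gy, so no
   further factors appear. The beta branch carries 96% of the emitted
   energy with a mean soft-tissue range of 2.5 mm, so all beta energy is
   booked to the delineated volume and no spatial dose kernel is used; the
   high-energy gamma contribution to local dose is neglected. Pairing an
   un-thresholded activity with a never-over-estimated volume makes `D`
   an upper bound by construction — the estimator is allowed to
   overestimate the hazard, not to understate it.

## Threshold calibration

The delineation threshold is calibrated on a six-sphere image-quality
phantom (0.5–26.5 ml spheres of known activity concentration in a 9.7 L
compartment). Candidate fractions (default grid 0.05–0.95, step 0.05) are
swept; at each, every sphere's volume and dose are estimated with the same
margin-ROI machinery used for patients. The **selected threshold** is the
smallest grid fraction at which no sphere with true volume ≥ 1 ml is
over-estimated (`estimated ≤ true`, strict; a relative-tolerance option
exists, default 0). Smallest-admissible gives the least volume
underestimation, hence the least dose overestimation, while preserving the
conservatism guarantee. The 0.5 ml sphere is excluded from the criterion:
at sub-ml volumes both activity and volume are underestimated and the dose
bound does not hold — which is why a 1 ml floor is the stated domain of
validity.

The selected fraction depends on the system resolution. With the
package's default 12 mm FWHM point-spread function, the default phantom
selects **0.65**: at this coarse resolution the 30% iso-contour of a
small blurred sphere is *larger* than the sphere, so 0.30 would
over-estimate. The package default threshold for patient quantification
remains **0.30**, the value calibrated on the clinical system this
analysis models (whose effective resolution was evidently finer); users
simulating other systems should quantify at the threshold their own
phantom run selects. At the selected threshold the estimated dose is ≥
the true dose for all spheres ≥ 1 ml — on the default phantom the
overestimation reaches roughly 2.5× for mid-size spheres, the same
qualitative partial-volume behaviour (up to ~4×) seen on real phantom
data.

Without blur there is still no threshold that makes the voxelized volume
exact: low thresholds count partially filled boundary voxels as whole
voxels (over-estimation), and the admissible region starts near 0.5,
where only majority-filled voxels survive. Calibration results should
therefore always be read per point-spread function, never reused across
systems.

## Synthetic data generator

The generator stands in for the study's SPECT/CT scans; it emulates the
features the dosimetry pipeline is sensitive to and nothing else.

**Geometry and rasterization.** Scenes are built from spheres, ellipsoids
and a cylinder on a physical grid (default 4.8 mm isotropic voxels, the
reconstruction grid of the modelled protocol). Each region is rasterized
with partial-volume-aware boundary voxels: each voxel's in-plane face is
sampled on a 16×16 sub-grid and the region's z-chord through each column
is integrated analytically. The error is then only the in-plane midpoint
quadrature: worst-case total-activity error < 0.15% down to 0.5 ml
spheres, comfortably inside the 0.5% rasterization tolerance the
conservation tests assert. (Pure 3-D point sampling at low sub-sampling
was rejected: lattice-aligned spheres produced correlated quantization
errors of several percent.)

**Imaging chain.** The point-spread function is an isotropic Gaussian,
default FWHM 12 mm — a typical medium-energy-collimator SPECT resolution,
single-parameter and adjustable. The kernel is normalized and truncated
at 4σ, so with the enforced 2·FWHM border margin the grand total is
conserved exactly (relative 1e-6) under blurring. Optional Poisson noise
is applied voxel-wise after scaling by `counts_per_bq` (default 1), using
a seeded `numpy` generator; fixed seed ⇒ bit-identical output. Collimator
response, scatter, attenuation in 3-D, and reconstruction artefacts are
*not* modelled — so passing tests demonstrate correctness of the analysis
given a quantitative image, not robustness to reconstruction bias on real
scans.

**Phantom defaults.** Six spheres of 0.5, 1.2, 2.6, 5.6, 11.5, 26.5 ml
(the standard image-quality set), unit concentration (1 MBq/ml — every
calibration property is concentration-invariant), on a ring of radius
85 mm, volumes interleaved so the per-sphere margin regions
(radius + 2·FWHM + 1 voxel, which covers the truncated blur support
exactly) stay pairwise disjoint; cold 9.7 L cylindrical background
(hot background available via its concentration field).

**Patient-scene defaults.** Liver and lungs as ellipsoids (~1.0 L liver),
250 MBq scout administration split 217 MBq liver / 33 MBq lungs (a 13.2%
shunt, the modelled cohort's mean), and a spherical extrahepatic
deposition of 3.7 MBq in 15.3 ml — the cohort's upper-median regime —
placed so that its margin region clears the liver's blurred support.
Planar views are axis-1 sums with optional single-μ exponential depth
attenuation (default off; the geometric mean exists precisely to cancel
it, and tests exercise that cancellation). Projected organ footprints can
be dilated (`roi_margin_mm`, typically 2·FWHM) to emulate ROIs drawn
around the blurred organ image.

## Cohort statistics

For an even-sized cohort the package reports three medians: the lower
(n/2-th order statistic), the standard (mean of the central pair), and
the upper ((n/2+1)-th). All three are reported because small published
cohorts differ in convention; for the six-deposition reference cohort the
published medians (3.6 Gy, 15.3 ml, 3.7 MBq) follow the *upper*-median
convention, and the reference table shipped in `scoutdose.reference`
records the published per-row values for comparison. Recomputing each
dose from its printed one-decimal activity and volume reproduces four of
the six published doses exactly at one decimal; the two largest-activity
rows land within 0.2 Gy, consistent with the originals having been
computed from unrounded measurements. No agreement tighter than 0.2 Gy is
claimed for those two rows.

## Numerical and interface choices

- Voxel values are stored in Bq; reporting converts to MBq. Display
  rounding is one decimal for ml, MBq, Gy; full precision is kept
  internally.
- Voxel indices are 0-based; physical coordinates refer to voxel centers;
  3-D images and masks travel as NIfTI, planar images and masks as CSV,
  specifications and records as JSON — all inspectable as text.
- Threshold tie-break: `value ≥ threshold` is inside.
- CLI outputs embed the effective configuration and seed and contain no
  timestamps, so any output file is regenerable bit-for-bit; wall-clock
  information goes to the stderr log only.
- Problem sizes: the default phantom and scene use 64×64×64 and 64×64×72
  grids at 4.8 mm; the calibration sweep covers 19 thresholds × 6
  spheres; the noisy activity-recovery study averages 50 seeded scenes.
  A full test run plus the headline recomputation completes in well under
  a minute on one CPU.

## Known limitations

- The dose model is a single-compartment beta absorber: no dose-point
  kernels, no gamma dose, no heterogeneity inside the deposition. It is a
  screening bound, not a voxel-dose map.
- The generator's blur is shift-invariant Gaussian; real SPECT resolution
  is depth-dependent and anisotropic, and reconstruction introduces
  correlated noise none of which is emulated.
- Margin ROIs are taken as given (their volume is recorded for
  provenance); the package does not model inter-observer delineation
  variability.
- The 30%-of-maximum default threshold is only as good as the phantom
  calibration of the system that produced the image; it is recalibrated,
  not reused, when the resolution changes.
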