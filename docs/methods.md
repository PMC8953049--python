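# Methods

## Scope and model

`vascupet` quantifies blood-pool PET volumes acquired with an intravascular
tracer (FDG-labeled erythrocytes): because the tracer stays inside vessels,
voxel activity in tissue is proportional to the local vascular volume
fraction, and a pharmacological vasodilator changes tissue signal without
changing whole-blood activity. The package implements the full
quantification chain — SUV conversion, VOI totals and histograms,
stress−rest clipped-difference imaging with the vasodilation "increased
ratio", three-class Otsu infarct stratification, TTC stain color
segmentation, and exact small-sample Wilcoxon inference — and validates it
on synthetic phantoms with closed-form ground truth plus the published
per-rat tables bundled as CSV fixtures.

Everything upstream of the reconstructed voxel volume (list-mode
acquisition, OSEM reconstruction, ECG hardware gating, attenuation and
scatter) is out of scope: the phantom emits already-reconstructed gated
volumes, and real data enter as NIfTI-1 volumes plus binary VOI masks on
congruent grids. No resampling is ever performed; mismatched grids are a
hard error, mirroring a single-scanner rest/stress session.

## SUV and VOI quantification

SUV (g/mL) = voxel (Bq/mL) × C × weight (kg) / dose (Bq) × 1000 (g/kg),
with decay correction C = 2^(Δt/T½), T½ = 109.77 min for ¹⁸F. The source
formula names C without defining it; correction to injection time is the
standard physical reading, and correction to scan start is recovered by
setting the delay to zero (then C = 1). VOI statistics report the raw voxel
sum (what the vasodilation tables use), the mean, the voxel count, and the
mL-normalised volume. Histograms default to 64 equal-width bins over the
masked min–max (no binning is prescribed by the source analysis);
counts always conserve the mask voxel count.

## Stress−rest difference and the increased ratio

Rest and stress volumes are co-registered by the integer voxel shift that
aligns the VOI centroids, with the sub-voxel remainder discarded. Rationale:
both volumes come from the same scanner and session, so the residual motion
is a small translation, and integer shifts introduce no interpolation into
the subtraction. The difference is computed voxelwise inside the mask and
negative values are set to zero (not excluded — the voxel count is
unchanged): negatives at the endocardial border are dominated by
partial-volume averaging against chamber blood, which carries ~10× the
tissue activity. The vasodilation statistic is

    increased ratio (%) = 100 × Σ_mask max(stress − rest, 0) / Σ_mask rest.

The rest-state denominator is the only reading consistent with the
internally consistent rows of the published per-rat tables (control rats 1
and 4, diabetic rats 3 and 4 reproduce at ±0.01; the other six ratio cells
do not reproduce from their own row's numbers and are flagged, not failed,
by `pipeline.reproduce_tables`). Differencing operates on Bq/mL volumes by
default; SUV volumes pass through the same code path since the statistic is
scale-equivariant.

On a noise-free, blur-free phantom with vasodilation delta d the ratio is
exactly 100·d. Under Poisson noise the clipped estimator is biased upward
(clipping can only add), but at the default count level (~10³ counts per
tissue voxel) the per-voxel difference is ~10σ from zero and the bias is
negligible (<0.01 points over 50 phantom realisations); the bias becomes
visible and strongly positive at a few counts per voxel, which the tests
assert directly.

## Otsu infarct stratification

The two thresholds maximising three-class between-class variance are found
by exhaustive search over all bin-pair splits of a 64-bin histogram
(O(bins²) with cumulative sums, exact and deterministic; ties broken toward
the lowest split). Thresholds are bin edges, so class assignment is
invariant under affine rescaling of the values. The low class is read as
infarct, medium + high as viable, and

    infarct % = 100 × low / (low + medium + high)

on the chosen short-axis slice (grid axis 2 is the declared LV long axis).
A whole-VOI aggregate with a single shared split is provided as a
convenience. The interactive expert adjustment of class boundaries in the
source workflow is replaced by an explicit threshold-override parameter.

Blind three-class stratification is fragile under partial-volume blur, and
the phantom reproduces this: at PSF σ ≈ 1 mm, chamber spill-in raises
inner-rim wedge voxels above the low threshold and the estimate dips below
truth, while at σ ≥ 2 mm the dominant variance direction becomes the
transmural spill gradient, the low threshold jumps into the viable cluster,
and the estimate overshoots grossly (the qualitative counterpart of the
perfusion margins over-estimating infarct size on real images). The
acceptance-level check asserts the upward drift across σ = 0/1.5/3 mm at a
fixed phantom seed; the per-σ trajectory between those points is not
monotone and should not be expected to be.

## TTC stain segmentation

Stain photographs are segmented in HSV/lightness space: background removed
at HSL-lightness > 0.9, viable tissue = hue ∈ [330°, 360°] ∪ [0°, 20°] with
saturation > 0.4 (dark red formazan), infarct = hue ∈ [20°, 60°] with
saturation ∈ [0.1, 0.5] (unstained tan). All boxes are configuration, since
real staining varies between preparations and the source workflow used
manual color thresholding. Pixels matching neither box are excluded from
the percentage.

## Phantom design

Geometry is deliberately schematic — the math under test does not depend on
rat anatomy. The LV is an axis-aligned ellipsoidal shell (outer semi-axes
0.5/0.5/0.7 of the half-extent of the grid's smallest dimension; inner =
0.6 × outer) around a blood-filled chamber; the brain is a filled
ellipsoid. Defaults: 64³ voxels at 1.4 mm isotropic (the scanner's
effective voxel size; 64³ rather than 256³ keeps a study of ~dozens of
phantom realisations at interactive speed while leaving ≥13 mm of margin,
i.e. >5σ of the largest tested PSF, to the grid edge), blood activity
10⁴ Bq/mL, vascular fraction 0.1 — the myocardial vascular volume fraction
is of order 10%, and neither wall thickness nor absolute activities are
stated for the source data, so these are free parameters chosen once, not
calibrated.

Gating is emulated by four wall-thickness states: the inner semi-axes are
scaled by 1 − 0.15·sin²(πk/n_gates), so gate 0 is diastole (thinnest wall,
largest cavity) and mid-cycle is systole. Masks are defined on the
diastolic geometry, which is also the gate the analyses consume. An infarct
is an angular wedge (about the long axis) of the shell with vascular signal
scaled by a factor in [0, 1]; its cross-section fraction equals its angular
fraction up to rasterization.

Degradation follows physical order: isotropic Gaussian PSF in mm first
(scipy.ndimage, truncated at the grid boundary), then per-voxel Poisson
noise on counts = activity × dwell_scale, rescaled back to Bq/mL
(dwell_scale defaults to 1.0 count per Bq/mL ≈ 10³ counts per tissue voxel,
a high-count regime). All randomness derives from the spec's single integer
seed, with rest/stress/gate draws on separated streams; phantoms are
bit-reproducible.

The synthetic TTC image is an annulus on white background with a tan wedge
and seeded Gaussian color jitter (σ = 5 intensity levels). What the
phantoms do *not* emulate: realistic anatomy and papillary muscles,
respiratory/cardiac motion beyond the wall-thickness states, attenuation
and scatter, reconstruction correlations between voxels (Poisson noise is
independent per voxel), lighting gradients and specular highlights in stain
photos. Passing tests therefore demonstrate correctness of the
quantification math under controlled degradation, not robustness to
everything real acquisitions contain.

## Exact rank tests

Both Wilcoxon tests enumerate their complete null distribution — all 2^n
sign patterns (signed rank, via dynamic programming over doubled midranks)
and all C(n+m, n) group allocations (rank sum) — with midranks for ties and
no continuity or normal approximation, valid up to n (or n+m) = 20. They
report the conventional min-tail statistic, min(W+, W−) or min(U_A, U_B),
plus the exact two-tailed p, so both the published "U = 0" values and the
significance claims are independently checkable. Notably, complete
separation of five pairs gives an exact two-tailed p of 2/32 = 0.0625, not
< 0.05: the published α = 0.05 claim for the n = 5 paired comparisons rests
on a critical-value-table convention that the exact computation does not
reproduce (the n = 6 and 5-vs-5 claims do survive: 2/64 = 0.031 and
2/252 = 0.0079). `reproduce_tables` flags these cells rather than failing
them.

## Study drivers and sizes

`run_vasodilation_study` defaults encode the two study designs: six brain
subjects at delta = 0.722 and five LV subjects at delta = 0.523 (the
reported mean responses), Poisson noise at the default count level.
`run_infarct_study` uses six subjects at wedge fraction 0.25 with zero
wedge signal, sized on the mid short-axis slice and on a matched 256²
synthetic stain image. Per-subject seeds are derived from the study seed;
identical configs yield byte-identical output CSVs.

## Known limitations

- Registration is translation-only; rotations or deformation between rest
  and stress are out of scope.
- The exact tests are limited to n ≤ 20 by design; beyond that a
  large-sample approximation (not included) is the right tool.
- Otsu stratification assumes the infarct is the *lowest* activity class on
  the slice; a slice without an infarct still produces a low class
  (~a third of voxels), so the estimate is only meaningful where a defect
  is known or suspected — as in the source workflow, where slices were
  selected by visual inspection.
- The stain segmentation assumes the two stain colors fall in disjoint
  hue–saturation boxes; heavily hemorrhagic or pale slices would need
  per-image configuration.
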