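# Methods

This note records the models, numerical choices and their rationale, the
way the digital phantom relates to physical reality, and the known limits
of what the validation shows.

## Coordinate and transform conventions

Voxel arrays are `(slice k, row, column)`; physical coordinates are mm,
ordered `(z, y, x)` with `z` along the scan axis.  Slice spacing may be
non-uniform, so slice centres are carried explicitly and all interpolation
works in mm.  A rigid transform is `(tx, ty, tz, rx, ry, rz)` (mm, degrees,
fixed-axis xyz composition) about the reference volume's physical centre;
rotating about the centre decouples rotations from translations in the
search.  The registration transform maps reference (t1) coordinates into
moving (t2) space — backward warping, so every output voxel pulls one
interpolated sample.  Out-of-overlap voxels are flagged in a validity mask
and excluded from all statistical measures; zero-filling them would bias
the intensity histograms.

## Digital phantom

The phantom stands in for bench-built agar/water head models: a smooth
"brain" ellipsoid (semi-axes 66×80×68 mm, intensity 100) containing a
connected CSF cavity (intensity 30) built from parametric solids named for
the anatomy they emulate — two C-shaped lateral-ventricle arc tubes,
foramina-of-Monro channels, a third-ventricle slab, a 2 mm-radius aqueduct
and a fourth-ventricle lobe.  A `size_scale` near 1 spans cavity volumes of
roughly 88–135 cm³ (the five-phantom suite uses scales 0.951–1.088), and a
seeded ±few-percent jitter varies the shapes between phantoms.  The
ground-truth volume `V_M` is a dense 0.5 mm voxelization of the union
(volume error of that oracle is far below the pipeline errors measured
against it); construction fails loudly if the cavity is not one connected
component.

Three hypodense "landmark" ellipsoids (two orbital analogues anterior-
inferior, one off-midline posterior) are embedded in the matrix.  Real
head CTs carry strongly asymmetric structures (orbits, sinuses, skull
base) that make rigid alignment well-posed; a bare ellipsoid phantom is
nearly rotation-symmetric, which leaves out-of-plane rotation almost
unobservable to any intensity measure.  The landmarks restore that
identifiability without touching the cavity.

Scanning: each voxel value is the mean of material intensities over a
supersampled sub-voxel grid — 3×3 in-plane and one sample per ~2 mm of
slice thickness, both counts odd so a sample sits at the voxel midpoint.
Odd counts matter: with even midpoint grids the ≥0.5 coverage rule of the
reference masks effectively thresholds at 0.375, inflating every boundary
by an eighth of a voxel and the suite volumes by ~4%.  Gantry tilt rotates
the slicing plane about the in-plane column axis; four scans at 0/5/10/15°
reproduce a repeated-angulation protocol.  Head displacement is a rigid
transform of the phantom before slicing.  Noise is additive Gaussian,
default σ=2 on the 0–100 intensity scale (CT-like contrast-to-noise for
brain/CSF); the physical phantoms' intensity histograms are not published,
so these values are declared assumptions, all configurable.

The slice schedule is 3 mm below z = −20 mm (the fourth-ventricle zone)
and 7 mm above, covering ±66 mm; the grid is 192 px over a 200 mm field of
view (~1 mm pixels), a down-scaled stand-in for the 512-px clinical matrix
chosen to keep a full validation suite in minutes.  Down-scaling mainly
coarsens the region granularity available to the segmentation's selection
step; at 160 px the per-run volume errors grow visibly (worst runs ~4%),
at 192 px they stay within the physical-phantom error budget.

## Registration

Normalized mutual information `(H(A)+H(B))/H(A,B)` is computed from a
64-bin joint histogram (each volume linearly rescaled to its own range;
64 bins is the standard bias/variance compromise) filled by partial-volume
interpolation: every in-overlap reference sample distributes unit mass
over the 8 neighbouring moving-grid intensities with trilinear weights,
which keeps the measure smooth in the transform parameters.  The gradient
term uses Gaussian-derivative gradients at σ = 1.5 mm; in-plane
derivatives are true Gaussian derivatives, the through-plane derivative is
a finite difference against the actual slice positions because the slice
spacing is non-uniform.  Moving-volume gradients are trilinearly sampled
from a precomputed field and rotated into the reference frame before the
angle is taken.

Sample positions are the reference voxel centres plus a fixed, seeded
sub-voxel jitter.  Without the jitter the measure acquires a spurious
local maximum at zero out-of-plane rotation: when the two 3–7 mm slice
stacks coincide exactly, interpolation adds no blur and both the gradient
term and the histogram sharpen, regardless of content.  Off-grid sampling
removes that grid-coincidence artifact (both volumes are then always
interpolated) while leaving the content-driven optimum in place; the
jitter is fixed per pyramid level, so the objective stays smooth and
deterministic.

Optimization is Nelder–Mead on −In′ over a 3-level in-plane Daubechies-4
approximation pyramid (through-plane resolution is already coarse at
3–7 mm, so decimating z would destroy what little there is).  The initial
simplex steps 5 mm/5° at the coarsest level, halved per level; translations
are carried in mm so optima transfer across levels unchanged; 400
evaluations per level, convergence at 0.01 in parameter units.  On the
noiseless phantom, displacements within ±10 mm/±10° are recovered to
better than 0.1 mm / 0.3°.

## Segmentation

Stage I builds the watershed input from DT-CWT features computed per
slice at 4 decomposition levels.  The DT-CWT here is two exactly
orthonormal real filter-bank trees per direction: level 1 uses a length-14
symlet with tree b delayed one sample; deeper levels use a length-14
"q-shift" lowpass designed in-repo by optimizing a paraunitary lattice
(orthonormality exact by construction) for linear phase at a quarter-sample
delay plus a vanishing moment, with tree b the time-reverse of tree a.
Measured negative-to-positive frequency leakage of the level-2/3 complex
wavelets is ~1%, and subband magnitudes change 2–3× less under a 1-px
shift than critically-sampled DWT coefficients.  Perfect reconstruction
holds to ~1e−11, which the texture map construction relies on.

Numerical choices in the feature chain:

- Subband magnitudes are divided by 2^level before use.  The orthonormal
  transform gains 2 per level, while the texture-activity calibration
  (λ=2, ψ=7) presumes magnitudes on the 8-bit image scale; without the
  rescale the whole head registers as "texture" and the activity map
  saturates.
- Directional median filters (length 7+2i, normal pass then parallel
  pass) are rasterized by rounding points along the orientation's unit
  vector, so ±15°/±75° follow Bresenham-like lines.
- Upsampling of subband-grid maps to the image grid (`f_z`) is zero
  insertion followed by a Gaussian matched to the upsampling factor
  (bare zero insertion combs) and a circular shift by the accumulated
  analysis group delay of the filters.  The delay correction matters: at
  level 3 the maps are otherwise displaced by ~45 px and the texture
  gradient no longer marks real boundaries.
- Subbands whose gradient content is numerically zero (noiseless synthetic
  slices) are skipped rather than max-normalized into pure noise.
- H-minima depth defaults to 10% of the modified gradient's range; the
  watershed floods the filled surface from its regional minima into a full
  partition (no ridge pixels — basin assignment settles boundary
  ownership).
- The intensity-gradient normalizer μ_I = 4·median(|∇F|) falls back to
  4·mean(|∇F|) when the median is exactly zero (legitimate for noiseless
  synthetic slices that are flat over half their area); a truly blank
  image still raises.

Stage II scores adjacent (8-connected) region pairs with 1 − KS statistic
on the original image and on the texture map and merges the best pair
until the paper-style criterion (max = min over remaining pairs, tolerance
1e−6) or a similarity floor (default 0.5) stops it.  The floor is an
extension: the max=min rule alone cannot stop a monotone cascade on
homogeneous synthetic data.  The KS *statistic* is used rather than its
p-value because p-values saturate at zero on region-sized pixel samples
and destroy the ordering the merge loop needs; the statistic is rank-based,
so the similarity is invariant under monotone intensity maps.  Region
samples are capped at 5000 pixels by seeded subsampling.

Region selection is a user step by design.  The validation harness
substitutes two deterministic stand-ins: seed points sampled inside the
eroded reference mask (the batch analogue of clicking every clearly
ventricular region), and majority-overlap picks (a region is ventricular
iff ≥50% of it lies in the reference mask), which mirrors the
include/exclude judgement an expert makes for partial-volume boundary
regions and is what the accuracy suite uses.  The residual volume error of
the suite is dominated by exactly these partial-volume wall regions
flipping wholly in or out.

## Volumetry and metrics

Volume arithmetic is exact: `a_k = p_s²·n_vk`, `V_k' = a_k·τ_k` with the
per-slice thickness (the mixed 3/7 mm schedule requires τ as a vector),
summed over slices with ventricle pixels.  The improvement ratio R is the
mean over slices of the fractional reduction in summed absolute intensity
difference; slices already identical before registration are skipped with
a warning (R is undefined there), and each metric counts its own relevant
slice set.  The similarity index is slice-averaged Dice over slices where
either mask is non-empty, in percent; >70% is the conventional "excellent
agreement" bar.  The change predictor flags |ΔṼ′| > 5% (the threshold
sits above the ~3.5% volumetry error margin and is configurable).  Case
clustering is k = 2 k-means on log10 |ΔṼ′| with changes floored at 0.01%
before the log; clusters are reported low-to-high with the midpoint
boundary.

## What the validation shows — and does not

The phantom suite (5 sizes × 4 gantry angles, mixed slice schedule) checks
the full segmentation + volumetry chain against exactly known volumes:
maximum single-run error 3.4%, suite mean 1.3%, mean Dice ~95% at the
default conditions (numbers recomputed by `scripts/acceptance.py`).  The
zero-change experiment checks that registration keeps a rigidly displaced
rescan's apparent volume change under the 5% predictor.

The simulator reproduces partial volume, anisotropic slicing, gantry
angulation, rigid displacement and additive noise.  It does not model
beam hardening, scatter, sinogram-domain reconstruction, non-rigid brain
deformation, pathology-driven intensity change, or the texture of real
brain parenchyma (its matrix is homogeneous), and the selection stand-in
has access to reference masks a radiologist would supply from expertise.
Passing these tests therefore demonstrates the numerical and algorithmic
integrity of the chain under controlled conditions, not clinical accuracy:
on real CTs the intensity model, the texture statistics and the user
interaction all differ.

## Problem sizes

Default study conditions: 192×192 px slices over a 200 mm field of view,
~28 slices per study, 5 phantoms × 4 angles for the accuracy suite, 20
random displacements for transform recovery (on a reduced 96-px uniform
5 mm protocol), single serial pair for the zero-change check.  These sizes
keep the complete validation, including registration searches, within
minutes per experiment on one CPU.
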