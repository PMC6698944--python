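# Methods

This note documents the model behind `mr2sct`, the parameters that
matter, the numerical choices, and what the synthetic phantom does and
does not establish about behaviour on clinical data.

## The segmentation model and its assumptions

The pipeline assumes a single 3D contrast-enhanced T1-weighted head
volume in which

* air and cortical bone are signal voids (indistinguishable by
  intensity),
* white matter is the most locally uniform bright tissue,
* CSF is dark relative to brain, fat is bright, muscle is intermediate,
  trabecular bone overlaps brain and fat,
* absolute intensities are not standardised: they vary with scanner,
  coil, field strength and patient.

The last point drives the whole design: every threshold in the chain is
*relative* — to the white-matter reference intensity `wmIntensity`, or to
statistics (μ, σ, min) measured in the patient's own image. As a
consequence the entire segmentation is invariant under a global
multiplicative rescaling of the MR intensities, a property the test suite
asserts bit-exactly.

Grid convention: arrays are indexed `(k, row, col)` with `k` increasing
superior, rows increasing anterior, columns increasing toward the
patient's left; all physical rules (cm/mm) convert through the header
spacing, rounding window extents to the nearest odd voxel count ≥ 1.

## Stage-by-stage parameters

All values live in `mr2sct.config.PipelineConfig` and are echoed into the
run report.

**Air** (`air.*`). The manual contours are interpolated by linear
interpolation of per-slice signed distance transforms (shape-based
interpolation); contoured slices are rasterised exactly and slices
outside the contoured span stay empty. The air statistics estimator
initialises on the darkest `stats_fraction` (default 0.5) of the outlined
voxels and then iteratively refits over all outlined voxels below
μ + `refit_sigma`·σ (default 4) until stable. The two-stage form matters:
a plain darkest-half estimate is biased low on a pure noise floor, while
a plain mean is biased high by enclosed mucosa; the fixed point of the
refit recovers the floor statistics in both situations, including the
non-zero-mean Rician floor of magnitude MR images. Soft tissue inside the
outline is excluded above μ_Air + `subtract_sigma`·σ_Air (default 3, the
same multiplier the skull seed rule uses).

**Brain windows** (`brain.*`). The coefficients 0.53 / 1.35 (statistical
brain range) and 0.7 / 1.2 (initial growing) multiply `wmIntensity` and
are treated as fixed constants of the method; all windows are closed
intervals. The uniformity search window is 1 cm × 1 cm in-plane on the
middle coronal slice; candidate centers are restricted to body voxels at
or above the slice's median body intensity (air and CSF are uniform too)
whose full window fits inside the grid. A perfectly uniform window
(σ = 0) ranks as infinitely uniform; ties are broken by the larger window
mean, then the lowest index. `wmIntensity` is recomputed exactly over the
winning window rather than taken from the running-sum filter, so the
derived window bounds are reproducible to the last bit.

**Edges** (`canny.*`). Intensities outside the statistical brain range
are zeroed, then 2D Canny runs per axial and per sagittal slice with
hysteresis thresholds at 40% / 80% of each slice's maximum gradient
magnitude — fractions of the per-slice maximum rather than absolute
values, which keeps edge detection scale-invariant. Gap closing operates
per axial slice: endpoints are located on the skeleton of the edge set
(raw Canny output can be two voxels wide, hiding curve tips) and each
endpoint is joined to its nearest edge pixel outside its own local branch
by a discrete straight (Bresenham) segment, up to `max_gap_mm` (10 mm).

**CSF** (`csf.*`). The reference search region is the initial brain mask
after a morphological closing (4 mm) and hole filling: ventricles
communicate with the peripheral CSF through narrow channels and are
therefore not strict topological holes of the initial brain; the closing
makes them searchable. Candidate 5 mm × 5 mm × 5 mm windows must lie
fully inside that region with center intensity below 0.53·wmIntensity;
the most uniform window supplies μ_CSF, σ_CSF and the growing seeds.

**Skull** (`skull.*`). Seeds are body voxels within 1 cm of the external
body contour at or below μ_Air + 3σ_Air; growing uses [0, μ_CSF + 2σ_CSF]
inside the body, barred by the initial brain, CSF and the edge voxels.
Because the upper bound deliberately reaches CSF level, the grown core
absorbs the peripheral CSF film wherever bone touches it; the filled
brain-interior region is therefore protected (removed from the core)
before the second step, in which every remaining body voxel whose
straight path to the brain centroid crosses the grown skull is added.
This "external to the skull" closure turns the mask into an exclusion
zone covering scalp and face, so the final brain growing (statistical
range, which overlaps fat and trabecular bone) cannot leak outward. The
ray test samples each path at 1-voxel steps, vectorised in chunks.

**Eyes** (`eye.*`). The typical eye is modelled as a 4 cm diameter
sphere. "Half a typical eye size" is read as half the *volume* of that
sphere (16.8 cm³) by default; a diameter-based reading is available via
`eye.size_rule`. Sphericity rejects components whose axis-aligned extents
differ by more than 1 cm; midline contact is tested against a 3-voxel
mid-sagittal slab.

**Bone** (`bone.*`). The trabecular reference is the set of cavities
enclosed by the cortical mask — voxels unreachable from the volume border
without crossing cortical bone, in 3D or within their own axial slice
(the slice-wise rule keeps the diploic space usable when an orbit or
sinus breaks the 3D enclosure). The pipeline additionally excludes the
filled brain ∪ CSF region (a contrast-enhancing lesion is enclosed by
brain, not by bone), the skull-grown core (absorbed CSF film), and
anything at or below CSF-level intensity. The statistics are then
median/MAD-trimmed at 4 robust SDs: enclosed cavities still contain stray
partial-volume and interface voxels whose tail would otherwise inflate σ
and make the μ ± 2σ recovery window meaningless. Recovery labels voxels
within 5 mm of cortical bone inside μ ± 2σ ("small neighbourhood window"
is unquantified in the underlying method; 5 mm is configurable).

**Soft tissue** (`soft.*`). "Adjacent slices" context is one slice on
each side (a 3-slice window; 5-slice available via `soft.context_slices`).
Class boundaries: muscle closed at μ_soft, fat half-open above it — this
guarantees an exact partition of the residual. The mapping windows for
muscle and fat use the *global* residual statistics (min_soft,
μ_soft + σ_soft, μ_soft + 2σ_soft), while classification uses the
per-slice statistics; each rule is applied in the context it is stated
for.

**Mapping.** Out-of-window intensities are clipped to the window before
the linear / inverse-linear transform (partial-volume voxels routinely
fall outside μ ± 2σ); a degenerate window maps to the midpoint HU. Eyes
have no published mapping row; they are assigned bulk 45 HU (water-like
soft tissue, matching the CSF bulk value), overridable via
`mapping.eye_hu`.

**Label precedence.** Stages run body → air → brain/CSF → eyes → bone →
soft tissue; on conflict AIR > CORTICAL > TRABECULAR > EYE > CSF > BRAIN
> CONTRAST > FAT > MUSCLE (earlier, more specific stages win),
implemented by painting in reverse precedence order. The final label grid
partitions the body exactly (asserted), and the pipeline contains no
randomness: identical inputs give byte-identical synthetic CTs.

## Evaluation metrics

Bone is HU ≥ 200 in both volumes. The external-skull contour distance is
*directed* (sCT → CT): each sCT contour voxel contributes its in-plane
distance to the nearest CT contour voxel on the selected slice. Each
volume contributes its own largest-width slice per view — the two scans
may be shifted against each other, so comparing a shared slice index is
not meaningful. Whole-body / air / soft-tissue regions use −400 / −800 /
[−100, 200) HU thresholds, with air required below −800 HU in *both*
volumes; the 200 HU boundary belongs to bone. ME = mean(CT − sCT),
MAE = mean|CT − sCT|; MAE ≥ |ME| is asserted on every computation.

## The phantom: what it emulates, and what it does not

`mr2sct.phantom` builds a 192 mm head from nested ellipsoids: fat scalp
over muscle; a cranial vault of outer cortical table, trabecular diploe
and inner table (≤ 8 mm under the scalp, so the 1 cm rim seed rule finds
it), bridged by cortical pillars as diploic septa so bone is one
connected dark structure; a 3 mm subarachnoid CSF film; a gray-matter
rind at 0.7× the white-matter intensity; lateral ventricles joined to the
film by a narrow CSF channel; 34 mm eyes in orbital fat sockets that
carve into the outer table but never through the inner one; a frontal
sinus continuous with an airway that opens at the inferior head surface;
optionally a 12 mm uniform bright lesion inside the white matter and a
surgical vault defect. MR degradation is a smooth multiplicative bias
field spanning [1 − a, 1 + a] (default a = 0.05) and Rician noise
(default σ = 20 a.u. = 2% of the white-matter mean 1000 a.u.), seeded and
bit-reproducible. Ground-truth CT numbers sit at the midpoint of each
tissue's mapping interval, so a perfect segmentation reproduces the
phantom CT within half of each interval's width by construction — the
test suite asserts exactly that bound.

Air contours are auto-derived from the true cavities on at most 12
slices, allocated greedily where linear area interpolation between chosen
slices would err most; this mimics how a planner contours sparsely and
lets the shape-based interpolation be tested against known truth.

What passing the phantom tests does **not** show: robustness to real
coil-profile bias (only a low-order smooth field is simulated), to
chemical shift, motion or flow artifacts, to genuinely textured tissue
(each phantom tissue is homogeneous apart from noise), to pathologies
other than one uniform enhancing lesion and one vault defect, or to MR
geometric distortion (assumed vendor-corrected upstream). Reported
clinical-scale agreement (skull contour distance ≈ 1 mm, bone Dice
≈ 0.7, whole-body MAE ≈ 125 HU on real patients) cannot be reproduced
from synthetic data; the phantom establishes correctness of the
algorithmic chain, not clinical accuracy.

## Problem sizes and numerical choices

The recovery benchmark runs the full pipeline on the 192³ / 1 mm phantom;
the exactness, scale-invariance and determinism checks use a 128³ /
1.5 mm grid of the same 192 mm head, so every mm-based rule is exercised
identically. On the clean (zero-noise, zero-bias) phantom, brain and eye
recovery are exact (Dice 1.0): the gray-matter rind sits exactly at the
0.7·wmIntensity window endpoint and the closed-interval convention admits
it. The scale-invariance check uses the *degraded* phantom deliberately:
with zero noise several tissues lie exactly on window boundaries, where a
×3.7 rescale can flip a closed-interval comparison by one floating-point
ulp — an artifact of float arithmetic, not of the method. Region growing
is implemented as connected-component labelling of the admissible voxel
set (verified against a brute-force BFS flood fill on hundreds of random
instances); local means and SDs use running-sum filters with an exact
min = max test to detect perfectly uniform windows; population (not
sample) SD is used throughout.

## Known limitations

* Peripheral (subarachnoid) CSF that the skull growing absorbs — its
  window deliberately extends to μ_CSF + 2σ_CSF — is not recoverable by
  the CSF stage and ends up classified as muscle (mapped 20–80 HU rather
  than 45 HU). Ventricular and sulcal CSF inside the brain contour are
  unaffected.
* Air regions outside the contoured slice span are not segmented (they
  map to −1000 HU only if outside the body contour).
* The eye volume window [16.8, 67.0] cm³ implied by the volume reading of
  the size rule is generous for human eyes (~7 cm³); the diameter-based
  reading is provided as a config switch.
* Teeth are folded into cortical bone; skin is not a separate class; no
  dosimetric validation is included.
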