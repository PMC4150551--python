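# Methods

## Measurement model

The measurement identifies materials on CT purely by first-order HU
statistics. A region's *homogeneity value* is the sample SD (n−1) of HU
inside it; cement filling the inter-trabecular space raises the mean HU
and sharply lowers this SD, which is why cement-penetrated trabecular bone
(≈1363 HU, homogeneity ≈71) is separable from untouched trabecular bone
(≈163 HU, homogeneity ≈152) even though it is barely separable from pure
cement (≈1328 HU, homogeneity ≈66). A consequence, accepted as a model
limitation, is that bulk cement (filled defects) and true interdigitation
cannot be told apart at clinical CT resolution.

Automatic-marking ranges are `mean ± (2·mean homogeneity +
SD(homogeneity))` over replicate ROIs. The shipped default table is the
*validated* range set, not the output of this formula on the published
aggregates: the two are known to disagree (e.g. the formula gives
[−155, 481] HU for trabecular bone where the validated table says
[−192, 516]), because the per-ROI inputs behind the validated table were
never published. We ship the validated table verbatim and keep the formula
for user-measured ROIs; `reproduce-tables` and the tests assert both facts
rather than guessing the unpublished inputs. Likewise the cortical-bone
range has no published derivation; it is shipped as printed.

Classification resolves the one genuine overlap (penetrated cement
[1062, 1706] vs cortical bone [1386, 1864]) by priority: metal first (so
it can always be masked), then penetrated cement, then cortical, then
trabecular. Pixels in the overlap therefore count as penetrated cement.
The induced bias comes from the thin cortical rim only and is nearly
constant across depth (asserted by test), so depth *differences* and
between-technique comparisons are unaffected; the raw fraction carries the
offset, exactly as in the validated physical procedure. Printed bounds are
read literally: closed on both ends, "> 2475" exclusive and unbounded.

Area fractions are percentages of the total scanned surface, *including*
metal pixels in the denominator by default (the convention the method was
validated with; the metal occupies a nearly constant share of the
cross-section over the relevant depths). An `exclude-metal` denominator is
available. Out-of-volume pixels of an oblique slab never enter any
denominator.

## Geometry

Voxels are cell-centred, 0-based, half-open cells; all depths in mm.
Depth zero is the tray-underside face, positive into the bone; slab *k*
covers (k·0.8, (k+1)·0.8] mm and a depth on a slab boundary belongs to the
deeper slab (this makes a cut "just above the bead" at 3.0 mm, i.e.
2.75 mm after subtracting the bead radius, correspond to slab 3, covering
(2.4, 3.2]).

The tray plane is fitted from the prosthesis-range voxels: largest
connected component, iterative mid-plane trimming to isolate the planar
sheet from the keel, a sheet-anisotropy test (thin axis < 0.35 of the next
axis, else the geometry is rejected as degenerate), per-column deepest
voxels filtered to the consensus underside level, and a total-least-squares
plane through those underside centres. The face level is the robust
(median) underside-centre level plus half the voxel extent along the
normal. On noise-free phantoms this recovers the normal to < 0.3° and
depth zero to ≤ 0.21 mm for tilts up to 15°. Bead fiducials are
prosthesis-range components with equivalent-sphere diameter < 2 mm.

### Resampling: piecewise-constant, classify-then-pool

Slab extraction samples the volume as piecewise-constant per voxel
(nearest-neighbour), with the sample planes spread evenly across the slab
thickness; axis-aligned native-thickness slabs reproduce native slices
exactly. We deliberately do not interpolate HU: an interpolating sampler
fabricates intermediate HU values at material interfaces (e.g. ≈760 HU
between trabecular bone and cement) that belong to *no* material range, so
boundary pixels would silently drop out of every fraction. For the same
reason the penetration profile classifies four thin sub-slices per 0.8 mm
slab and pools the counts, rather than classifying an HU-averaged thick
slab.

One discretisation effect remains and is inherent: for oblique poses the
first slab abuts the staircased metal underside and exchanges up to half a
voxel of tray/bone at the interface, so profile values in slab 0 carry a
partial-volume ambiguity of a few points. All deeper slabs are
pose-invariant to ≤ 0.5 percentage points (tested at 7°).

## Synthetic phantom

The generator reproduces the validation construct with exact ground
truth: 36×80×80 voxels at 0.8×0.4×0.4 mm (0.8 mm slices as in the
validating scanner), a 3 mm metal tray inset 1.6 mm from the lateral
boundary, an 8 mm keel of radius 2.5 mm, an optional 1.6 mm cortical rim,
and 0.5 mm tantalum beads (default one at 3 mm depth). The default
penetration profile is an exponential decay `0.9·exp(−d/3 mm)`, which
yields ≈33–40 % cement fraction at 3 mm — the scale observed physically.
Cement voxels are placed per 0.8 mm depth bin by thresholding a smoothed
Gaussian field (correlation length 2.5 mm, a realistic interdigitation
blob scale) at the exact target count, so per-bin realised fractions match
the profile to < 1 %. Texture is independent per-voxel Gaussian HU at each
material's homogeneity value; scanner effects are Gaussian partial-volume
blur (parameterised as FWHM in mm, the convention for quoted CT
resolution) followed by additive noise. All randomness flows from one
seeded generator per call, and the draw order is geometry-independent, so
the with-tray and without-tray variants of one seed share bit-identical
bone — the in-silico analogue of scanning the same specimen twice.

What the phantom does *not* model: trabecular micro-structure (only its
first-order HU statistics), beam-hardening or streak artifacts (the
method's premise is that modern CT leaves none worth modelling), scanner
projection physics, and bulk-vs-interdigitated cement morphology. Passing
the in-silico experiment therefore demonstrates the correctness of the
measurement chain — geometry, classification, fraction accounting,
optical pairing — not robustness to artifact-laden scans.

The end-to-end checks run on phantoms without the cortical rim: the rim
falls partly inside the penetrated-cement range *by design of the
validated table*, so with a rim present the raw fraction is truth plus the
known constant offset (≈3 points at these proportions, verified
separately), and per-bin truth recovery is only meaningful without it.
Recovery holds to ≤ 0.1 points noise-free and ≤ 0.1 points at 50 HU noise
with 0.4 mm blur at these problem sizes; the acceptance gates are ±2 and
±5 points.

## Statistics

Arms are compared with the pooled-variance (equal-variance) independent
two-sample Student t-test, two-sided. Degenerate inputs follow an explicit
contract: both samples constant and equal → t = 0, p = 1; constant but
unequal → t = ±∞, p = 0. Type-I error at α = 0.05 is verified at
0.05 ± 0.01 under 10 000 null replicates (n = 5 + 5). Report rendering
rounds half-up (mean to 2 decimals, SD to 1, HU to integers); full
precision is kept internally. Recomputing the photo-vs-CT comparison from
the packaged per-slice percentages gives t = −1.19 (df 2), p = 0.356; the
historically reported p = 0.04 for this comparison cannot be reproduced
from any pairing of the published columns under a standard independent
t-test, so the package reports its own computed value and documents the
discrepancy rather than targeting it.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| profile step | 0.8 mm | native slice thickness of the validating scanner |
| profile depth | 10 mm | covers the clinically discussed 3–6 mm with margin |
| mantle floor | 5 % | no published floor exists; explicit and configurable |
| denominator | total surface | the validated convention (metal included) |
| colour similarity | Euclidean RGB | simplest reproducible analogue of interactive colour-range tools; numeric equality with any specific proprietary tool is not expected |
| calibration criteria | water 0±4, teflon 990±30, nylon 100±30, SD ≤ 15 HU | conventional QC ballpark; no published criteria exist; only an additive offset is ever suggested (a single water anchor cannot constrain slope) |

## Known limitations

Only axis-aligned single-frame DICOM series are read (no gantry tilt, no
enhanced multi-frame). Bulk cement and interdigitated cement are
indistinguishable. The cortical-rim bias is constant, not zero. Bead
detection assumes beads are not fused to the tray component. The first
profile slab carries the interface partial-volume ambiguity described
above.
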