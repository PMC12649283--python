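# Methods

## The defacing model

The pipeline treats defacing as a purely geometric operation driven by
clinical contours rather than by image content. Its two landmarks come
from the eye ROIs of the RT Structure Set:

- `z_inf`: the smallest contour-plane *z* over all eye ROIs, snapped to
  the nearest CT slice position. The crop is inclusive: the
  inferior-most eye slice itself is cropped.
- `y_mid`: the unweighted mean over eye ROIs of each ROI's
  vertex-centroid *y*. This is one global coronal plane for the whole
  scan — not per-slice and not per-eye. A per-slice midpoint would
  follow the orbital surface more tightly but produce a jagged,
  harder-to-validate cut; the single plane is the simplest reading of
  "the midpoint of the eye" and matches the planar cut the workflow
  illustrations show. Multiple eye ROIs all contribute to `z_inf`, and
  `y_mid` averages per-ROI centroids; a single contoured eye proceeds
  with a warning, while no contoured eye is a hard error — the tool
  never attempts to segment eyes itself, because silently guessing the
  landmark that guards both privacy and tumor anatomy is worse than
  refusing.

The retain rule, evaluated at voxel centers,

```
keep = (z < z_inf) ∨ (y ≥ y_mid) ∨ PTV ∨ brain
```

is deliberately monotone: relaxing either landmark only ever keeps more
voxels, and preservation is a union over all PTV ROIs and all brain
ROIs. Removed image voxels are filled with −1000 HU (air) by default,
configurable via `--fill-hu`; air is the natural outside-body value and,
unlike blurring or deformation, leaves nothing recoverable.

## Coordinate and rasterization conventions

Only axis-aligned head-first-supine series are accepted (anything else
is rejected with an explicit error), so "anterior" is always decreasing
*y* and "inferior" decreasing *z* in DICOM LPS coordinates. Contour ↔
mask conversion is:

- **Rasterization**: a voxel belongs to an ROI iff its center lies
  inside an odd number of that slice's polygons (even-odd rule). This is
  deterministic, independent of vertex order and winding, and handles
  holes and islands uniformly. A contour plane must coincide with a CT
  slice within half a slice gap, else the polygon is skipped with a
  warning.
- **Polygonization**: marching squares at the 0.5 iso-level on the
  zero-padded slice, mapped back to patient mm. On binary masks the
  round trip rasterize(polygonize(M)) reproduces M exactly in practice
  (property-tested on random blobs); the contract only promises
  agreement up to a one-voxel boundary band.

Structure-set clipping runs in voxel space (rasterize → AND with the
keep-grid → re-polygonize) rather than by analytic polygon/half-space
clipping, because PTV/brain preservation makes the retained region
non-convex; voxel space handles every case uniformly at the cost of
sub-voxel fidelity. ROIs clipped to nothing are kept with an empty
contour list plus a warning — deleting them would hide the information
loss. PTV and brain contours are never re-generated: they pass through
byte-identical.

## Dose handling

The retain rule is re-evaluated analytically at each dose voxel center,
so no interpolation of a binary mask is needed; PTV/brain membership is
looked up at the nearest CT voxel (nearest-neighbour rather than
trilinear, to avoid fractional membership eroding or leaking preserved
dose at PTV edges). Dose voxels outside the CT extent use the analytic
rule alone. Cropped dose voxels are set to 0 Gy instead of shrinking the
grid, keeping the file valid for DVH tooling. On write, the
dose-grid-scaling factor is re-derived from the new maximum over a
32-bit integer range, so retained values round-trip well below clinical
precision (~1e-8 Gy per step for a 70 Gy plan).

## ROI role assignment

The field has no naming standard for ROIs, so roles (eye, lens, cornea,
brain, ptv, body, other) are assigned by a case-insensitive regex table
(`eye|orbit|globe`, `lens`, `cornea`, `ptv`, `^brain$|brain(?!stem)`,
`body|external`), shipped as an editable plain-text config
(`role = regex` lines). "Brainstem" deliberately does not match brain.
Unmatched names become `other`, which means they are clipped if they
protrude into the crop — the safe default for unknown structures.

## The phantom

The generator emulates the study objects the pipeline consumes: a
128×128×80 grid at 2 mm isotropic spacing; an ellipsoidal head
(semi-axes 75×95×85 mm); two 12 mm eye spheres at z = 100 mm near the
anterior surface (giving a crop slice at 90 mm and a midpoint plane at
−55 mm); 3 mm lenses and 2.5 mm corneas anterior to the eye centers —
entirely inside the crop by construction; a posterior-superior brain
ellipsoid that just crosses the midpoint plane, so preservation is
actually exercised; parotid-like and mandible-like OARs inferior to the
eyes; and one PTV per declared mode — `below` (entirely inferior to the
crop), `same_slice` (on crop slices but posterior of the plane), or
`overlap` (intruding into the crop). Tissue HU values (air −1000, soft
tissue 40, brain 30, eye 20, lens 80, bone 700, PTV region 50) are
plausible but irrelevant to the geometry-driven algorithm. The dose is a
Gaussian blob (70 Gy amplitude, 15 mm sigma) centred on the PTV on a
4 mm grid covering the CT extent.

Contours are produced by rasterizing each analytic shape and
re-polygonizing it, which keeps contours, HU painting and landmark
recovery mutually consistent to within a voxel: the recovered `z_inf`
lands on the first slice whose in-plane eye cross-section contains a
pixel center, at most one slice spacing above the analytic inferior
extent. Generation is bit-deterministic given the spec and seed;
optional Gaussian HU noise is seeded and off by default so round-trip
tests can assert bit equality. Each generated triplet self-checks that
the declared PTV mode holds against its own landmarks and raises on
infeasible geometry.

What the phantom does **not** emulate: realistic anatomy and texture
(no auto-segmentation tool would accept it), patient-to-patient
variability, couch/immobilisation hardware, non-axial acquisitions, and
real face-recognition behaviour. Tests passing on phantoms therefore
demonstrate the geometric contracts of the pipeline — preservation,
removal, and propagation across the three DICOM objects — not clinical
recognition rates, which require patient data and trained embedding
models. Accordingly the recognition metrics operate on externally
supplied cosine-distance lists (two-column `pair_id distance` files),
and the embedding computation itself is out of scope.

## Numerical choices and degenerate inputs

- Candidate thresholds for the Youden index are the midpoints of the
  sorted unique pooled distances plus one sentinel below the minimum and
  one above the maximum; ties break toward the smallest threshold. A
  pair "matches" when distance ≤ threshold (boundary counts as a
  match). Both conventions are fixed for determinism.
- Dice of two empty masks is defined as 1 (identical, if empty,
  structures should not flag as mismatch); exactly one empty gives 0.
- PTV position is classified against the *initial* crop region, before
  PTV/brain preservation — otherwise no PTV could ever overlap.
- Slice gaps must be uniform within 0.01 mm; contour planes must sit
  within half a slice gap of a CT slice.
- Fresh series/SOP instance UIDs are generated on every write, derived
  deterministically from a seed when one is given (for reproducible
  tests); the frame of reference UID is always preserved.

## Problem sizes

Unit and property tests run oracles on grids up to 32³ voxels (100
random trials for the retain rule, 20 each for clipping and dose
resampling) and the full pipeline on the default 128×128×80 phantom,
which defaces in a few seconds; the acceptance script uses one full-size
below-mode phantom per run.

## Known limitations

- v1 supports only axis-aligned head-first-supine geometry; tilted
  gantry or non-HFS setups are rejected, not resampled.
- Clipping fidelity is limited to the voxel grid; clipped contours can
  deviate from the analytic intersection by up to one voxel.
- Co-registered volumes (e.g. cone-beam CTs) must already be resampled
  onto the CT grid; the package applies the mask but does not register.
- RT Plan objects are untouched, and dose-volume histograms are not
  recomputed after dose defacing.
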