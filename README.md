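# rtdeface

Automated defacing of head-and-neck radiotherapy DICOM data: CT-simulation
image series, RT Structure Set, and RT Dose.

3D renderings of head CT scans expose a recognisable face, which makes
sharing head-and-neck cancer (HNC) imaging for research a re-identification
risk. Generic neuro-imaging defacing tools, however, routinely destroy
exactly the anatomy HNC research needs — planning target volumes (PTVs),
organs at risk (OARs) near the facial surface, and the dose delivered to
them. `rtdeface` removes the identifiable facial region while guaranteeing
that every PTV voxel and the brain survive, and applies the *same* crop
consistently to the image, the contours, and the dose grid.

## Algorithm

All geometry is in DICOM LPS patient coordinates (head-first-supine:
anterior = decreasing *y*, superior = increasing *z*). From the clinically
contoured eyes the algorithm derives two landmarks:

- **z_inf** — the *z* position of the inferior-most CT slice containing an
  eye contour, snapped to the slice grid;
- **y_mid** — the mean of the per-eye contour-centroid *y* coordinates
  (one global coronal plane).

The binary retain-mask on the CT grid is then

```
keep(v) = [ z(v) < z_inf ]  ∨  [ y(v) ≥ y_mid ]  ∨  PTV(v)  ∨  brain(v)
```

i.e. everything on or above the inferior-most eye slice *and* anterior to
the eye-midpoint plane is removed — the eyes, eyebrows and forehead —
except voxels inside a PTV or the brain, which are always kept. The
pipeline has three steps:

1. **Image** — removed voxels are set to a configurable fill value
   (−1000 HU, air, by default) via the series' rescale mapping; retained
   voxels are bit-identical to the input.
2. **Structure set** — eye, lens and cornea ROIs are deleted; PTV and
   brain contours pass through byte-identical; the body contour is rebuilt
   against the defaced surface; any other ROI protruding into the cropped
   region is clipped (rasterize → intersect with the retain-mask →
   re-polygonize at the 0.5 iso-level).
3. **Dose** — the retain rule is re-evaluated analytically at each dose
   voxel center (the dose grid usually differs from the CT grid), with
   PTV/brain membership looked up at the nearest CT voxel; cropped dose
   voxels are set to 0 Gy.

Validation metrics are included: the Dice coefficient
2|A∩B| / (|A|+|B|) between original and defaced structure
rasterizations, the three-way classification of PTV position relative to
the initial crop region (below / same slices without overlap / overlap),
retained-voxel fractions, and — for face-recognition evaluations on
externally computed embedding cosine distances — Youden-index
(J = TPR − FPR) threshold selection and match rates.

Because real CT-sim data cannot be shipped, the package includes a
synthetic phantom generator (`rtdeface.phantom`) producing standard DICOM
CT + RTSTRUCT + RTDOSE triplets: an ellipsoidal head with spherical eyes,
lenses and corneas near the anterior surface, a posterior-superior brain,
inferior OARs, a PTV placeable in any of the three position classes, and a
Gaussian dose blob on a coarser grid.

## Worked example

```
$ rtdeface simulate --mode overlap --seed 42 --out demo/case
wrote 82 files (overlap-mode phantom, seed 42) to demo/case

$ rtdeface deface --ct-dir demo/case --rtstruct demo/case/rtstruct.dcm \
      --rtdose demo/case/rtdose.dcm --out demo/defaced --seed 42
defaced: z_inf=90.0 mm, y_mid=-55.0 mm, 13166 voxels removed, ROIs removed: Eye_L, Eye_R, Lens_L, Lens_R, Cornea_L, Cornea_R
PTV category: overlap
```

The phantom's eyes are 12 mm spheres centred at z = 100 mm on 2 mm
slices, so the crop starts at the slice at 90 mm and the eye-midpoint
plane sits at y = −55 mm. The PTV was deliberately placed to intrude
into the cropped region (`--mode overlap`); 292 of its voxels fall inside
the crop and every one of them is preserved. `demo/defaced/deface_report.json`
records per-ROI Dice between the original and defaced contour
rasterizations:

```
Body 0.979   Parotid_L 1.0  Parotid_R 1.0  Mandible 1.0  Brain 1.0  PTV70 1.0
Eye_L 0.0    Eye_R 0.0      Lens_L 0.0     Lens_R 0.0    Cornea_L 0.0  Cornea_R 0.0
```

Structures inferior to the crop are untouched (Dice 1), the removed
facial structures score 0, and the body changes only where the face was
cut away. Re-running `deface` on its own output exits with the dedicated
missing-eyes status (2), since the eye contours are gone.

CLI exit codes: 0 success, 2 eyes not contoured, 3 I/O error, 4 geometry
error.

## Layout

- `rtdeface.geometry` — image/dose grid containers and geometry checks
- `rtdeface.contours` — ROI polygons, role tagging, rasterize/polygonize
- `rtdeface.dicom_io` — CT series / RTSTRUCT / RTDOSE read and write
- `rtdeface.defacing` — landmarks, retain-mask, image defacing
- `rtdeface.structset_edit` — structure-set editing
- `rtdeface.dose_deface` — dose-grid mask resampling and application
- `rtdeface.phantom` — synthetic phantom generator
- `rtdeface.metrics` — Dice, PTV classification, ROC/Youden statistics
- `rtdeface.cli` — `rtdeface deface | simulate | evaluate`

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
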