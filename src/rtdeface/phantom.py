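"""Synthetic head-and-neck phantom: CT + structure set + dose triplets.

The phantom emulates the objects a CT-simulation study produces: an
ellipsoidal head with spherical eyes (plus lenses and corneas) near the
anterior surface, a posterior-superior brain, organs at risk inferior to
the eyes, a planning target volume placeable in three positions relative
to the crop region the eyes induce (entirely below it, on the same
slices without overlapping, or overlapping), and a Gaussian dose blob
centred on the PTV on its own coarser grid.

Structure-set contours are produced by rasterising each shape and
re-polygonising it, so contours, HU painting and landmark computation
are mutually consistent to within a voxel.  Generation is fully
deterministic for a given spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydicom.uid import generate_uid

from .contours import RoiContour, StructureSet, polygonize_mask
from .defacing import compute_landmarks, crop_region_grid
from .geometry import DoseGrid, GridGeometry, ImageVolume

__all__ = ["PhantomSpec", "Shape", "PhantomError", "generate_phantom", "randomized_spec"]

PTV_MODES = ("below", "same_slice", "overlap")

DEFAULT_HU = {
    "air": -1000.0,
    "body": 40.0,
    "brain": 30.0,
    "eye": 20.0,
    "lens": 80.0,
    "cornea": 55.0,
    "bone": 700.0,
    "oar": 45.0,
    "ptv": 50.0,
}

# Default PTV placement per mode, chosen relative to the default eyes
# (radius 12 mm at z = 100 mm, giving a crop starting near z = 90 mm and
# an eye-midpoint plane near y = -55 mm).
DEFAULT_PTV = {
    "below": ((0.0, -20.0, 40.0), 18.0),
    "same_slice": ((0.0, 20.0, 95.0), 15.0),
    "overlap": ((0.0, -45.0, 100.0), 18.0),
}


class PhantomError(ValueError):
    """Raised for infeasible phantom geometry."""


@dataclass(frozen=True)
class Shape:
    """An axis-aligned ellipsoid (spheres are the equal-axes case)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    name: str = ""
    hu_key: str = "oar"

    @staticmethod
    def sphere(center, radius, name="", hu_key="oar") -> "Shape":
        return Shape(tuple(center), (radius, radius, radius), name, hu_key)

    def mask(self, geometry: GridGeometry) -> np.ndarray:
        x = geometry.x_coords()[None, :, None]
        y = geometry.y_coords()[:, None, None]
        z = geometry.z_coords()[None, None, :]
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _default_oars() -> tuple[Shape, ...]:
    return (
        Shape.sphere((-38.0, 8.0, 50.0), 10.0, "Parotid_L", "oar"),
        Shape.sphere((38.0, 8.0, 50.0), 10.0, "Parotid_R", "oar"),
        Shape.sphere((0.0, -40.0, 55.0), 14.0, "Mandible", "bone"),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head phantom.

    Distances are mm, HU values Hounsfield units.  ``ptv_mode`` picks the
    PTV position class relative to the crop region its own eyes induce;
    ``ptv`` overrides the default (center, radius) placement for that
    mode.  ``noise_hu`` adds seeded Gaussian noise to the CT (default
    off, keeping tests bit-exact).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 80)  # rows, cols, slices
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # dy, dx, dz
    body: Shape = Shape((0.0, 0.0, 80.0), (75.0, 95.0, 85.0), "Body", "body")
    eyes: tuple[Shape, ...] = (
        Shape.sphere((-28.0, -55.0, 100.0), 12.0, "Eye_L", "eye"),
        Shape.sphere((28.0, -55.0, 100.0), 12.0, "Eye_R", "eye"),
    )
    lenses: tuple[Shape, ...] = (
        Shape.sphere((-28.0, -61.0, 100.0), 3.0, "Lens_L", "lens"),
        Shape.sphere((28.0, -61.0, 100.0), 3.0, "Lens_R", "lens"),
    )
    corneas: tuple[Shape, ...] = (
        Shape.sphere((-28.0, -66.5, 100.0), 2.5, "Cornea_L", "cornea"),
        Shape.sphere((28.0, -66.5, 100.0), 2.5, "Cornea_R", "cornea"),
    )
    brain: Shape = Shape((0.0, 0.0, 118.0), (45.0, 60.0, 32.0), "Brain", "brain")
    oars: tuple[Shape, ...] = field(default_factory=_default_oars)
    ptv_mode: str = "below"
    ptv: Shape | None = None
    dose_amplitude_gy: float = 70.0
    dose_sigma_mm: float = 15.0
    dose_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    hu_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ptv_mode not in PTV_MODES:
            raise PhantomError(f"ptv_mode must be one of {PTV_MODES}, got {self.ptv_mode!r}")

    def resolved_ptv(self) -> Shape:
        if self.ptv is not None:
            return self.ptv
        center, radius = DEFAULT_PTV[self.ptv_mode]
        return Shape.sphere(center, radius, "PTV70", "ptv")

    def ct_geometry(self, frame_of_reference_id: str = "") -> GridGeometry:
        rows, cols, n_slices = self.grid_shape
        dy, dx, dz = self.spacing
        return GridGeometry(
            origin=(-(cols - 1) / 2 * dx, -(rows - 1) / 2 * dy, 0.0),
            pixel_spacing=(dy, dx),
            slice_positions=np.arange(n_slices) * dz,
            rows=rows,
            cols=cols,
            frame_of_reference_id=frame_of_reference_id,
        )


def _contour_roi(mask: np.ndarray, geometry: GridGeometry, name: str, number: int, role: str) -> RoiContour:
    return RoiContour(name=name, roi_number=number, role=role,
                      polygons=polygonize_mask(mask, geometry))


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, StructureSet, DoseGrid]:
    """Build the (CT, structure set, dose) triplet for a spec.

    The CT is painted tissue-by-tissue (later shapes overwrite earlier
    ones); contours come from the painted masks; the dose is an analytic
    Gaussian blob centred on the PTV.  A self-check recomputes the crop
    landmarks from the generated structure set and verifies the declared
    ``ptv_mode``; infeasible geometry raises :class:`PhantomError`.
    """
    rng = np.random.default_rng(spec.seed)
    frame_of_reference = generate_uid(entropy_srcs=[f"rtdeface-phantom-{spec.seed}-for"])
    geom = spec.ct_geometry(frame_of_reference)
    hu = spec.hu_values

    ptv_shape = spec.resolved_ptv()
    # paint order: overwritten by later, more specific tissues
    paint_order: list[Shape] = [spec.body, *spec.oars, spec.brain, ptv_shape,
                                *spec.eyes, *spec.lenses, *spec.corneas]
    hu_grid = np.full(geom.shape, hu["air"], dtype=np.float64)
    masks: dict[str, tuple[np.ndarray, str]] = {}
    for i, shape in enumerate(paint_order):
        m = shape.mask(geom)
        if not m.any():
            raise PhantomError(f"shape {shape.name or i} covers no voxels on this grid")
        hu_grid[m] = hu[shape.hu_key]
        if shape.name:
            masks[shape.name] = (m, shape.hu_key)
    if spec.noise_hu > 0:
        hu_grid += rng.normal(0.0, spec.noise_hu, size=geom.shape)

    intercept, slope = -1024.0, 1.0
    stored = np.clip(np.round((hu_grid - intercept) / slope), -32768, 32767).astype(np.int16)
    volume = ImageVolume(stored_values=stored, geometry=geom,
                         rescale_slope=slope, rescale_intercept=intercept)

    role_of_key = {"eye": "eye", "lens": "lens", "cornea": "cornea",
                   "brain": "brain", "ptv": "ptv", "body": "body"}
    rois = []
    for number, (name, (m, key)) in enumerate(masks.items(), start=1):
        rois.append(_contour_roi(m, geom, name, number, role_of_key.get(key, "other")))
    ss = StructureSet(rois=rois, referenced_frame_of_reference_id=frame_of_reference)

    dose = _gaussian_dose(spec, ptv_shape, frame_of_reference)
    _self_check(spec, volume, ss, masks)
    return volume, ss, dose


def _gaussian_dose(spec: PhantomSpec, ptv_shape: Shape, frame_of_reference: str) -> DoseGrid:
    dy, dx, dz = spec.dose_spacing
    rows_ct, cols_ct, n_ct = spec.grid_shape
    # dose grid covers the CT extent at its own (coarser) spacing
    extent_x = (cols_ct - 1) * spec.spacing[1]
    extent_y = (rows_ct - 1) * spec.spacing[0]
    extent_z = (n_ct - 1) * spec.spacing[2]
    cols = int(extent_x // dx) + 1
    rows = int(extent_y // dy) + 1
    frames = int(extent_z // dz) + 1
    geom = GridGeometry(
        origin=(-(cols - 1) / 2 * dx, -(rows - 1) / 2 * dy, 0.0),
        pixel_spacing=(dy, dx),
        slice_positions=np.arange(frames) * dz,
        rows=rows,
        cols=cols,
        frame_of_reference_id=frame_of_reference,
    )
    x = geom.x_coords()[None, :, None]
    y = geom.y_coords()[:, None, None]
    z = geom.z_coords()[None, None, :]
    cx, cy, cz = ptv_shape.center
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    dose = spec.dose_amplitude_gy * np.exp(-r2 / (2 * spec.dose_sigma_mm**2))
    return DoseGrid(dose_values=np.broadcast_to(dose, geom.shape).copy(), geometry=geom)


def _self_check(spec: PhantomSpec, volume: ImageVolume, ss: StructureSet, masks) -> None:
    landmarks = compute_landmarks(ss, volume)
    cropped = crop_region_grid(volume.geometry, landmarks)
    ptv_name = spec.resolved_ptv().name or "PTV70"
    ptv_mask = masks[ptv_name][0]
    z = volume.geometry.z_coords()[None, None, :]
    on_crop_slices = ptv_mask & np.broadcast_to(z >= landmarks.z_inf, ptv_mask.shape)
    overlapping = ptv_mask & cropped
    if overlapping.any():
        mode = "overlap"
    elif on_crop_slices.any():
        mode = "same_slice"
    else:
        mode = "below"
    if mode != spec.ptv_mode:
        raise PhantomError(
            f"PTV placement realises mode {mode!r}, but spec declares {spec.ptv_mode!r}; "
            "geometry is infeasible for the requested mode"
        )


def randomized_spec(seed: int, ptv_mode: str = "below") -> PhantomSpec:
    """A jittered phantom spec for parameter-recovery and property tests.

    Eye centres are jittered a few mm (z snapped to the slice grid so the
    inferior eye extent stays resolvable), radii varied, and the PTV kept
    at its per-mode default relative to the shifted crop landmarks.
    """
    rng = np.random.default_rng(seed)
    dz = 2.0
    eye_r = float(rng.uniform(10.5, 11.8))
    eye_cz = float(np.round(rng.uniform(96.0, 104.0) / dz) * dz)
    eye_cy = float(rng.uniform(-58.0, -50.0))
    eye_dx = float(rng.uniform(24.0, 32.0))
    eyes = (
        Shape.sphere((-eye_dx, eye_cy, eye_cz), eye_r, "Eye_L", "eye"),
        Shape.sphere((eye_dx, eye_cy, eye_cz), eye_r, "Eye_R", "eye"),
    )
    lens_r = 3.0
    lenses = (
        Shape.sphere((-eye_dx, eye_cy - eye_r + lens_r + 1.0, eye_cz), lens_r, "Lens_L", "lens"),
        Shape.sphere((eye_dx, eye_cy - eye_r + lens_r + 1.0, eye_cz), lens_r, "Lens_R", "lens"),
    )
    corneas = (
        Shape.sphere((-eye_dx, eye_cy - eye_r - 1.0, eye_cz), 2.5, "Cornea_L", "cornea"),
        Shape.sphere((eye_dx, eye_cy - eye_r - 1.0, eye_cz), 2.5, "Cornea_R", "cornea"),
    )
    center, radius = DEFAULT_PTV[ptv_mode]
    # re-anchor the PTV to the jittered landmarks so the mode still holds
    z_inf_expect = eye_cz - eye_r
    y_mid_expect = eye_cy
    if ptv_mode == "below":
        ptv = Shape.sphere((0.0, -20.0, min(40.0, z_inf_expect - radius - 12.0)), radius, "PTV70", "ptv")
    elif ptv_mode == "same_slice":
        ptv = Shape.sphere((0.0, y_mid_expect + radius + 12.0, eye_cz - 5.0), radius, "PTV70", "ptv")
    else:
        ptv = Shape.sphere((0.0, y_mid_expect + 8.0, eye_cz), radius, "PTV70", "ptv")
    return PhantomSpec(eyes=eyes, lenses=lenses, corneas=corneas, ptv_mode=ptv_mode,
                       ptv=ptv, seed=seed)
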