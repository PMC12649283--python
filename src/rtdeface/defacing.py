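"""Landmark computation and retain-mask construction.

The crop region is defined by two scalars derived from the clinically
contoured eyes: the inferior-most slice containing an eye contour
(``z_inf``) and the mean anterior-posterior position of the eye centroids
(``y_mid``).  A voxel is removed iff it lies on or above the inferior-most
eye slice AND anterior to the eye-midpoint plane, unless it belongs to a
planning target volume (PTV) or the brain, which are always preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .contours import StructureSet, rasterize_roi
from .geometry import GeometryError, GridGeometry, ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "CropLandmarks",
    "RetainMask",
    "MissingEyesError",
    "compute_landmarks",
    "build_retain_mask",
    "deface_image",
    "apply_mask_to_coregistered",
]

DEFAULT_FILL_HU = -1000.0  # air


class MissingEyesError(ValueError):
    """The structure set has no contoured eyes, so no landmarks exist."""


@dataclass(frozen=True)
class CropLandmarks:
    """The two scalars that define the crop region.

    z_inf : mm
        Position of the inferior-most CT slice containing any eye
        contour (snapped to the slice grid).  Slices at z >= z_inf are
        candidates for cropping.
    y_mid : mm
        Mean of the per-eye contour-centroid y coordinates; voxels with
        y < y_mid (anterior) on crop slices are removed.
    """

    z_inf: float
    y_mid: float
    source_roi_names: tuple[str, ...] = ()


@dataclass
class RetainMask:
    """Binary keep-grid on the CT geometry (True = voxel is retained)."""

    keep: np.ndarray
    geometry: GridGeometry
    landmarks: CropLandmarks
    preserved_ptv_voxels: int = 0
    preserved_brain_voxels: int = 0

    @property
    def removed_voxels(self) -> int:
        return int(self.keep.size - self.keep.sum())


def compute_landmarks(ss: StructureSet, volume: ImageVolume) -> CropLandmarks:
    """Derive crop landmarks from the eye contours of a structure set.

    ``z_inf`` is the smallest contour plane over all eye ROIs, snapped to
    the nearest CT slice position; ``y_mid`` is the unweighted mean over
    eye ROIs of each ROI's vertex-centroid y.  Deterministic for a given
    input.  Raises :class:`MissingEyesError` when no eye ROI with
    contours exists; a single eye produces a warning but proceeds.
    """
    eyes = [r for r in ss.by_role("eye") if r.polygons]
    if not eyes:
        raise MissingEyesError("eyes not contoured: no ROI with role 'eye' has contour data")
    if len(eyes) == 1:
        warnings.warn(
            f"only one eye ROI ({eyes[0].name!r}) found; landmarks use a single centroid",
            stacklevel=2,
        )
    z_min = min(float(r.z_values().min()) for r in eyes)
    zs = volume.geometry.slice_positions
    z_inf = float(zs[np.argmin(np.abs(zs - z_min))])
    centroids = [float(np.mean(np.concatenate([p[:, 1] for p in r.polygons]))) for r in eyes]
    y_mid = float(np.mean(centroids))
    logger.info("landmarks: z_inf=%.2f mm, y_mid=%.2f mm from %s", z_inf, y_mid,
                [r.name for r in eyes])
    return CropLandmarks(z_inf=z_inf, y_mid=y_mid, source_roi_names=tuple(r.name for r in eyes))


def crop_region_grid(geometry: GridGeometry, landmarks: CropLandmarks) -> np.ndarray:
    """Boolean grid of the *initial* crop region (before preservation).

    True where a voxel center satisfies z >= z_inf and y < y_mid.
    """
    y = geometry.y_coords()[:, None, None]
    z = geometry.z_coords()[None, None, :]
    return (z >= landmarks.z_inf) & (y < landmarks.y_mid)


def build_retain_mask(
    volume: ImageVolume,
    landmarks: CropLandmarks,
    ptv_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
) -> RetainMask:
    """Build the keep-grid, preserving PTV and brain voxels.

    keep(v) = z(v) < z_inf  OR  y(v) >= y_mid  OR  ptv(v)  OR  brain(v).
    The inferior-most eye slice itself is part of the cropped slab.
    """
    shape = volume.geometry.shape
    if ptv_mask is None:
        ptv_mask = np.zeros(shape, dtype=bool)
    if brain_mask is None:
        brain_mask = np.zeros(shape, dtype=bool)
    if ptv_mask.shape != shape or brain_mask.shape != shape:
        raise GeometryError("PTV/brain masks must be on the CT grid")

    cropped = crop_region_grid(volume.geometry, landmarks)
    keep = ~cropped | ptv_mask | brain_mask
    return RetainMask(
        keep=keep,
        geometry=volume.geometry,
        landmarks=landmarks,
        preserved_ptv_voxels=int((cropped & ptv_mask).sum()),
        preserved_brain_voxels=int((cropped & brain_mask & ~ptv_mask).sum()),
    )


def deface_image(
    volume: ImageVolume, mask: RetainMask, fill_hu: float = DEFAULT_FILL_HU
) -> ImageVolume:
    """Apply the retain-mask to a CT volume.

    Retained voxels are bit-identical to the input; removed voxels are
    set to the stored value that maps to ``fill_hu`` (air by default)
    under the volume's rescale mapping, clamped to the representable
    range.  Geometry and rescale metadata are unchanged.
    """
    if mask.keep.shape != volume.stored_values.shape or not mask.geometry.same_grid(volume.geometry):
        raise GeometryError("retain-mask grid does not match the volume grid")
    fill_stored = volume.stored_value_for_hu(fill_hu)
    out = volume.copy()
    out.stored_values[~mask.keep] = fill_stored
    return out


def apply_mask_to_coregistered(
    volume2: ImageVolume, mask: RetainMask, fill_hu: float = DEFAULT_FILL_HU
) -> ImageVolume:
    """Deface another volume already co-registered onto the mask's grid.

    The volume must share the frame of reference and have identical
    geometry; resampling onto the CT grid must happen upstream.
    """
    if volume2.frame_of_reference_id != mask.geometry.frame_of_reference_id:
        raise GeometryError("volume frame of reference does not match the mask's")
    if not volume2.geometry.same_grid(mask.geometry):
        raise GeometryError(
            "volume geometry differs from the mask grid; resample the volume "
            "onto the CT grid before applying the mask"
        )
    return deface_image(volume2, mask, fill_hu=fill_hu)


def structure_masks(
    ss: StructureSet, volume: ImageVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Union rasterizations of all PTV ROIs and all brain ROIs."""
    shape = volume.geometry.shape
    ptv = np.zeros(shape, dtype=bool)
    brain = np.zeros(shape, dtype=bool)
    for roi in ss.by_role("ptv"):
        ptv |= rasterize_roi(roi, volume.geometry)
    for roi in ss.by_role("brain"):
        brain |= rasterize_roi(roi, volume.geometry)
    return ptv, brain
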