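"""Validation metrics for the defacing pipeline.

Covers volumetric overlap (Dice), the three-way classification of PTV
position relative to the initial crop region, retained-voxel fractions,
and recognition-threshold statistics (Youden-index threshold selection
and match rates) on externally supplied cosine-distance lists from
face-embedding comparisons.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contours import StructureSet, rasterize_roi
from .defacing import CropLandmarks, RetainMask, crop_region_grid
from .geometry import DoseGrid, GeometryError, GridGeometry, ImageVolume
from .structset_edit import REMOVED_ROLES

__all__ = [
    "dice",
    "classify_ptv",
    "retained_fraction",
    "youden_threshold",
    "match_rate",
    "PairingDistances",
    "read_distance_file",
    "DefaceReport",
    "build_report",
]

PTV_CATEGORIES = ("below", "same_slice_no_overlap", "overlap")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Two empty masks count as identical (Dice 1); exactly one empty gives 0.
    """
    if a.shape != b.shape:
        raise GeometryError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def classify_ptv(
    ptv_mask: np.ndarray, landmarks: CropLandmarks, geometry: GridGeometry
) -> str:
    """Position of a PTV relative to the *initial* crop region.

    ``overlap`` if any PTV voxel lies inside the crop region (z >= z_inf
    and y < y_mid), else ``same_slice_no_overlap`` if any PTV voxel lies
    on a crop slice, else ``below``.  Evaluated against the crop region
    before PTV/brain preservation.
    """
    if ptv_mask.shape != geometry.shape:
        raise GeometryError("PTV mask is not on the given grid")
    if not ptv_mask.any():
        raise ValueError("empty PTV mask cannot be classified")
    z = geometry.z_coords()[None, None, :]
    y = geometry.y_coords()[:, None, None]
    on_slices = ptv_mask & np.broadcast_to(z >= landmarks.z_inf, ptv_mask.shape)
    if (on_slices & np.broadcast_to(y < landmarks.y_mid, ptv_mask.shape)).any():
        return "overlap"
    if on_slices.any():
        return "same_slice_no_overlap"
    return "below"


def retained_fraction(structure_mask: np.ndarray, keep: np.ndarray) -> float:
    """Fraction of a structure's voxels that survive defacing."""
    if structure_mask.shape != keep.shape:
        raise GeometryError("masks must share a grid")
    total = int(structure_mask.sum())
    if total == 0:
        raise ValueError("empty structure has no retained fraction")
    return int((structure_mask & keep).sum()) / total


def youden_threshold(
    same: np.ndarray, different: np.ndarray
) -> tuple[float, float, float, float]:
    """Pick the distance threshold maximising the Youden index J = TPR - FPR.

    A positive is a same-source pair; a pair *matches* when its distance
    is <= the threshold.  Candidates are the midpoints of the sorted
    unique pooled distances plus sentinels below the minimum and above
    the maximum; ties are broken toward the smallest threshold.

    Returns ``(threshold, tpr, fpr, J)``.
    """
    same = np.asarray(same, dtype=float)
    different = np.asarray(different, dtype=float)
    if same.size == 0 or different.size == 0:
        raise ValueError("both distance lists must be non-empty")
    if not (np.isfinite(same).all() and np.isfinite(different).all()):
        raise ValueError("distances must be finite")
    pooled = np.unique(np.concatenate([same, different]))
    midpoints = (pooled[:-1] + pooled[1:]) / 2.0
    candidates = np.concatenate([[pooled[0] - 1.0], midpoints, [pooled[-1] + 1.0]])
    tpr = (same[None, :] <= candidates[:, None]).mean(axis=1)
    fpr = (different[None, :] <= candidates[:, None]).mean(axis=1)
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximiser
    return float(candidates[best]), float(tpr[best]), float(fpr[best]), float(j[best])


def match_rate(distances: np.ndarray, threshold: float) -> float:
    """Fraction of pairs whose distance is <= the threshold."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty distance list")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return float((distances <= threshold).mean())


@dataclass(frozen=True)
class PairingDistances:
    """Cosine distances for the three recognition pairing groups.

    ``same_patient`` compares two scans of one subject at different time
    points, ``different_patient`` all cross-subject pairs, and
    ``defaced_same_patient`` the defaced first-time-point scan against
    the original second scan.
    """

    same_patient: np.ndarray
    different_patient: np.ndarray
    defaced_same_patient: np.ndarray

    def __post_init__(self) -> None:
        for name in ("same_patient", "different_patient", "defaced_same_patient"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
                raise ValueError(f"{name} distances must be finite and non-negative")


def read_distance_file(path: str | Path) -> np.ndarray:
    """Read distances from a two-column delimited file (pair_id, distance).

    Delimiter may be comma, tab or whitespace; lines starting with ``#``
    are skipped.
    """
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"expected 'pair_id distance', got {line!r}")
            values.append(float(parts[-1]))
    return np.asarray(values, dtype=float)


@dataclass
class DefaceReport:
    """Machine-readable summary of one defacing run."""

    landmarks_z_inf_mm: float
    landmarks_y_mid_mm: float
    voxels_total: int
    voxels_removed: int
    preserved_ptv_voxels: int
    preserved_brain_voxels: int
    rois_removed: list[str] = field(default_factory=list)
    rois_clipped: list[str] = field(default_factory=list)
    rois_kept: list[str] = field(default_factory=list)
    ptv_category: str | None = None
    retained_fractions: dict[str, float] = field(default_factory=dict)
    roi_dice: dict[str, float] = field(default_factory=dict)
    dose_removed_voxels: int | None = None
    wall_seconds: float = 0.0

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "DefaceReport":
        return cls(**json.loads(text))


def build_report(
    volume: ImageVolume,
    defaced: ImageVolume,
    ss: StructureSet,
    defaced_ss: StructureSet,
    dose: DoseGrid | None,
    defaced_dose: DoseGrid | None,
    landmarks: CropLandmarks,
    mask: RetainMask,
    wall_seconds: float = 0.0,
) -> DefaceReport:
    """Summarise one defacing run: per-ROI Dice, retained fractions, counts.

    Dice compares the rasterisation of each ROI in the original structure
    set with its counterpart in the defaced one (removed ROIs rasterise
    empty, scoring 0 against any non-empty original).
    """
    start = time.perf_counter()
    geometry = volume.geometry
    removed_from_image = int((volume.stored_values != defaced.stored_values).sum())

    defaced_by_name = {r.name: r for r in defaced_ss.rois}
    rois_removed, rois_clipped, rois_kept = [], [], []
    roi_dice: dict[str, float] = {}
    retained: dict[str, float] = {}
    ptv_category = None
    empty = np.zeros(geometry.shape, dtype=bool)

    for roi in ss.rois:
        original_mask = rasterize_roi(roi, geometry)
        counterpart = defaced_by_name.get(roi.name)
        defaced_mask = rasterize_roi(counterpart, geometry) if counterpart is not None else empty
        roi_dice[roi.name] = dice(original_mask, defaced_mask)
        if original_mask.any():
            retained[roi.name] = retained_fraction(original_mask, mask.keep)
        if roi.role in REMOVED_ROLES:
            rois_removed.append(roi.name)
        elif counterpart is not None and roi_dice[roi.name] < 1.0:
            rois_clipped.append(roi.name)
        else:
            rois_kept.append(roi.name)
        if roi.role == "ptv" and original_mask.any():
            ptv_category = classify_ptv(original_mask, landmarks, geometry)

    dose_removed = None
    if dose is not None and defaced_dose is not None:
        dose_removed = int(
            ((dose.dose_values > 0) & (defaced_dose.dose_values == 0)).sum()
        )

    return DefaceReport(
        landmarks_z_inf_mm=landmarks.z_inf,
        landmarks_y_mid_mm=landmarks.y_mid,
        voxels_total=int(volume.stored_values.size),
        voxels_removed=removed_from_image,
        preserved_ptv_voxels=mask.preserved_ptv_voxels,
        preserved_brain_voxels=mask.preserved_brain_voxels,
        rois_removed=rois_removed,
        rois_clipped=rois_clipped,
        rois_kept=rois_kept,
        ptv_category=ptv_category,
        retained_fractions=retained,
        roi_dice=roi_dice,
        dose_removed_voxels=dose_removed,
        wall_seconds=wall_seconds + (time.perf_counter() - start),
    )
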