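"""ROI contours, role assignment, and polygon/voxel conversion.

An RT Structure Set stores each region of interest (ROI) as a stack of
closed planar polygons in patient millimetres, one or more per axial
slice.  The defacing algorithm needs both representations: polygons to
read and rewrite the structure set, binary voxel masks to combine with
the retain-mask.  Conversion is pixel-center-in-polygon with the
even-odd rule going one way, and 0.5-level iso-contouring going back.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath
from skimage import measure

from .geometry import GeometryError, GridGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "RoiContour",
    "StructureSet",
    "DEFAULT_ROLE_PATTERNS",
    "assign_role",
    "load_role_patterns",
    "rasterize_roi",
    "rasterize_polygons",
    "polygonize_mask",
]

ROLES = ("eye", "lens", "cornea", "brain", "ptv", "body", "other")

# Order matters: more specific roles are tried first so that e.g. a lens
# inside an orbit name is not swallowed by the eye pattern.  "brainstem"
# must not match brain.
DEFAULT_ROLE_PATTERNS: dict[str, str] = {
    "lens": r"lens",
    "cornea": r"cornea",
    "eye": r"eye|orbit|globe",
    "ptv": r"ptv",
    "brain": r"^brain$|brain(?!stem)",
    "body": r"body|external",
}


def assign_role(name: str, patterns: dict[str, str] | None = None) -> str:
    """Deterministically map an ROI name to a role via regex patterns.

    Matching is case-insensitive substring search; unmatched names get
    role ``"other"``.
    """
    patterns = patterns if patterns is not None else DEFAULT_ROLE_PATTERNS
    for role, pat in patterns.items():
        if re.search(pat, name, flags=re.IGNORECASE):
            return role
    return "other"


def load_role_patterns(path) -> dict[str, str]:
    """Read a role->regex table from a plain ``role = regex`` text file.

    Lines starting with ``#`` and blank lines are ignored.  Roles must be
    drawn from the known role set.
    """
    patterns: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'role = regex', got {line!r}")
            role, _, pat = line.partition("=")
            role = role.strip().lower()
            if role not in ROLES:
                raise ValueError(f"{path}:{lineno}: unknown role {role!r}")
            patterns[role] = pat.strip()
    return patterns


@dataclass
class RoiContour:
    """A named ROI: closed planar polygons in patient mm plus a role tag.

    Each polygon is an ``(n, 3)`` float array of (x, y, z) vertices with
    constant z; the closing edge from last to first vertex is implicit.
    """

    name: str
    roi_number: int
    role: str
    polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        for poly in self.polygons:
            if poly.ndim != 2 or poly.shape[1] != 3 or poly.shape[0] < 3:
                raise ValueError("each polygon must be an (n>=3, 3) array")
            if np.ptp(poly[:, 2]) > 1e-6:
                raise ValueError(f"polygon of ROI {self.name!r} is not planar in z")

    def z_values(self) -> np.ndarray:
        """The z plane of every polygon (mm)."""
        return np.array([p[0, 2] for p in self.polygons])

    def copy(self) -> "RoiContour":
        return replace(self, polygons=[p.copy() for p in self.polygons])


@dataclass
class StructureSet:
    rois: list[RoiContour]
    referenced_frame_of_reference_id: str = ""
    referenced_series_id: str = ""

    def __post_init__(self) -> None:
        numbers = [r.roi_number for r in self.rois]
        if len(set(numbers)) != len(numbers):
            raise ValueError("ROI numbers must be unique")

    def by_role(self, role: str) -> list[RoiContour]:
        return [r for r in self.rois if r.role == role]

    def get(self, name: str) -> RoiContour:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def copy(self) -> "StructureSet":
        return replace(self, rois=[r.copy() for r in self.rois])


def _polygon_membership(
    polygon_xy: np.ndarray, geometry: GridGeometry
) -> np.ndarray:
    """Boolean (rows, cols) grid of pixel centers inside one polygon."""
    xs = geometry.x_coords()
    ys = geometry.y_coords()
    gx, gy = np.meshgrid(xs, ys)  # (rows, cols)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # closed=True alone would treat the final supplied vertex as the
    # CLOSEPOLY marker and drop it; repeat the first vertex explicitly
    path = MplPath(np.vstack([polygon_xy, polygon_xy[:1]]), closed=True)
    inside = path.contains_points(pts)
    return inside.reshape(geometry.rows, geometry.cols)


def rasterize_polygons(
    polygons: list[np.ndarray], geometry: GridGeometry
) -> np.ndarray:
    """Rasterize closed planar polygons onto a voxel grid.

    A voxel is set iff its center lies inside an odd number of the
    polygons on that voxel's slice (even-odd rule), which makes holes and
    multiple islands behave correctly regardless of winding.  Polygons
    whose plane matches no slice (within half a slice gap) are skipped
    with a warning.
    """
    mask = np.zeros(geometry.shape, dtype=bool)
    for poly in polygons:
        z = float(poly[0, 2])
        k = geometry.slice_index_of(z)
        if k is None:
            logger.warning("polygon at z=%.3f mm matches no CT slice; skipped", z)
            continue
        mask[:, :, k] ^= _polygon_membership(poly[:, :2], geometry)
    return mask


def rasterize_roi(roi: RoiContour, geometry: GridGeometry) -> np.ndarray:
    """Binary (rows, cols, slices) mask of an ROI on the CT grid."""
    return rasterize_polygons(roi.polygons, geometry)


def polygonize_mask(mask: np.ndarray, geometry: GridGeometry) -> list[np.ndarray]:
    """Extract per-slice closed polygons from a binary mask.

    Runs marching squares at the 0.5 level on each (zero-padded) slice
    and maps the resulting (row, col) vertices to patient mm.  The output
    re-rasterizes to the input mask up to a sub-voxel boundary band.
    """
    if mask.shape != geometry.shape:
        raise GeometryError(f"mask shape {mask.shape} does not match geometry {geometry.shape}")
    dy, dx = geometry.pixel_spacing
    x0, y0, _ = geometry.origin
    polygons: list[np.ndarray] = []
    for k in range(geometry.n_slices):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(np.float32), 1)
        for contour in measure.find_contours(padded, 0.5):
            rr = contour[:, 0] - 1.0
            cc = contour[:, 1] - 1.0
            closed = np.allclose(contour[0], contour[-1])
            if closed:
                rr, cc = rr[:-1], cc[:-1]
            if len(rr) < 3:
                continue
            poly = np.column_stack(
                [
                    x0 + cc * dx,
                    y0 + rr * dy,
                    np.full(len(rr), geometry.slice_positions[k]),
                ]
            )
            polygons.append(poly)
    return polygons
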