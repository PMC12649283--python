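"""Core spatial containers for the defacing pipeline.

All coordinates are DICOM patient coordinates in the LPS convention
(millimetres): x increases toward the patient's left, y toward posterior,
z toward superior.  Only head-first-supine, axis-aligned acquisitions are
supported, so "anterior" always means decreasing y and "inferior"
decreasing z.

Voxel grids are stored as ``(rows, cols, slices)`` arrays: the first axis
runs along y (posterior-increasing), the second along x (left-increasing),
the third along z (superior-increasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridGeometry", "ImageVolume", "DoseGrid", "GeometryError"]

#: Direction cosines of an axis-aligned head-first-supine acquisition.
IDENTITY_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class GeometryError(ValueError):
    """Raised when grids that must share a geometry do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular axial voxel grid.

    Parameters
    ----------
    origin : tuple of float
        Patient-space (x, y, z) of the center of voxel ``[0, 0, 0]`` in mm.
    pixel_spacing : tuple of float
        (row, col) spacing in mm, i.e. (dy, dx).
    slice_positions : ndarray
        Per-slice z coordinate in mm, strictly increasing.
    """

    origin: tuple[float, float, float]
    pixel_spacing: tuple[float, float]
    slice_positions: np.ndarray
    rows: int
    cols: int
    orientation: tuple[float, ...] = IDENTITY_ORIENTATION
    frame_of_reference_id: str = ""

    def __post_init__(self) -> None:
        sp = np.asarray(self.slice_positions, dtype=float)
        object.__setattr__(self, "slice_positions", sp)
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise GeometryError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if sp.size >= 2 and not np.all(np.diff(sp) > 0):
            raise GeometryError("slice_positions must be strictly increasing")
        if not np.allclose(self.orientation, IDENTITY_ORIENTATION, atol=1e-6):
            raise GeometryError(
                "only axis-aligned head-first-supine orientation is supported, "
                f"got {tuple(self.orientation)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.rows, self.cols, len(self.slice_positions))

    @property
    def n_slices(self) -> int:
        return len(self.slice_positions)

    @property
    def slice_gap(self) -> float:
        """Median distance between neighbouring slices (mm)."""
        sp = self.slice_positions
        if sp.size < 2:
            return float(self.pixel_spacing[0])
        return float(np.median(np.diff(sp)))

    def x_coords(self) -> np.ndarray:
        """Pixel-center x coordinate (mm) for each column."""
        return self.origin[0] + np.arange(self.cols) * self.pixel_spacing[1]

    def y_coords(self) -> np.ndarray:
        """Pixel-center y coordinate (mm) for each row."""
        return self.origin[1] + np.arange(self.rows) * self.pixel_spacing[0]

    def z_coords(self) -> np.ndarray:
        return self.slice_positions

    def slice_index_of(self, z: float, tol: float | None = None) -> int | None:
        """Index of the slice closest to ``z``, or None if beyond ``tol``.

        By default the tolerance is half the slice gap, so a contour plane
        must coincide with one CT slice.
        """
        if tol is None:
            tol = 0.5 * self.slice_gap
        k = int(np.argmin(np.abs(self.slice_positions - z)))
        if abs(self.slice_positions[k] - z) > tol + 1e-9:
            return None
        return k

    def same_grid(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.pixel_spacing, other.pixel_spacing, atol=tol)
            and np.allclose(self.slice_positions, other.slice_positions, atol=tol)
        )


@dataclass
class ImageVolume:
    """An axial CT stack with its geometry and stored-value -> HU mapping.

    ``stored_values`` holds the raw integer pixel values exactly as stored
    on disk; Hounsfield units are obtained via
    ``HU = stored * rescale_slope + rescale_intercept``.
    """

    stored_values: np.ndarray  # (rows, cols, slices), integer dtype
    geometry: GridGeometry
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    bits_stored: int = 16
    pixel_representation: int = 1  # 1 = signed two's complement
    series_id: str = ""
    per_slice_instance_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.stored_values.shape != self.geometry.shape:
            raise GeometryError(
                f"pixel array shape {self.stored_values.shape} does not match "
                f"geometry {self.geometry.shape}"
            )

    @property
    def frame_of_reference_id(self) -> str:
        return self.geometry.frame_of_reference_id

    def stored_range(self) -> tuple[int, int]:
        """Representable stored-value range for the declared bit depth."""
        if self.pixel_representation == 1:
            return (-(2 ** (self.bits_stored - 1)), 2 ** (self.bits_stored - 1) - 1)
        return (0, 2**self.bits_stored - 1)

    def to_hu(self) -> np.ndarray:
        return self.stored_values.astype(np.float64) * self.rescale_slope + self.rescale_intercept

    def stored_value_for_hu(self, hu: float) -> int:
        """Invert the rescale mapping, rounding and clamping to bit depth."""
        raw = round((hu - self.rescale_intercept) / self.rescale_slope)
        lo, hi = self.stored_range()
        return int(min(max(raw, lo), hi))

    def copy(self) -> "ImageVolume":
        return replace(self, stored_values=self.stored_values.copy())


@dataclass
class DoseGrid:
    """A 3D dose distribution (Gy) on its own grid.

    The grid shares the CT frame of reference but may have different
    origin, spacing and extent.  ``dose_values`` is in Gy after the
    dose-grid-scaling factor has been applied.
    """

    dose_values: np.ndarray  # (rows, cols, frames), float, Gy
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.dose_values.shape != self.geometry.shape:
            raise GeometryError(
                f"dose array shape {self.dose_values.shape} does not match "
                f"geometry {self.geometry.shape}"
            )
        if np.any(self.dose_values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def frame_of_reference_id(self) -> str:
        return self.geometry.frame_of_reference_id

    def copy(self) -> "DoseGrid":
        return replace(self, dose_values=self.dose_values.copy())
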