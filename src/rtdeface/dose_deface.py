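"""Propagating the defacing mask to the RT Dose grid.

The dose grid usually differs from the CT grid in origin, spacing and
extent, so the retain rule is re-evaluated analytically (z < z_inf or
y >= y_mid) at each dose voxel center in patient millimetres, while
PTV/brain preservation — which only exists as a voxel mask on the CT
grid — is looked up at the nearest CT voxel.  Dose voxels outside the CT
extent fall back to the analytic rule alone.
"""

from __future__ import annotations

import numpy as np

from .defacing import RetainMask
from .geometry import DoseGrid, GeometryError, GridGeometry

__all__ = ["resample_mask_to_dose", "deface_dose"]


def resample_mask_to_dose(
    mask: RetainMask, ct_geometry: GridGeometry, dose_geometry: GridGeometry
) -> np.ndarray:
    """Evaluate the retain rule on the dose grid.

    Returns a boolean (rows, cols, frames) keep-grid on the dose
    geometry.  Raises :class:`GeometryError` if the frames of reference
    differ.
    """
    if dose_geometry.frame_of_reference_id != ct_geometry.frame_of_reference_id:
        raise GeometryError("dose frame of reference does not match the CT's")
    lm = mask.landmarks

    y = dose_geometry.y_coords()[:, None, None]
    z = dose_geometry.z_coords()[None, None, :]
    keep = np.broadcast_to((z < lm.z_inf) | (y >= lm.y_mid), dose_geometry.shape).copy()

    # preserved-structure membership: nearest CT voxel, only where the
    # analytic rule would crop and the dose voxel lies inside the CT extent
    preserved_ct = mask.keep & ~(
        (ct_geometry.z_coords()[None, None, :] < lm.z_inf)
        | (ct_geometry.y_coords()[:, None, None] >= lm.y_mid)
    )
    if preserved_ct.any():
        xs, ys, zs = (
            dose_geometry.x_coords(),
            dose_geometry.y_coords(),
            dose_geometry.z_coords(),
        )
        ct_x0, ct_y0, _ = ct_geometry.origin
        dy, dx = ct_geometry.pixel_spacing
        ci = np.round((xs - ct_x0) / dx).astype(int)
        ri = np.round((ys - ct_y0) / dy).astype(int)
        ki = np.array(
            [int(np.argmin(np.abs(ct_geometry.slice_positions - z))) for z in zs]
        )
        in_x = (xs >= ct_geometry.x_coords()[0] - dx / 2) & (xs <= ct_geometry.x_coords()[-1] + dx / 2)
        in_y = (ys >= ct_geometry.y_coords()[0] - dy / 2) & (ys <= ct_geometry.y_coords()[-1] + dy / 2)
        gap = ct_geometry.slice_gap
        in_z = (zs >= ct_geometry.slice_positions[0] - gap / 2) & (
            zs <= ct_geometry.slice_positions[-1] + gap / 2
        )
        inside = in_y[:, None, None] & in_x[None, :, None] & in_z[None, None, :]
        ri_c = np.clip(ri, 0, ct_geometry.rows - 1)
        ci_c = np.clip(ci, 0, ct_geometry.cols - 1)
        preserved = preserved_ct[np.ix_(ri_c, ci_c, ki)] & inside
        keep |= preserved
    return keep


def deface_dose(dose: DoseGrid, dose_mask: np.ndarray) -> DoseGrid:
    """Zero every dose voxel outside the retained region.

    Retained voxels are numerically identical to the input (quantization
    happens only when the grid is re-written to disk); removed voxels are
    set to 0 Gy so the grid stays valid for downstream DVH tooling.
    """
    if dose_mask.shape != dose.dose_values.shape:
        raise GeometryError(
            f"dose mask shape {dose_mask.shape} does not match dose grid {dose.dose_values.shape}"
        )
    out = dose.copy()
    out.dose_values[~dose_mask] = 0.0
    return out
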