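"""Defacing the RT Structure Set.

Eye, lens and cornea ROIs are dropped outright; PTV and brain contours
are passed through untouched; the body contour is rebuilt from the
defaced image extent; and any other ROI protruding into the cropped
region is clipped to the retained volume.  Clipping runs in voxel space
(rasterize, intersect with the keep-grid, re-polygonize), which handles
the non-convex carve-outs the PTV/brain preservation introduces at the
cost of sub-voxel fidelity.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .contours import RoiContour, StructureSet, polygonize_mask, rasterize_roi
from .defacing import RetainMask
from .geometry import GridGeometry

logger = logging.getLogger(__name__)

__all__ = ["deface_structure_set", "clip_roi", "rebuild_body", "REMOVED_ROLES"]

#: Roles stripped from the structure set entirely (identifiable facial anatomy).
REMOVED_ROLES = frozenset({"eye", "lens", "cornea"})


def clip_roi(roi: RoiContour, mask: RetainMask, geometry: GridGeometry) -> RoiContour:
    """Clip an ROI to the retained volume.

    The output polygons are ``polygonize(rasterize(roi) AND keep)``; name
    and number are preserved.  An ROI clipped to nothing is kept with an
    empty polygon list and a logged warning rather than silently dropped.
    """
    clipped = rasterize_roi(roi, geometry) & mask.keep
    polygons = polygonize_mask(clipped, geometry)
    if not polygons:
        logger.warning("ROI %r lies entirely within the cropped region; kept empty", roi.name)
    return replace(roi, polygons=polygons)


def rebuild_body(body: RoiContour, mask: RetainMask, geometry: GridGeometry) -> RoiContour:
    """Update the body contour to follow the defaced image surface."""
    return clip_roi(body, mask, geometry)


def deface_structure_set(
    ss: StructureSet, mask: RetainMask, volume
) -> StructureSet:
    """Produce the defaced structure set.

    - eye / lens / cornea ROIs: removed;
    - PTV and brain ROIs: polygon data passed through bit-identical;
    - body: rebuilt against the retained volume;
    - any other ROI: clipped iff some of its voxels fall in the cropped
      region, otherwise returned vertex-for-vertex unchanged.

    ROI numbers and names of surviving ROIs are preserved.
    """
    geometry = volume.geometry
    out_rois: list[RoiContour] = []
    for roi in ss.rois:
        if roi.role in REMOVED_ROLES:
            logger.info("removing ROI %r (role %s)", roi.name, roi.role)
            continue
        if roi.role in ("ptv", "brain"):
            out_rois.append(roi.copy())
            continue
        if roi.role == "body":
            out_rois.append(rebuild_body(roi, mask, geometry))
            continue
        roi_mask = rasterize_roi(roi, geometry)
        if np.any(roi_mask & ~mask.keep):
            logger.info("clipping ROI %r (protrudes into the cropped region)", roi.name)
            out_rois.append(clip_roi(roi, mask, geometry))
        else:
            out_rois.append(roi.copy())
    return StructureSet(
        rois=out_rois,
        referenced_frame_of_reference_id=ss.referenced_frame_of_reference_id,
        referenced_series_id=ss.referenced_series_id,
    )
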