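"""End-to-end defacing: image, structure set and dose in one call."""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path

from . import dicom_io
from .contours import DEFAULT_ROLE_PATTERNS, StructureSet
from .defacing import (
    DEFAULT_FILL_HU,
    RetainMask,
    build_retain_mask,
    compute_landmarks,
    deface_image,
    structure_masks,
)
from .dose_deface import deface_dose, resample_mask_to_dose
from .geometry import DoseGrid, ImageVolume
from .metrics import DefaceReport, build_report
from .structset_edit import deface_structure_set

__all__ = ["deface_case", "run_deface", "DefaceResult"]


@dataclass
class DefaceResult:
    volume: ImageVolume
    structure_set: StructureSet
    dose: DoseGrid | None
    mask: RetainMask
    report: DefaceReport


def deface_case(
    volume: ImageVolume,
    ss: StructureSet,
    dose: DoseGrid | None = None,
    fill_hu: float = DEFAULT_FILL_HU,
) -> DefaceResult:
    """Deface an in-memory (CT, structure set, dose) triplet.

    Runs the three-step workflow: crop landmarks from the eye contours
    and retain-mask construction with PTV/brain preservation, structure
    set editing, and dose-grid mask resampling.  Raises
    :class:`rtdeface.defacing.MissingEyesError` if no eyes are contoured.
    """
    start = time.perf_counter()
    landmarks = compute_landmarks(ss, volume)
    ptv_mask, brain_mask = structure_masks(ss, volume)
    mask = build_retain_mask(volume, landmarks, ptv_mask, brain_mask)
    defaced = deface_image(volume, mask, fill_hu=fill_hu)
    defaced_ss = deface_structure_set(ss, mask, volume)
    defaced_dose = None
    if dose is not None:
        dose_keep = resample_mask_to_dose(mask, volume.geometry, dose.geometry)
        defaced_dose = deface_dose(dose, dose_keep)
    report = build_report(
        volume, defaced, ss, defaced_ss, dose, defaced_dose, landmarks, mask,
        wall_seconds=time.perf_counter() - start,
    )
    return DefaceResult(defaced, defaced_ss, defaced_dose, mask, report)


def run_deface(
    ct_dir: str | Path,
    rtstruct_path: str | Path,
    rtdose_path: str | Path | None,
    out_dir: str | Path,
    role_patterns: dict[str, str] | None = None,
    fill_hu: float = DEFAULT_FILL_HU,
    seed: int | None = None,
) -> DefaceReport:
    """Deface a DICOM case on disk and write the results.

    Reads the CT series, structure set and (optionally) dose, defaces
    them, writes the outputs with fresh identifiers to ``out_dir`` along
    with a JSON report, and returns the report.
    """
    patterns = role_patterns if role_patterns is not None else DEFAULT_ROLE_PATTERNS
    volume = dicom_io.read_ct_series(ct_dir)
    ss = dicom_io.read_structure_set(rtstruct_path, patterns)
    dose = dicom_io.read_dose(rtdose_path) if rtdose_path is not None else None

    result = deface_case(volume, ss, dose, fill_hu=fill_hu)
    dicom_io.write_outputs(result.volume, result.structure_set, result.dose, out_dir, seed=seed)
    out_dir = Path(out_dir)
    (out_dir / "deface_report.json").write_text(result.report.to_json())
    return result.report
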