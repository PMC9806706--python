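"""NIfTI and cohort-table input/output.

Volumes are written as NIfTI-1 with a diagonal affine built from the voxel
size; a 4-D DWI series carries its b-values in an FSL-style sidecar
(``<stem>.bval``, space-separated, same stem as the image).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortResult, SyntheticPatient
from .reduction import SegmentationSet
from .rsi import DwiSeries

__all__ = [
    "save_volume",
    "load_volume",
    "save_dwi",
    "load_dwi",
    "save_segmentation",
    "load_segmentation",
    "write_cohort",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_volume(data: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), voxel


def _bval_path(image_path: Path) -> Path:
    name = image_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return image_path.with_name(name[: -len(suffix)] + ".bval")
    return image_path.with_suffix(".bval")


def save_dwi(series: DwiSeries, path) -> Path:
    path = save_volume(series.signal, series.voxel_size_mm, path)
    _bval_path(path).write_text(" ".join(f"{b:g}" for b in series.b_values) + "\n")
    return path


def load_dwi(path, normalized: bool = False) -> DwiSeries:
    data, voxel = load_volume(path)
    bvals = tuple(float(x) for x in _bval_path(Path(path)).read_text().split())
    return DwiSeries(signal=data, b_values=bvals, voxel_size_mm=voxel, normalized=normalized)


_MASK_FILES = {
    "prostate": "mask_prostate.nii.gz",
    "peripheral_zone": "mask_peripheral_zone.nii.gz",
    "central_gland": "mask_central_gland.nii.gz",
}


def save_segmentation(seg: SegmentationSet, directory) -> Path:
    directory = Path(directory)
    for attr, fname in _MASK_FILES.items():
        save_volume(getattr(seg, attr).astype(np.float32), seg.voxel_size_mm, directory / fname)
    return directory


def load_segmentation(directory) -> SegmentationSet:
    directory = Path(directory)
    arrays = {}
    voxel = (1.0, 1.0, 1.0)
    for attr, fname in _MASK_FILES.items():
        data, voxel = load_volume(directory / fname)
        arrays[attr] = data > 0.5
    return SegmentationSet(voxel_size_mm=voxel, **arrays)


def write_cohort(cohort: CohortResult, directory) -> Path:
    """Write per-patient DWI + masks and the truth table CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for patient in cohort.patients:
        pdir = directory / patient.patient_id
        save_dwi(patient.dwi, pdir / "dwi.nii.gz")
        save_segmentation(patient.segmentation, pdir)
        save_volume(
            patient.lesion_mask.astype(np.float32),
            patient.dwi.voxel_size_mm,
            pdir / "mask_lesion.nii.gz",
        )
    cohort.table.to_csv(directory / "cohort.csv", index=False)
    return directory


def write_patient_maps(
    patient: SyntheticPatient, rsirs, adc_maps: dict, directory
) -> Path:
    directory = Path(directory)
    save_volume(rsirs.value, rsirs.voxel_size_mm, directory / "rsirs.nii.gz")
    for name, amap in adc_maps.items():
        save_volume(amap.value, amap.voxel_size_mm, directory / f"adc_{name}.nii.gz")
    return directory
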