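"""Reading DICOM series / NIfTI volumes and writing masks and reports.

A volume source is either a directory holding one DICOM series or a
single NIfTI file. DICOM slices are sorted by their position along the
slice normal; intensities are returned as stored values with the rescale
slope/intercept applied. Masks and phantoms are written as NIfTI-1, with
the voxel spacing encoded in the affine.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pydicom

from .image_model import BinaryMask, VoxelGrid
from .phantom import PhantomResult

__all__ = [
    "read_volume",
    "read_nifti",
    "read_dicom_series",
    "write_volume",
    "write_mask",
    "write_report_json",
    "write_phantom",
    "SeriesError",
    "GeometryError",
]

PathLike = Union[str, Path]

# relative tolerance on slice-gap uniformity before the geometry is rejected
_SLICE_GAP_RTOL = 0.01


class SeriesError(ValueError):
    """The DICOM directory does not contain exactly one consistent series."""


class GeometryError(ValueError):
    """Slice geometry is inconsistent (nonuniform gaps, mixed orientation)."""


def read_volume(path: PathLike) -> VoxelGrid:
    """Read a DICOM series directory or a NIfTI file into a VoxelGrid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)


def read_nifti(path: PathLike) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(data, spacing)


def read_dicom_series(directory: PathLike) -> VoxelGrid:
    """Load a single-series DICOM directory, sorted along the slice normal."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except (pydicom.errors.InvalidDicomError, IsADirectoryError):
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise SeriesError(f"no DICOM slices found in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise SeriesError(f"directory mixes {len(uids)} series UIDs")

    orientations = {tuple(round(float(v), 6) for v in ds.ImageOrientationPatient) for ds in slices}
    if len(orientations) != 1:
        raise GeometryError("slices have mixed image orientations")
    row_cos, col_cos = np.array(slices[0].ImageOrientationPatient, float).reshape(2, 3)
    normal = np.cross(row_cos, col_cos)

    positions = [float(np.dot(normal, np.array(ds.ImagePositionPatient, float))) for ds in slices]
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = [positions[i] for i in order]

    if len(slices) > 1:
        gaps = np.diff(positions)
        if np.any(gaps <= 0):
            raise GeometryError("duplicate or non-monotone slice positions")
        if (gaps.max() - gaps.min()) > _SLICE_GAP_RTOL * gaps.mean():
            raise GeometryError(f"nonuniform slice gaps: {gaps.min():.4f}..{gaps.max():.4f} mm")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)
    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    data = np.stack(arrays, axis=-1)  # (rows, cols, slices)
    return VoxelGrid(data, (row_sp, col_sp, dz))


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(grid: VoxelGrid, path: PathLike) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(grid.data.astype(np.float32), _affine(grid.spacing)), str(path))
    return path


def write_mask(mask: BinaryMask, path: PathLike,
               reference: Optional[VoxelGrid] = None) -> Path:
    """Write a 0/1 NIfTI mask; geometry must match the reference grid if given."""
    if reference is not None:
        if reference.shape != mask.shape or not np.allclose(reference.spacing, mask.spacing):
            raise ValueError(
                f"mask geometry {mask.shape}/{mask.spacing} does not match "
                f"reference {reference.shape}/{reference.spacing}"
            )
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing)), str(path))
    return path


def read_mask(path: PathLike) -> BinaryMask:
    grid = read_nifti(path)
    return BinaryMask(grid.data > 0.5, grid.spacing)


def write_report_json(report_dict: dict, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report_dict, indent=2, default=float) + "\n")
    return path


def write_phantom(result: PhantomResult, directory: PathLike, stem: str = "phantom") -> List[Path]:
    """Write a phantom as a NIfTI pair: image and ground-truth mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = write_volume(result.grid, directory / f"{stem}_image.nii")
    mask_path = write_mask(result.truth_mask, directory / f"{stem}_truth.nii")
    return [img_path, mask_path]
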