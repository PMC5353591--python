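"""Reading and writing volumes.

NIfTI is the required interchange format for dose, activity and mask volumes.
Only axis-aligned affines are accepted: the rotation/zoom block must be
diagonal. Negative diagonal entries (e.g. nibabel's RAS flips) are repaired by
flipping the corresponding array axis so that in-memory spacing is always
positive and the origin names the center of voxel (0, 0, 0). Oblique affines
raise ``ObliqueAffineError`` — this pipeline does no resampling-on-load and a
rotated volume cannot be represented on the axis-aligned grid model.

A minimal DICOM RT-DOSE reader is also provided (``DoseGridScaling`` applied,
``GridFrameOffsetVector`` for the z axis); NIfTI remains the supported path.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import BinaryMask, GeometryError, ImageGrid

_OBLIQUE_ATOL = 1e-6


class ObliqueAffineError(GeometryError):
    """NIfTI affine has off-diagonal rotation terms; not representable here."""


def _parse_affine(affine: np.ndarray, shape) -> tuple[list, tuple, tuple]:
    """Return (flip axes, spacing, origin) for an axis-aligned affine."""
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > _OBLIQUE_ATOL:
        raise ObliqueAffineError(
            "affine is oblique (off-diagonal rotation terms "
            f"up to {np.max(np.abs(off_diag)):.3g}); only axis-aligned volumes "
            "are supported"
        )
    diag = np.diag(rot)
    if np.any(diag == 0):
        raise GeometryError("affine has a zero scale on some axis")
    origin = affine[:3, 3].astype(float)
    flips = [ax for ax in range(3) if diag[ax] < 0]
    spacing = np.abs(diag)
    for ax in flips:
        # voxel (0,0,0) after the flip is old voxel (n-1) on that axis
        origin[ax] = origin[ax] + diag[ax] * (shape[ax] - 1)
    return flips, tuple(spacing), tuple(origin)


def _load_array(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {img.shape}")
    flips, spacing, origin = _parse_affine(np.asarray(img.affine), img.shape)
    data = np.asarray(img.get_fdata(), dtype=float)
    for ax in flips:
        data = np.flip(data, axis=ax)
    return np.ascontiguousarray(data), spacing, origin


def read_image(path, on_nonfinite: str = "error") -> ImageGrid:
    """Load a scalar volume (dose or activity) from NIfTI.

    ``on_nonfinite`` is ``"error"`` (reject NaN/Inf voxels) or ``"zero"``
    (repair them to 0 — useful for padded SPECT exports).
    """
    data, spacing, origin = _load_array(path)
    bad = ~np.isfinite(data)
    if bad.any():
        if on_nonfinite == "zero":
            data = np.where(bad, 0.0, data)
        else:
            raise ValueError(
                f"{path}: {int(bad.sum())} non-finite voxels "
                "(pass on_nonfinite='zero' to repair)"
            )
    return ImageGrid(data, spacing=spacing, origin=origin)


def read_mask(path) -> BinaryMask:
    """Load a binary mask stored as a 0/1 (or 0/nonzero) NIfTI volume."""
    data, spacing, origin = _load_array(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: mask contains non-finite voxels")
    return BinaryMask(data != 0, spacing=spacing, origin=origin)


def _affine_of(vol) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    return aff


def write_image(grid: ImageGrid, path) -> None:
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine_of(grid))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_of(mask))
    nib.save(img, str(path))


def read_dicom_rtdose(path) -> ImageGrid:
    """Read a DICOM RT-DOSE grid (scaled to Gy).

    Supports the common axis-aligned case: identity-like
    ``ImageOrientationPatient`` and a uniform ``GridFrameOffsetVector``.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError(f"{path}: not an RT-DOSE object (Modality={getattr(ds, 'Modality', None)!r})")
    iop = np.asarray(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float)
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise ObliqueAffineError(f"{path}: only axis-aligned RT-DOSE orientation is supported")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0], atol=1e-6):
        raise GeometryError(f"{path}: non-uniform GridFrameOffsetVector")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    # pixel_array axes are (frame, row, col) = (z, y, x); ours are (x, y, z)
    dose = ds.pixel_array.astype(float) * scaling
    dose = np.ascontiguousarray(np.transpose(dose, (2, 1, 0)))
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    spacing = (col_mm, row_mm, float(dz[0]) if offsets.size > 1 else 1.0)
    ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
    origin = (ipp[0], ipp[1], ipp[2] + offsets[0])
    return ImageGrid(dose, spacing=spacing, origin=origin)


def file_sha256(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
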