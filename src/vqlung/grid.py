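"""Axis-aligned volumetric grids and binary masks.

All voxel computation in the pipeline happens on these two containers. The
geometry convention is fixed package-wide: voxel indices are 0-based, axes are
ordered (x, y, z), ``origin`` is the patient-frame position (mm) of the
*center* of voxel (0, 0, 0), and the center of voxel (i, j, k) sits at
``origin + (i, j, k) * spacing``. A single stated convention avoids silent
half-voxel shifts between dose, activity and mask volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

#: Componentwise tolerance (mm) when comparing voxel spacings of two grids.
SPACING_ATOL_MM: float = 1e-6
#: Componentwise tolerance (mm) when comparing grid origins.
ORIGIN_ATOL_MM: float = 1e-3


class GeometryError(ValueError):
    """Invalid grid geometry (non-positive spacing, wrong rank, ...)."""


class GeometryMismatchError(ValueError):
    """Two volumes that must share a geometry do not."""


def _as_triplet(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {arr.size}")
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class ImageGrid:
    """A 3D scalar field (dose in Gy, or SPECT activity in counts).

    Parameters
    ----------
    values
        3D array of non-negative, finite scalars, axis order (x, y, z).
    spacing
        Voxel size in mm per axis; strictly positive.
    origin
        Patient-frame position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3:
            raise GeometryError(f"values must be 3D, got ndim={vals.ndim}")
        if min(vals.shape) < 1:
            raise GeometryError(f"all shape components must be >= 1, got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("grid values contain non-finite entries")
        if np.any(vals < 0):
            raise ValueError("dose/activity values must be non-negative")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", _as_triplet(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triplet(self.origin, "origin"))
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Patient-frame coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean voxel set carrying the same geometry contract as ImageGrid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 3:
            raise GeometryError(f"mask values must be 3D, got ndim={vals.ndim}")
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
            vals = vals.astype(bool)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", _as_triplet(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triplet(self.origin, "origin"))
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


Volume = ImageGrid | BinaryMask


def validate_alignment(
    a: Volume,
    b: Volume,
    spacing_atol_mm: float = SPACING_ATOL_MM,
    origin_atol_mm: float = ORIGIN_ATOL_MM,
) -> bool:
    """True iff two volumes share shape, spacing and origin within tolerance.

    Shape must match exactly; spacing within ``spacing_atol_mm`` and origin
    within ``origin_atol_mm`` componentwise, absorbing format round-tripping
    noise without hiding real misregistration. Symmetric in its arguments.
    """
    if a.shape != b.shape:
        return False
    if not np.allclose(a.spacing, b.spacing, rtol=0.0, atol=spacing_atol_mm):
        return False
    return bool(np.allclose(a.origin, b.origin, rtol=0.0, atol=origin_atol_mm))


def require_alignment(a: Volume, b: Volume, what: str = "volumes") -> None:
    if not validate_alignment(a, b):
        raise GeometryMismatchError(
            f"{what} are not aligned: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.spacing} vs {b.spacing}, origins {a.origin} vs {b.origin}"
        )


def _reference_points(reference: Volume) -> np.ndarray:
    axes = [reference.axis_coords(i) for i in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def resample_to(source: ImageGrid, reference: Volume, mode: str = "linear") -> ImageGrid:
    """Resample ``source`` onto the geometry of ``reference``.

    ``linear`` interpolates trilinearly; ``nearest`` copies nearest-voxel
    values. Reference voxels whose centers fall outside the source extent
    (the bounding box of source voxel centers) are filled with 0 — no
    activity and no dose outside the imaged volume.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if mode == "linear":
        for ax in range(3):
            if source.shape[ax] < 2:
                raise GeometryError(
                    f"linear resampling needs >= 2 voxels along axis {ax}, "
                    f"source has {source.shape[ax]}"
                )
    axes = [source.axis_coords(i) for i in range(3)]
    interp = RegularGridInterpolator(
        axes, source.values, method=mode, bounds_error=False, fill_value=0.0
    )
    out = interp(_reference_points(reference)).reshape(reference.shape)
    # trilinear weights can produce -1e-17 on exactly-zero neighborhoods
    np.clip(out, 0.0, None, out=out)
    return ImageGrid(out, spacing=reference.spacing, origin=reference.origin)


def resample_mask_to(source: BinaryMask, reference: Volume) -> BinaryMask:
    """Nearest-neighbor resampling for masks; preserves binarity.

    Out-of-extent reference voxels are False.
    """
    f = [
        (reference.axis_coords(i)[:, None] - source.origin[i]) / source.spacing[i]
        for i in range(3)
    ]
    idx = [np.rint(fi).astype(int).ravel() for fi in f]
    inside = [
        (fi.ravel() >= -0.5) & (fi.ravel() <= source.shape[i] - 0.5)
        for i, fi in enumerate(f)
    ]
    clipped = [np.clip(ix, 0, source.shape[i] - 1) for i, ix in enumerate(idx)]
    gx, gy, gz = np.meshgrid(*clipped, indexing="ij")
    ok = np.ones(reference.shape, dtype=bool)
    for axis, ins in enumerate(inside):
        sl = [None, None, None]
        sl[axis] = slice(None)
        ok &= ins[tuple(sl)]
    out = np.zeros(reference.shape, dtype=bool)
    out[ok] = source.values[gx[ok], gy[ok], gz[ok]]
    return BinaryMask(out, spacing=reference.spacing, origin=reference.origin)


def mask_intersect(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    require_alignment(a, b, "masks")
    return BinaryMask(a.values & b.values, spacing=a.spacing, origin=a.origin)


def mask_union(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    require_alignment(a, b, "masks")
    return BinaryMask(a.values | b.values, spacing=a.spacing, origin=a.origin)


def mask_difference(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxels in ``a`` and not in ``b``."""
    require_alignment(a, b, "masks")
    return BinaryMask(a.values & ~b.values, spacing=a.spacing, origin=a.origin)


def mask_volume(m: BinaryMask) -> float:
    """Mask volume in cm^3: true-voxel count times voxel volume (mm^3 / 1000)."""
    return m.voxel_count * m.voxel_volume_mm3 / 1000.0
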