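"""Grid checks, resampling and gray-level discretization for dual-phase CT.

The pipeline expects arterial and venous phases already registered onto a
common grid (registration is an upstream, external step).  This module
validates that assumption, resamples cases to the working spacing
(default 5 x 1 x 1 mm in (z, y, x) order) with cubic B-spline interpolation,
and discretizes in-mask Hounsfield units with a fixed bin width
(default 25 HU, minimum-anchored, IBSI "FBS").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageGrid",
    "DualPhaseCase",
    "DiscretizedRegion",
    "AlignmentError",
    "check_alignment",
    "resample",
    "discretize",
    "read_volume",
    "write_volume",
    "load_case",
]

DEFAULT_SPACING = (5.0, 1.0, 1.0)  # mm, (z, y, x)
DEFAULT_BIN_WIDTH = 25.0  # HU


class AlignmentError(ValueError):
    """Raised when the two phases or the mask do not share one grid."""


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice: shape in voxels, spacing and origin in mm, (z, y, x)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class DualPhaseCase:
    """Aligned arterial/venous volumes plus a binary tumor mask on one grid."""

    arterial: np.ndarray
    venous: np.ndarray
    mask: np.ndarray
    grid: ImageGrid
    case_id: str = "case"
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.arterial = np.asarray(self.arterial, dtype=float)
        self.venous = np.asarray(self.venous, dtype=float)
        self.mask = np.asarray(self.mask)
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.uint8)
        if self.mask.sum() < 1:
            raise ValueError("mask must contain at least one voxel")

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DiscretizedRegion:
    """Integer gray levels (1..level_count) for the in-mask voxels of a region."""

    levels: np.ndarray  # 1-D, one entry per in-mask voxel
    bin_width: float
    level_count: int
    intensity_min: float

    def __post_init__(self) -> None:
        if self.levels.min() < 1:
            raise ValueError("levels must start at 1")


def check_alignment(case: DualPhaseCase, tol: float = 1e-6) -> DualPhaseCase:
    """Validate that both phases and the mask live on one grid.

    Returns the case unchanged on success; raises :class:`AlignmentError`
    naming the first offending field otherwise.
    """
    shape = case.grid.shape
    for name, arr in (("arterial", case.arterial), ("venous", case.venous), ("mask", case.mask)):
        if tuple(arr.shape) != tuple(shape):
            raise AlignmentError(
                f"{name} shape {tuple(arr.shape)} does not match grid shape {tuple(shape)}"
            )
    # grids constructed per-volume upstream must agree within tolerance
    if case.arterial.shape != case.venous.shape:
        raise AlignmentError("arterial/venous shape mismatch")
    return case


def _grids_agree(a: ImageGrid, b: ImageGrid, tol: float = 1e-6) -> None:
    if tuple(a.shape) != tuple(b.shape):
        raise AlignmentError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.max(np.abs(np.subtract(a.spacing, b.spacing))) > tol:
        raise AlignmentError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if np.max(np.abs(np.subtract(a.origin, b.origin))) > tol:
        raise AlignmentError(f"origin mismatch: {a.origin} vs {b.origin}")


def assemble_case(
    arterial: tuple[np.ndarray, ImageGrid],
    venous: tuple[np.ndarray, ImageGrid],
    mask: tuple[np.ndarray, ImageGrid],
    case_id: str = "case",
    label: Optional[int] = None,
    tol: float = 1e-6,
) -> DualPhaseCase:
    """Combine three independently-loaded volumes, enforcing grid agreement."""
    a_arr, a_grid = arterial
    v_arr, v_grid = venous
    m_arr, m_grid = mask
    _grids_agree(a_grid, v_grid, tol)
    _grids_agree(a_grid, m_grid, tol)
    return DualPhaseCase(a_arr, v_arr, m_arr > 0.5, a_grid, case_id=case_id, label=label)


def _to_sitk(arr: np.ndarray, grid: ImageGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))
    img.SetSpacing(tuple(grid.spacing[::-1]))  # sitk wants (x, y, z)
    img.SetOrigin(tuple(grid.origin[::-1]))
    return img


def _resample_one(
    arr: np.ndarray, grid: ImageGrid, target_spacing: tuple[float, float, float], interp
) -> tuple[np.ndarray, ImageGrid]:
    img = _to_sitk(arr, grid)
    new_shape = tuple(
        int(round(n * s / t)) for n, s, t in zip(grid.shape, grid.spacing, target_spacing)
    )
    new_shape = tuple(max(1, n) for n in new_shape)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(float(t) for t in target_spacing[::-1]))
    res.SetSize(tuple(int(n) for n in new_shape[::-1]))
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interp)
    res.SetDefaultPixelValue(float(np.min(arr)))
    out = sitk.GetArrayFromImage(res.Execute(img))
    new_grid = ImageGrid(tuple(out.shape), tuple(float(t) for t in target_spacing), grid.origin)
    return out, new_grid


def resample(
    case: DualPhaseCase, target_spacing: tuple[float, float, float] = DEFAULT_SPACING
) -> DualPhaseCase:
    """Resample a case to ``target_spacing`` (mm, (z, y, x)).

    Intensities use cubic B-spline interpolation; the mask uses nearest
    neighbour and is re-binarized.  Raises if the mask vanishes.
    """
    check_alignment(case)
    art, grid = _resample_one(case.arterial, case.grid, target_spacing, sitk.sitkBSpline)
    ven, _ = _resample_one(case.venous, case.grid, target_spacing, sitk.sitkBSpline)
    msk, _ = _resample_one(
        case.mask.astype(np.float64), case.grid, target_spacing, sitk.sitkNearestNeighbor
    )
    msk = (msk > 0.5).astype(np.uint8)
    if msk.sum() < 1:
        raise ValueError("mask is empty after resampling")
    return DualPhaseCase(art, ven, msk, grid, case_id=case.case_id, label=case.label)


def discretize(values: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedRegion:
    """Fixed-bin-size discretization anchored at the region minimum.

    ``level(x) = floor((x - min) / bin_width) + 1``; a constant region maps
    to the single level 1.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 1:
        raise ValueError("need at least one in-mask voxel")
    if not np.isfinite(values).all():
        raise ValueError("non-finite intensities in region")
    lo = float(values.min())
    levels = np.floor((values - lo) / float(bin_width)).astype(np.int64) + 1
    return DiscretizedRegion(
        levels=levels,
        bin_width=float(bin_width),
        level_count=int(levels.max()),
        intensity_min=lo,
    )


# ---------------------------------------------------------------------------
# I/O (NIfTI via nibabel-compatible SimpleITK readers; NRRD via SimpleITK)

def read_volume(path: str) -> tuple[np.ndarray, ImageGrid]:
    """Read a NIfTI or NRRD volume; returns (array (z,y,x), grid)."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(float)
    grid = ImageGrid(tuple(arr.shape), tuple(img.GetSpacing()[::-1]), tuple(img.GetOrigin()[::-1]))
    return arr, grid


def write_volume(path: str, arr: np.ndarray, grid: ImageGrid) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd) by extension."""
    img = _to_sitk(np.asarray(arr, dtype=float), grid)
    sitk.WriteImage(img, str(path))


def load_case(
    arterial_path: str,
    venous_path: str,
    mask_path: str,
    case_id: str = "case",
    label: Optional[int] = None,
) -> DualPhaseCase:
    """Load one case from three image files, enforcing grid agreement."""
    return assemble_case(
        read_volume(arterial_path),
        read_volume(venous_path),
        read_volume(mask_path),
        case_id=case_id,
        label=label,
    )
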