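"""The 14 mesh-based 3-D shape features.

Surface quantities come from a marching-cubes mesh of the (zero-padded)
binary mask at physical spacing; axis lengths come from the eigenvalues of
the physical-coordinate covariance of the mask voxels (axis length =
4 * sqrt(lambda), the full axis of the equivalent ellipsoid).  Degenerate
masks (too thin for a mesh) fall back to voxel-based values and emit a
warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

SHAPE_NAMES = [
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
]


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Diameter of a point set, via its convex hull when possible."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 4:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # flat set: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


MESH_SIGMA = 0.6  # voxels; pre-smoothing of the binary field before meshing


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    # marching cubes on the raw binary field overestimates the area of
    # digitized smooth surfaces by ~9%; a sub-voxel Gaussian smoothing of the
    # indicator restores convergence (sphere sphericity ~0.98 instead of 0.91)
    padded = gaussian_filter(np.pad(mask.astype(float), 2), MESH_SIGMA)
    verts, faces, *_ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0))


def shape(mask: np.ndarray, spacing) -> dict[str, float]:
    """Compute the 14 shape features for a binary mask at ``spacing`` (z,y,x) mm."""
    mask = np.asarray(mask) > 0
    n = int(mask.sum())
    if n < 1:
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(spacing.prod())

    coords = np.column_stack(np.nonzero(mask)).astype(float) * spacing  # physical mm

    try:
        if n == 1:
            raise ValueError("single-voxel mask")
        verts, faces = _mesh(mask, spacing)
        surface_area = float(mesh_surface_area(verts, faces))
        mesh_volume = _mesh_volume(verts, faces)
        # padding shifted coordinates by one voxel; irrelevant for distances
        hull_pts = verts
    except (ValueError, RuntimeError):
        warnings.warn("degenerate mask: voxel-based shape fallback", stacklevel=2)
        mesh_volume = n * voxel_volume
        # cuboid surface approximation from voxel faces
        surface_area = float(
            2 * n * (spacing[0] * spacing[1] + spacing[0] * spacing[2] + spacing[1] * spacing[2])
        )
        half = spacing / 2.0
        offs = np.array([[sz, sy, sx] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
        hull_pts = (coords[:, None, :] + offs[None, :, :] * half).reshape(-1, 3)

    sphericity = (36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / surface_area

    max3d = _max_pairwise_distance(hull_pts)
    # in-plane (axial), coronal-ish and sagittal-ish maximum diameters
    max2d_slice = _max_pairwise_distance(hull_pts[:, [1, 2]])
    max2d_column = _max_pairwise_distance(hull_pts[:, [0, 2]])
    max2d_row = _max_pairwise_distance(hull_pts[:, [0, 1]])

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_column,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
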