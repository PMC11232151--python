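"""Morphological (shape) features of a binary lesion mask.

Volume and surface area come from the marching-cubes mesh of the mask so
sphericity is stable under resampling; axis lengths come from the principal
components of the physical voxel-centre coordinates (lengths are
4*sqrt(eigenvalue), the convention that makes an ellipsoid's axis length
equal its diameter).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    # Mild Gaussian smoothing before meshing suppresses the voxel staircase
    # that would otherwise inflate the surface area of digital shapes; thin
    # structures that would vanish under smoothing fall back to the raw mask.
    padded = np.pad(mask.astype(float), 2)
    from scipy import ndimage
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    surface = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(surface, level=0.5, spacing=spacing)
    verts = verts - 2 * np.asarray(spacing)  # undo padding offset
    return verts, faces

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    # divergence theorem over signed tetrahedra
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def _max_diameter_in_plane(coords: np.ndarray, fixed_axis: int) -> float:
    """Largest in-plane distance between voxel centres, maximized over slices
    perpendicular to ``fixed_axis``."""
    best = 0.0
    plane = [ax for ax in range(3) if ax != fixed_axis]
    vals = np.unique(coords[:, fixed_axis])
    for v in vals:
        pts = coords[coords[:, fixed_axis] == v][:, plane]
        if len(pts) >= 2:
            best = max(best, _max_pairwise(pts))
    return best


def compute_shape_features(mask: np.ndarray,
                           spacing: tuple[float, float, float]) -> dict[str, float]:
    """The 14 morphological features of a nonempty binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape features require a nonempty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))
    nvox = int(mask.sum())

    verts, faces = _mesh(mask, spacing)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)

    coords = np.argwhere(mask) * np.asarray(spacing)
    centered = coords - coords.mean(axis=0)
    if nvox > 1:
        cov = centered.T @ centered / nvox
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    sphericity = (36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / surface_area
    hull_pts = verts
    features = {
        "MeshVolume": mesh_volume,
        "VoxelVolume": nvox * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_pairwise(hull_pts),
        "Maximum2DDiameterSlice": _max_diameter_in_plane(coords, fixed_axis=2),
        "Maximum2DDiameterColumn": _max_diameter_in_plane(coords, fixed_axis=1),
        "Maximum2DDiameterRow": _max_diameter_in_plane(coords, fixed_axis=0),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
    return features
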