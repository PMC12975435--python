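"""Shape features of a binary lesion mask in physical (mm) units.

Mesh-based quantities (volume, surface area) come from a marching-cubes
triangulation of the zero-padded mask at iso-level 0.5; axis lengths come
from the eigenvalues of the physical-coordinate covariance matrix
(principal-axes, 4*sqrt(lambda) convention). Degenerate masks (too few or
perfectly coplanar voxels) fall back to 0 for the quantities that are
undefined on them.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["shape_features"]


def _mesh(mask: np.ndarray, spacing):
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # coplanar / degenerate: brute force below
    return float(pdist(points).max())


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    vv = float(np.prod(spacing))
    coords = np.argwhere(mask).astype(float) * np.asarray(spacing)
    n = len(coords)

    f: dict[str, float] = {"VoxelVolume": n * vv}

    verts, faces = _mesh(mask, spacing)
    volume = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    f["MeshVolume"] = volume
    f["SurfaceArea"] = area
    f["SurfaceVolumeRatio"] = area / volume if volume > 0 else 0.0
    f["Sphericity"] = (
        (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area if area > 0 else 0.0
    )

    f["Maximum3DDiameter"] = _max_pairwise(coords)
    # in-plane diameters: max pairwise distance among voxels sharing an index
    # along the fixed axis (axis 0 = slice plane, 1 = column plane, 2 = row)
    for axis, name in ((0, "Maximum2DDiameterSlice"),
                       (1, "Maximum2DDiameterColumn"),
                       (2, "Maximum2DDiameterRow")):
        best = 0.0
        idx = np.argwhere(mask)
        for plane in np.unique(idx[:, axis]):
            pts = coords[idx[:, axis] == plane][:, [a for a in range(3) if a != axis]]
            best = max(best, _max_pairwise(pts))
        f[name] = best

    if n > 1:
        lam = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        lam = np.clip(lam, 0.0, None)
        f["MajorAxisLength"] = float(4.0 * np.sqrt(lam[0]))
        f["MinorAxisLength"] = float(4.0 * np.sqrt(lam[1]))
        f["LeastAxisLength"] = float(4.0 * np.sqrt(lam[2]))
        f["Elongation"] = float(np.sqrt(lam[1] / lam[0])) if lam[0] > 0 else 0.0
        f["Flatness"] = float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 0.0
    else:
        for name in ("MajorAxisLength", "MinorAxisLength", "LeastAxisLength",
                     "Elongation", "Flatness"):
            f[name] = 0.0
    return f
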