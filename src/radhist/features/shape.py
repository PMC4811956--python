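"""3D shape descriptors of a binary tumor mask.

Volume is voxel counting times the physical voxel volume; surface area is
exact voxel-face counting (the sum of exposed faces, each weighted by its
physical area), which is exact for axis-aligned shapes and deterministic for
everything else.  Sphericity and its relatives compare the mask's surface
area against that of a sphere of equal volume, so sphericity <= 1 with
equality only in the isoperimetric limit.  The maximal 3D diameter is the
largest distance between any two mask voxel centers (computed on the mask
surface voxels, which always contain the extremal pair).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES = (
    "volume", "surface_area", "surface_to_volume_ratio", "sphericity",
    "compactness1", "compactness2", "spherical_disproportion", "max_3d_diameter",
)


def _surface_area(mask: np.ndarray, spacing) -> float:
    area = 0.0
    face = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    padded = np.pad(mask, 1).astype(np.int8)
    for ax in range(3):
        diff = np.diff(padded, axis=ax)
        area += float(np.abs(diff).sum()) * face[ax]
    return area


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(mask.astype(bool) & ~interior)


def _max_diameter(mask: np.ndarray, spacing) -> float:
    pts = _surface_voxels(mask).astype(float) * np.asarray(spacing, dtype=float)
    if len(pts) == 1:
        return 0.0
    # surface voxels of small masks are few; pdist is fine at study sizes
    return float(pdist(pts).max())


def shape_features(mask, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """The 8 shape features of a 0/1 mask, all in mm-based units."""
    from ..image import as_mask

    m = as_mask(mask).flags
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))
    volume = m.sum() * voxel_volume
    area = _surface_area(m, spacing)
    radius_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * np.pi * radius_eq ** 2
    return {
        "volume": float(volume),
        "surface_area": float(area),
        "surface_to_volume_ratio": float(area / volume),
        "sphericity": float(sphere_area / area),
        "compactness1": float(volume / (np.sqrt(np.pi) * area ** 1.5)),
        "compactness2": float(36.0 * np.pi * volume ** 2 / area ** 3),
        "spherical_disproportion": float(area / sphere_area),
        "max_3d_diameter": _max_diameter(m, spacing),
    }
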