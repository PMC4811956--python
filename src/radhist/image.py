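"""Lightweight containers for 3D image volumes and aligned binary tumor masks.

Arrays are plain numpy with axis order (axis0, axis1, axis2); ``spacing``
gives the physical voxel size in mm along the same axes.  No resampling is
performed anywhere in the package: a mask must live on the grid of its image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "TumorMask"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D intensity grid (HU for CT) with per-axis voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("ImageVolume requires a 3D array with all dims >= 1")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive lengths (mm)")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class TumorMask:
    """A binary (0/1) mask on the same grid as its image."""

    flags: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.flags)
        if arr.ndim != 3:
            raise ValueError("TumorMask requires a 3D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be 0/1")
        arr = arr.astype(bool)
        if not arr.any():
            raise ValueError("mask must contain at least one foreground voxel")
        object.__setattr__(self, "flags", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())


def as_volume(obj, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    if isinstance(obj, ImageVolume):
        return obj
    return ImageVolume(np.asarray(obj, dtype=float), spacing)


def as_mask(obj) -> TumorMask:
    if isinstance(obj, TumorMask):
        return obj
    return TumorMask(np.asarray(obj))
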