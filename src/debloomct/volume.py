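"""Core voxel-volume container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid Hounsfield range for 12-bit CT data.
HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class ImageVolume:
    """A 3-D grid of Hounsfield Units with physical voxel spacing.

    Parameters
    ----------
    voxels :
        3-D float array of HU values, indexed ``(x, y, z)``.
    spacing :
        Voxel edge lengths in mm per axis, all strictly positive.
    origin :
        World-space (mm) position of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing, self.origin)

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """New volume with the same geometry but different voxel data."""
        return ImageVolume(voxels, self.spacing, self.origin)
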