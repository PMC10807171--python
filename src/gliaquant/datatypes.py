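"""Core in-memory containers shared by all analysis stages.

All rasters use (row, col) = (y, x) array indexing; stacks are (z, y, x).
Angles are measured in degrees from the image x-axis (columns), in array
coordinates, and reduced to [0, 180) where only orientation matters.
Physical calibration travels with the data: pixel size in µm/px and the
z-interval in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A single-channel confocal z-stack with physical calibration.

    Parameters
    ----------
    voxels : ndarray, shape (z, y, x)
        Intensity values. A 2D array is promoted to a single-plane stack.
    pixel_size : float
        Lateral pixel size, µm/px.
    z_step : float
        Axial spacing between planes, µm (0.5 µm is the usual acquisition).
    """

    voxels: np.ndarray
    pixel_size: float
    z_step: float = 0.5

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[np.newaxis, ...]
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (z, y, x) array with >= 1 plane")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm/px)")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive (µm)")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def project(self, how: str = "max") -> np.ndarray:
        """Merge the stack into a single plane ('max' or 'sum')."""
        if how == "max":
            return self.voxels.max(axis=0)
        if how == "sum":
            return self.voxels.sum(axis=0)
        raise ValueError(f"unknown projection {how!r}; use 'max' or 'sum'")

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float, z_step: float = 0.5) -> "ImageStack":
        return cls(tifffile.imread(str(path)), pixel_size, z_step)

    def to_tiff(self, path: str | Path) -> None:
        arr = self.voxels
        if np.issubdtype(arr.dtype, np.floating):
            # 16-bit output; clip to the representable range
            arr = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
        tifffile.imwrite(str(path), arr)


@dataclass
class CellGeometry:
    """Cell outline, nucleus and long-axis orientation of one cell.

    The cell outline is what a DIC image provides in practice; the nucleus
    comes from a DNA stain. ``long_axis_angle`` is the orientation of the
    cell's principal axis in degrees, [0, 180).
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    pixel_size: float
    long_axis_angle: float = 0.0

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValueError("cell and nucleus masks must share a shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm/px)")
        if not self.cell_mask.any():
            raise ValueError("cell mask is empty")
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError("nucleus mask must lie inside the cell mask")
        self.long_axis_angle = float(self.long_axis_angle) % 180.0

    @property
    def cell_area_px(self) -> int:
        return int(self.cell_mask.sum())

    @property
    def cell_area_um2(self) -> float:
        return self.cell_area_px * self.pixel_size**2

    @property
    def nucleus_area_px(self) -> int:
        return int(self.nucleus_mask.sum())


@dataclass
class RegionSet:
    """Cell subregions used for occupancy measurements.

    ``subplasmalemmal_mask`` is the annular band between the cell outline and
    an outline shrunk to ``shrink_fraction`` of the cell area;
    ``inner_mask`` is that shrunk outline, so band and inner partition the
    cell. ``perinuclear_mask`` covers twice the nuclear area (nucleus
    included) unless the cell boundary clips it, in which case
    ``perinuclear_clipped`` is set.
    """

    subplasmalemmal_mask: np.ndarray
    inner_mask: np.ndarray
    shrink_fraction: float
    perinuclear_mask: np.ndarray | None = None
    perinuclear_clipped: bool = False
    warnings: list[str] = field(default_factory=list)
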