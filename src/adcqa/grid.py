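"""Voxel-grid geometry shared by the simulator, ADC maps and ROI placement.

Conventions: arrays are indexed (slice, row, col) = (z, y, x); voxel indices
are 0-based; physical coordinates (mm) are taken at voxel centers, and the
grid is centered on the origin so that the phantom axis sits at (x, y) = (0, 0)
when the object is simulated (or acquired) centered in the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Regular axis-aligned voxel grid.

    Parameters
    ----------
    shape : tuple of int
        ``(n_slices, n_rows, n_cols)``.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in mm.  ``dz`` is the slice *spacing* (thickness
        plus gap), which is what locates voxel centers along the slice axis.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of voxels along one axis."""
        n = self.shape[axis]
        d = self.voxel_size[axis]
        return (np.arange(n) - (n - 1) / 2.0) * d

    def inplane_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) coordinate meshes of shape (n_rows, n_cols), mm."""
        y = self.axis_coords(1)
        x = self.axis_coords(2)
        return np.meshgrid(y, x, indexing="ij")

    @property
    def n_slices(self) -> int:
        return self.shape[0]

    def central_slices(self, n: int = 3) -> list[int]:
        """Indices of the ``n`` central slices.

        The center is the lower-median slice ``(n_slices - 1) // 2``; for odd
        slice counts this is the true middle, for even counts the lower median.
        """
        c = (self.n_slices - 1) // 2
        half = (n - 1) // 2
        lo = c - half
        hi = lo + n
        if lo < 0 or hi > self.n_slices:
            raise ValueError(
                f"cannot take {n} central slices from a {self.n_slices}-slice grid"
            )
        return list(range(lo, hi))

    def disk_mask(self, center_xy: tuple[float, float], diameter_mm: float) -> np.ndarray:
        """In-plane boolean mask of pixels whose *centers* fall inside a circle.

        Degenerate circles smaller than one pixel still claim the pixel
        nearest the center, so a mask is never empty.
        """
        ym, xm = self.inplane_mesh()
        cx, cy = center_xy
        r = diameter_mm / 2.0
        mask = (xm - cx) ** 2 + (ym - cy) ** 2 <= r**2
        if not mask.any():
            j = int(np.argmin(np.abs(self.axis_coords(1) - cy)))
            i = int(np.argmin(np.abs(self.axis_coords(2) - cx)))
            mask[j, i] = True
        return mask
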