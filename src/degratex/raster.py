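"""Lightweight in-memory raster grid.

All pipeline stages operate on grids in raster row/col space: row 0 is the
top of the image, coordinates are 0-based, and windows are half-open. The
only georeferencing carried along is the pixel size (metres) and the grid
origin, which is enough for the grid-local science done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster"]


@dataclass
class Raster:
    """A 2-D value grid with an invalid-data mask.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Cell values. dtype is preserved.
    mask : ndarray of bool, same shape
        True where the cell is *invalid* (nodata).
    pixel_size : float
        Cell edge length in metres.
    origin : tuple of float
        (x, y) of the top-left corner, metres. Purely informational.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    pixel_size: float = 3.125
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D (or 3-D band stack)")
        if self.mask is None:
            if np.issubdtype(self.data.dtype, np.floating):
                self.mask = ~np.isfinite(self.data)
            else:
                self.mask = np.zeros(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        """Data with invalid cells as NaN (float view)."""
        out = self.data.astype(float).copy()
        out[self.mask] = np.nan
        return out

    def unmasked(self) -> np.ndarray:
        """1-D array of valid cell values."""
        return self.data[~self.mask]

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.data.shape[-2:] == other.data.shape[-2:]
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "Raster":
        return Raster(
            self.data.copy(),
            self.mask.copy(),
            self.pixel_size,
            tuple(self.origin),
            dict(self.meta),
        )
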