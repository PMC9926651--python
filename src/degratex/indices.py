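"""Enhanced Vegetation Index from blue/red/NIR surface reflectance.

EVI = G * (NIR - Red) / (NIR + C1*Red - C2*Blue + L) with the standard
coefficients G = 2.5, C1 = 6, C2 = 7.5, L = 1. Inputs are reflectances on
the 0-1 scale; a scale divisor is accepted for sensor-native integer
encodings. Pixels where the denominator is <= 0 are set to nodata rather
than producing unbounded values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Raster

__all__ = ["BandSet", "compute_evi", "bands_from_evi"]

G, C1, C2, L = 2.5, 6.0, 7.5, 1.0


@dataclass
class BandSet:
    """Aligned blue, red and NIR reflectance rasters with a unioned mask."""

    blue: Raster
    red: Raster
    nir: Raster

    def __post_init__(self) -> None:
        if not (self.blue.same_grid(self.red) and self.blue.same_grid(self.nir)):
            raise ValueError("bands must share shape, pixel size and origin")

    @property
    def mask(self) -> np.ndarray:
        return self.blue.mask | self.red.mask | self.nir.mask


def compute_evi(bands: BandSet, scale: float = 1.0) -> Raster:
    """Per-pixel EVI raster; nodata wherever any band is masked,
    reflectance is out of [0, 1], or the denominator is nonpositive."""
    blue = bands.blue.data.astype(float) / scale
    red = bands.red.data.astype(float) / scale
    nir = bands.nir.data.astype(float) / scale

    mask = bands.mask.copy()
    with np.errstate(invalid="ignore"):
        out_of_range = (
            (blue < 0) | (blue > 1) | (red < 0) | (red > 1) | (nir < 0) | (nir > 1)
        )
    mask |= out_of_range & ~bands.mask

    denom = nir + C1 * red - C2 * blue + L
    bad_denom = denom <= 0
    mask |= bad_denom
    with np.errstate(divide="ignore", invalid="ignore"):
        evi = G * (nir - red) / denom
    evi[mask] = np.nan
    return Raster(evi, mask, bands.blue.pixel_size, bands.blue.origin)


def bands_from_evi(evi: Raster, red: float = 0.06, blue: float = 0.03) -> BandSet:
    """Synthesize a reflectance BandSet whose EVI equals the given raster.

    Red and blue are held at constant plausible canopy reflectances and the
    NIR band is solved from the EVI identity:
    NIR = (EVI * (C1*Red - C2*Blue + L) + G*Red) / (G - EVI).
    Valid for EVI < G with the resulting NIR in [0, 1]; used to exercise
    the index computation on synthetic landscapes, where EVI is generated
    directly.
    """
    e = evi.data.astype(float)
    nir = (e * (C1 * red - C2 * blue + L) + G * red) / (G - e)
    bad = evi.mask | (nir < 0) | (nir > 1)
    mk = lambda arr: Raster(arr, bad.copy(), evi.pixel_size, evi.origin,
                            dict(evi.meta))  # noqa: E731
    return BandSet(
        mk(np.full_like(nir, blue)), mk(np.full_like(nir, red)), mk(nir)
    )
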