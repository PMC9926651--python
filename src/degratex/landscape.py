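"""Synthetic degraded-forest landscapes.

Generates per-site rasters with the statistical structure the downstream
analysis assumes: a smooth intact canopy (spatially correlated vegetation
index), selective-logging patches carrying linear roads and small log-deck
clearings, and burned patches with a diffuse index depression plus
fine-grained speckle. Each disturbed patch is a pixel-aligned rectangle, so
the emitted reference polygons rasterize back to the class map exactly.

Class codes used throughout the package: 0 = intact, 1 = logged, 2 = burned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

from .raster import Raster

__all__ = [
    "CLASS_NAMES",
    "SiteConfig",
    "ReferencePolygon",
    "generate_landscape",
    "generate_acd_plots",
    "make_multisite_fixture",
]

CLASS_NAMES = ("intact", "logged", "burned")
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Canopy-texture knobs, per class. EVI is unitless; lengths are pixels.
DEFAULT_TEXTURE_PARAMS = {
    "intact": {"base_evi": 0.55, "corr_length_px": 5.0, "noise_sd": 0.05},
    "logged": {"road_spacing_px": 24, "road_width_px": 3, "road_depth": 0.25,
               "deck_size_px": 8},
    "burned": {"burn_depth": 0.18, "speckle_sd": 0.08},
}

#: Class-conditional aboveground carbon density (mean, SD), Mg C ha^-1.
#: The low-ACD regime matches lidar-derived southern-Amazon degraded
#: landscapes; the high regime a taller, denser forest.
DEFAULT_ACD_PARAMS = {
    "intact": (89.2, 10.2),
    "logged": (93.9, 16.3),
    "burned": (57.9, 35.0),
}


@dataclass
class SiteConfig:
    """Configuration for one synthetic site."""

    site_id: str
    extent: tuple[int, int] = (480, 480)
    pixel_size: float = 3.125
    image_year: int = 2018
    class_fraction: tuple[float, float, float] = (0.6, 0.25, 0.15)
    texture_params: dict = field(default_factory=lambda: _deep_copy(DEFAULT_TEXTURE_PARAMS))
    acd_params: dict = field(default_factory=lambda: dict(DEFAULT_ACD_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        frac = np.asarray(self.class_fraction, dtype=float)
        if frac.size != 3 or (frac < 0).any() or not np.isclose(frac.sum(), 1.0):
            raise ValueError("class_fraction must be 3 nonnegative values summing to 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for cls, (_, sd) in self.acd_params.items():
            if sd < 0:
                raise ValueError(f"acd_params SD for {cls!r} must be >= 0")


def _deep_copy(params: dict) -> dict:
    return {k: dict(v) for k, v in params.items()}


@dataclass
class ReferencePolygon:
    """A manually-delineated-style disturbance polygon with its event year."""

    geometry: Polygon
    dclass: str
    event_year: int

    def __post_init__(self) -> None:
        if self.dclass not in ("logged", "burned"):
            raise ValueError("dclass must be 'logged' or 'burned'")
        if not self.geometry.is_valid:
            raise ValueError("polygon geometry must be valid (non-self-intersecting)")


def _place_patches(rng, shape, target_frac, occupied):
    """Pixel-aligned rectangles covering ~target_frac of the raster.

    Rectangles may overlap others of the same class but never `occupied`
    pixels of another class. Returns (rect list, boolean cover mask).
    """
    rows, cols = shape
    total = rows * cols
    cover = np.zeros(shape, dtype=bool)
    rects: list[tuple[int, int, int, int]] = []
    attempts = 0
    lo = max(8, min(rows, cols) // 10)
    hi = max(lo + 1, min(rows, cols) // 3)
    while cover.sum() / total < target_frac and attempts < 2000:
        attempts += 1
        h = int(rng.integers(lo, hi + 1))
        w = int(rng.integers(lo, hi + 1))
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        if occupied[r0 : r0 + h, c0 : c0 + w].any():
            continue
        rects.append((r0, r0 + h, c0, c0 + w))
        cover[r0 : r0 + h, c0 : c0 + w] = True
    return rects, cover


def generate_landscape(config: SiteConfig, min_window: int = 45):
    """Generate one site's EVI raster, class map, event-year map and polygons.

    Returns ``(evi, class_map, year_map, polygons)``. The class map and the
    polygons are mutually consistent by construction: rasterizing the
    polygon rectangles reproduces the class map pixel-for-pixel.
    """
    rows, cols = config.extent
    if rows < min_window or cols < min_window:
        raise ValueError(
            f"extent {config.extent} is smaller than one GLCM window "
            f"({min_window} px); enlarge the site or shrink the window"
        )
    rng = np.random.default_rng(config.seed)
    tp = config.texture_params
    ip = tp["intact"]

    # correlated intact canopy: smoothed white noise rescaled to noise_sd
    noise = rng.standard_normal((rows, cols))
    smooth = gaussian_filter(noise, sigma=ip["corr_length_px"], mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    evi = ip["base_evi"] + ip["noise_sd"] * smooth

    class_map = np.zeros((rows, cols), dtype=np.int16)
    polygons: list[ReferencePolygon] = []
    occupied = np.zeros((rows, cols), dtype=bool)

    frac_intact, frac_logged, frac_burned = config.class_fraction
    year_lo = config.image_year - 8

    logged_rects, logged_cover = _place_patches(rng, (rows, cols), frac_logged, occupied)
    occupied |= logged_cover
    burned_rects, burned_cover = _place_patches(rng, (rows, cols), frac_burned, occupied)

    class_map[logged_cover] = CLASS_CODES["logged"]
    class_map[burned_cover] = CLASS_CODES["burned"]

    year_map = np.full((rows, cols), -1, dtype=np.int32)
    for rects, dclass in ((logged_rects, "logged"), (burned_rects, "burned")):
        for r0, r1, c0, c1 in rects:
            year = int(rng.integers(year_lo, config.image_year + 1))
            year_map[r0:r1, c0:c1] = year
            polygons.append(
                ReferencePolygon(box(c0, r0, c1, r1), dclass, year)
            )

    # logging signature: linear roads plus square log decks inside each patch
    lp = tp["logged"]
    road = np.zeros((rows, cols), dtype=bool)
    for r0, r1, c0, c1 in logged_rects:
        for c in range(c0 + lp["road_spacing_px"] // 2, c1, lp["road_spacing_px"]):
            road[r0:r1, c : min(c + lp["road_width_px"], c1)] = True
        mid = (r0 + r1) // 2
        road[mid : min(mid + lp["road_width_px"], r1), c0:c1] = True
        d = lp["deck_size_px"]
        for c in range(c0 + lp["road_spacing_px"] // 2, c1 - d, 2 * lp["road_spacing_px"]):
            road[max(r0, mid - d) : mid, c : c + d] = True
    road &= logged_cover
    evi = np.where(road, evi - lp["road_depth"], evi)

    # fire signature: diffuse depression + fine-grained speckle
    bp = tp["burned"]
    if burned_cover.any():
        speckle = rng.normal(0.0, bp["speckle_sd"], size=(rows, cols))
        evi = np.where(burned_cover, evi - bp["burn_depth"] + speckle, evi)

    evi = np.clip(evi, -1.0, 1.0)
    ps, org = config.pixel_size, (0.0, 0.0)
    return (
        Raster(evi, pixel_size=ps, origin=org, meta={"site_id": config.site_id}),
        Raster(class_map, pixel_size=ps, origin=org, meta={"site_id": config.site_id}),
        Raster(year_map, year_map < 0, pixel_size=ps, origin=org,
               meta={"site_id": config.site_id}),
        polygons,
    )


def rasterize_polygons(polygons, shape) -> np.ndarray:
    """Burn rectangle polygons into a class-code array (intact elsewhere)."""
    out = np.zeros(shape, dtype=np.int16)
    for p in polygons:
        c0, r0, c1, r1 = (int(round(v)) for v in p.geometry.bounds)
        out[r0:r1, c0:c1] = CLASS_CODES[p.dclass]
    return out


def _truncated_normal(rng, mean, sd, size):
    """Normal draws resampled until nonnegative (carbon density >= 0)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0
    return out


def generate_acd_plots(
    config: SiteConfig, class_map: Raster, plot_px: int = 16, seed: int | None = None
) -> Raster:
    """Plot-level ACD raster (one value per 50 m plot, Mg C ha^-1).

    Each plot takes the majority class of its pixels and draws its ACD from
    that class's (mean, SD), truncated at zero. ``plot_px`` is the plot edge
    in native pixels (16 px x 3.125 m = 50 m).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    cm = class_map.data
    rows, cols = cm.shape[-2:]
    prows, pcols = rows // plot_px, cols // plot_px
    if prows == 0 or pcols == 0:
        raise ValueError("class_map smaller than one ACD plot")

    blocks = cm[: prows * plot_px, : pcols * plot_px].reshape(
        prows, plot_px, pcols, plot_px
    )
    counts = np.stack(
        [(blocks == code).sum(axis=(1, 3)) for code in range(3)], axis=0
    )
    # majority class; ties broken burned > logged > intact
    plot_class = np.flip(counts, axis=0).argmax(axis=0)
    plot_class = 2 - plot_class

    present = np.unique(plot_class)
    acd = np.zeros((prows, pcols), dtype=float)
    for code in present:
        name = CLASS_NAMES[code]
        if name not in config.acd_params:
            raise ValueError(f"acd_params missing for class {name!r} present in class_map")
        mean, sd = config.acd_params[name]
        sel = plot_class == code
        acd[sel] = _truncated_normal(rng, mean, sd, int(sel.sum()))
    return Raster(
        acd,
        pixel_size=config.pixel_size * plot_px,
        origin=(0.0, 0.0),
        meta={"site_id": config.site_id, "plot_px": plot_px},
    )


@dataclass
class SiteBundle:
    config: SiteConfig
    evi: Raster
    class_map: Raster
    year_map: Raster
    polygons: list
    acd_plots: Raster


def make_multisite_fixture(seed: int, extent: tuple[int, int] = (480, 480),
                           min_window: int = 45) -> dict[str, SiteBundle]:
    """Three synthetic sites mirroring a mixed / burn-only / logging-only design.

    Site 1 ("mixed") has logging and fire in a low-carbon forest; site 2
    ("burnonly") has fire but no logging in the same carbon regime; site 3
    ("loghigh") has logging but no fire in a high-carbon forest, so its
    burned-class ACD distribution is empty and must be substituted from the
    donor sites downstream.
    """
    rng = np.random.default_rng(seed)
    high_acd = {"intact": (185.3, 31.9), "logged": (156.8, 26.0)}
    specs = [
        ("mixed", (0.60, 0.25, 0.15), dict(DEFAULT_ACD_PARAMS)),
        ("burnonly", (0.80, 0.0, 0.20), dict(DEFAULT_ACD_PARAMS)),
        ("loghigh", (0.75, 0.25, 0.0), high_acd),
    ]
    bundle: dict[str, SiteBundle] = {}
    for site_id, frac, acd in specs:
        cfg = SiteConfig(
            site_id=site_id,
            extent=extent,
            class_fraction=frac,
            acd_params=acd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        evi, class_map, year_map, polys = generate_landscape(cfg, min_window=min_window)
        acd_plots = generate_acd_plots(cfg, class_map)
        bundle[site_id] = SiteBundle(cfg, evi, class_map, year_map, polys, acd_plots)
    return bundle
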