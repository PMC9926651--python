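"""Grid-cell predictor table: aggregation, labels, purity, age filter, scaling.

Texture bands at native resolution are aggregated to the classification
grid (562.5 m cells = 180 native pixels by default) with nine statistics
each, giving 72 predictors per cell for the 8 texture metrics. Cells carry
the dominant reference class, its purity (fraction of the cell it covers),
and the most recent disturbance year; disturbances older than five years
are excluded from training because their optical signal has faded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import CLASS_NAMES
from .raster import Raster

__all__ = [
    "STAT_NAMES",
    "aggregate",
    "compute_purity",
    "attach_labels",
    "filter_recent",
    "standardize_per_site",
    "build_feature_table",
    "feature_columns",
]

STAT_NAMES = ("mean", "sd", "skewness", "rms", "min", "q1", "median", "q3", "max")

#: ties in the dominant class go to the rarer disturbance first
TIE_PRIORITY = ("burned", "logged", "intact")


def _block_view(data: np.ndarray, cell_px: int):
    rows, cols = data.shape
    nr, nc = rows // cell_px, cols // cell_px
    return data[: nr * cell_px, : nc * cell_px].reshape(nr, cell_px, nc, cell_px)


def _stats(vals: np.ndarray) -> dict[str, float]:
    n = vals.size
    mean = vals.mean()
    sd = vals.std(ddof=1) if n > 1 else 0.0
    m2 = ((vals - mean) ** 2).mean()
    m3 = ((vals - mean) ** 3).mean()
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    return {
        "mean": mean,
        "sd": sd,
        "skewness": skew,
        "rms": float(np.sqrt((vals**2).mean())),
        "min": vals.min(),
        "q1": q1,
        "median": med,
        "q3": q3,
        "max": vals.max(),
    }


def aggregate(
    feature_raster: Raster,
    cell_px: int = 180,
    statistics: tuple = STAT_NAMES,
    min_valid_frac: float = 0.5,
) -> pd.DataFrame:
    """Aggregate one texture band (or an 8-band stack) to grid cells.

    Returns one row per grid cell with columns ``<band>_<stat>``; cells with
    fewer than ``min_valid_frac`` valid pixels are dropped. Quantiles use
    linear interpolation between order statistics; the SD is the sample SD
    and skewness the population-moment ratio m3/m2^1.5 (0 when m2 = 0).
    """
    if not statistics:
        raise ValueError("statistics list must not be empty")
    if cell_px < 2:
        raise ValueError("cell_px must be >= 2")
    data = feature_raster.data
    mask = feature_raster.mask
    if data.ndim == 2:
        data = data[None]
        mask = mask[None]
    bands = feature_raster.meta.get("bands") or [f"b{i}" for i in range(data.shape[0])]

    rows = []
    nr, nc = data.shape[1] // cell_px, data.shape[2] // cell_px
    vblocks = _block_view(~mask[0], cell_px)
    for r in range(nr):
        for c in range(nc):
            ok = vblocks[r, :, c, :]
            nvalid = int(ok.sum())
            if nvalid < min_valid_frac * cell_px * cell_px:
                continue
            rec = {"cell_row": r, "cell_col": c, "valid_frac": nvalid / cell_px**2}
            for b, name in enumerate(bands):
                vals = _block_view(data[b], cell_px)[r, :, c, :][ok].astype(float)
                st = _stats(vals)
                for stat in statistics:
                    rec[f"{name}_{stat}"] = float(st[stat])
            rows.append(rec)
    return pd.DataFrame(rows)


def compute_purity(class_map: Raster, cell_px: int = 180) -> pd.DataFrame:
    """Dominant class and purity for each grid cell.

    purity = (pixels of the dominant class) / (valid pixels in the cell).
    A 50/50 tie resolves by the fixed priority burned > logged > intact.
    Fully-masked cells are dropped.
    """
    cm = class_map.data
    valid = ~class_map.mask
    nr, nc = cm.shape[0] // cell_px, cm.shape[1] // cell_px
    cblocks = _block_view(cm, cell_px)
    vblocks = _block_view(valid, cell_px)
    rows = []
    for r in range(nr):
        for c in range(nc):
            ok = vblocks[r, :, c, :]
            n = int(ok.sum())
            if n == 0:
                continue
            vals = cblocks[r, :, c, :][ok]
            counts = {name: int((vals == code).sum())
                      for code, name in enumerate(CLASS_NAMES)}
            dominant = max(TIE_PRIORITY, key=lambda k: (counts[k], -TIE_PRIORITY.index(k)))
            rows.append(
                {
                    "cell_row": r,
                    "cell_col": c,
                    "ref_class": dominant,
                    "purity": counts[dominant] / n,
                }
            )
    return pd.DataFrame(rows)


def _cell_event_year(year_map: Raster, cell_px: int) -> pd.DataFrame:
    """Most recent disturbance year per grid cell (NaN if undisturbed)."""
    ym = np.where(year_map.mask, -1, year_map.data)
    nr, nc = ym.shape[0] // cell_px, ym.shape[1] // cell_px
    blocks = _block_view(ym, cell_px)
    years = blocks.max(axis=(1, 3)).astype(float)
    years[years < 0] = np.nan
    rows = [
        {"cell_row": r, "cell_col": c, "event_year": years[r, c]}
        for r in range(nr)
        for c in range(nc)
    ]
    return pd.DataFrame(rows)


def attach_labels(
    features: pd.DataFrame,
    class_map: Raster,
    year_map: Raster | None,
    site_id: str,
    cell_px: int = 180,
) -> pd.DataFrame:
    """Join per-cell features with reference class, purity and event year."""
    purity = compute_purity(class_map, cell_px)
    out = features.merge(purity, on=["cell_row", "cell_col"], how="inner")
    if year_map is not None:
        out = out.merge(_cell_event_year(year_map, cell_px),
                        on=["cell_row", "cell_col"], how="left")
    else:
        out["event_year"] = np.nan
    # intact cells carry no disturbance year
    out.loc[out["ref_class"] == "intact", "event_year"] = np.nan
    out.insert(0, "site_id", site_id)
    return out


def filter_recent(cells: pd.DataFrame, image_year: int, max_age: int = 5) -> pd.DataFrame:
    """Drop disturbed cells older than ``max_age`` years (boundary inclusive:
    a disturbance exactly ``max_age`` years before the image is retained).
    Intact cells always pass."""
    age = image_year - cells["event_year"]
    keep = (cells["ref_class"] == "intact") | age.isna() | (age <= max_age)
    return cells.loc[keep].reset_index(drop=True)


def feature_columns(cells: pd.DataFrame) -> list[str]:
    meta = {"site_id", "cell_row", "cell_col", "valid_frac", "ref_class",
            "purity", "event_year", "_row"}
    return [c for c in cells.columns if c not in meta]


def standardize_per_site(cells: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each feature within each site (zero-SD features -> 0)."""
    out = cells.copy()
    cols = feature_columns(cells)
    for _, idx in out.groupby("site_id").groups.items():
        block = out.loc[idx, cols]
        mu = block.mean()
        sd = block.std(ddof=1).replace(0.0, np.nan)
        out.loc[idx, cols] = ((block - mu) / sd).fillna(0.0)
    return out


def build_feature_table(
    texture_stack: Raster,
    class_map: Raster,
    year_map: Raster | None,
    site_id: str,
    image_year: int,
    cell_px: int = 180,
) -> pd.DataFrame:
    """Aggregate + label + age-filter one site (standardization is applied
    after sites are concatenated)."""
    feats = aggregate(texture_stack, cell_px=cell_px)
    cells = attach_labels(feats, class_map, year_map, site_id, cell_px=cell_px)
    return filter_recent(cells, image_year)
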