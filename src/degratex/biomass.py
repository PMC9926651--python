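"""Site x class aboveground-carbon-density distributions.

Plot-level ACD (50 m, 0.25 ha) is resampled to coarse cells by the block
median (10 x 10 plot-equivalents -> 500 m, 25 ha, by default) and pooled
into one empirical distribution per site and degradation class, with no
distinction by time since disturbance. A class that never occurs at a site
(e.g. fire at a logging-only site) yields an empty distribution that must
be filled by pooling the same class from donor sites before simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import CLASS_NAMES
from .raster import Raster

__all__ = [
    "ACDDistribution",
    "resample_acd",
    "class_map_for_grid",
    "build_distributions",
    "apply_substitution",
    "summarize",
    "percent_change",
]


@dataclass
class ACDDistribution:
    """Empirical ACD sample (Mg C ha^-1) for one site x class."""

    site_id: str
    dclass: str
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    substituted_from: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("ACD values must be nonnegative")

    @property
    def empty(self) -> bool:
        return self.values.size == 0


def resample_acd(plot_raster: Raster, factor: int = 10,
                 min_valid_frac: float = 0.5) -> Raster:
    """Block-median resampling of the plot ACD raster.

    Each output cell is the median of its ``factor x factor`` unmasked
    inputs; cells with fewer than ``min_valid_frac`` valid inputs become
    nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    data = plot_raster.values  # NaN where masked
    rows, cols = data.shape
    nr, nc = rows // factor, cols // factor
    blocks = data[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(nr, nc, factor * factor)
    nvalid = np.isfinite(blocks).sum(axis=2)
    with np.errstate(all="ignore"):
        med = np.nanmedian(blocks, axis=2)
    bad = nvalid < min_valid_frac * factor * factor
    med[bad] = np.nan
    return Raster(
        med,
        pixel_size=plot_raster.pixel_size * factor,
        origin=plot_raster.origin,
        meta=dict(plot_raster.meta),
    )


def class_map_for_grid(class_map: Raster, cell_px: int) -> np.ndarray:
    """Majority class per coarse cell (ties burned > logged > intact),
    aligning a native-resolution class map to the resampled ACD grid."""
    cm = class_map.data
    nr, nc = cm.shape[0] // cell_px, cm.shape[1] // cell_px
    blocks = cm[: nr * cell_px, : nc * cell_px].reshape(nr, cell_px, nc, cell_px)
    counts = np.stack([(blocks == k).sum(axis=(1, 3)) for k in range(3)])
    return 2 - np.flip(counts, axis=0).argmax(axis=0)


def build_distributions(resampled: Raster, cell_class: np.ndarray,
                        site_id: str) -> list[ACDDistribution]:
    """Pool resampled ACD values per class for one site.

    Classes present in ``cell_class`` but with no valid ACD cell — and
    classes entirely absent — yield empty distributions (flagged, not
    dropped) so downstream substitution can see them.
    """
    data = resampled.values
    if cell_class.shape != data.shape:
        raise ValueError("cell_class must align with the resampled ACD grid")
    out = []
    for code, name in enumerate(CLASS_NAMES):
        sel = (cell_class == code) & np.isfinite(data)
        out.append(ACDDistribution(site_id, name, data[sel]))
    return out


def apply_substitution(dists: list[ACDDistribution],
                       manifest: dict | None = None) -> list[ACDDistribution]:
    """Fill empty site x class distributions by pooling the same class
    from every other site where it is nonempty (donor pooling).

    The substitution is recorded in ``manifest['substitutions']`` when a
    manifest dict is supplied. Raises if a class is empty everywhere.
    """
    by_class: dict[str, list[ACDDistribution]] = {}
    for d in dists:
        by_class.setdefault(d.dclass, []).append(d)
    out = []
    for d in dists:
        if not d.empty:
            out.append(d)
            continue
        donors = [o for o in by_class[d.dclass] if o.site_id != d.site_id and not o.empty]
        if not donors:
            raise ValueError(
                f"no donor distribution available for {d.site_id}/{d.dclass}"
            )
        pooled = np.concatenate([o.values for o in donors])
        names = tuple(o.site_id for o in donors)
        out.append(ACDDistribution(d.site_id, d.dclass, pooled, substituted_from=names))
        if manifest is not None:
            manifest.setdefault("substitutions", []).append(
                {"site_id": d.site_id, "dclass": d.dclass, "donors": list(names)}
            )
    return out


def summarize(dists: list[ACDDistribution],
              pool_sites: dict[str, tuple] | None = None) -> pd.DataFrame:
    """Per site x class mean and sample SD (n-1) of ACD.

    ``pool_sites`` optionally maps a reporting label to a tuple of site ids
    whose same-class values are pooled into one reporting unit (sites stay
    separate for simulation).
    """
    rows = []
    for d in dists:
        if d.empty:
            continue
        rows.append(
            {
                "site_id": d.site_id,
                "dclass": d.dclass,
                "n": d.values.size,
                "mean": float(d.values.mean()),
                "sd": float(d.values.std(ddof=1)) if d.values.size > 1 else 0.0,
                "substituted_from": ",".join(d.substituted_from),
            }
        )
    df = pd.DataFrame(rows)
    if pool_sites:
        pooled_rows = []
        for label, sites in pool_sites.items():
            for cls in CLASS_NAMES:
                vals = [
                    d.values
                    for d in dists
                    if d.site_id in sites and d.dclass == cls
                    and not d.empty and not d.substituted_from
                ]
                if not vals:
                    continue
                v = np.concatenate(vals)
                pooled_rows.append(
                    {
                        "site_id": label,
                        "dclass": cls,
                        "n": v.size,
                        "mean": float(v.mean()),
                        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                        "substituted_from": "",
                    }
                )
        df = pd.concat([df, pd.DataFrame(pooled_rows)], ignore_index=True)
    return df


def percent_change(intact_mean: float, other_mean: float) -> float:
    """Percent ACD change of a degraded class relative to intact:
    100 * (other - intact) / intact."""
    if intact_mean == 0:
        raise ValueError("intact mean ACD is zero; percent change undefined")
    return 100.0 * (other_mean - intact_mean) / intact_mean
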