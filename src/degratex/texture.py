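"""Moving-window gray-level co-occurrence (GLCM) texture metrics.

A co-occurrence matrix tabulates how often pairs of quantized gray levels
occur at a fixed pixel displacement inside a window. Eight Haralick-style
metrics are derived from it — mean, variance, correlation (descriptive);
contrast, homogeneity, dissimilarity (contrast group); angular second
moment and entropy (orderliness). Metrics are computed per displacement
direction and then averaged across directions, which removes directional
effects. Co-occurrence counting is symmetric (each pair counted in both
orders) and entropy uses the natural logarithm.

Two engines produce the moving-window product: a naive per-window engine
that composes :func:`cooccurrence` and :func:`glcm_metrics` literally, and
a fast engine built on exact integer integral-image box sums over level-pair
indicator planes. The two agree to floating-point error (< 1e-10) by
construction; tests enforce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import Raster

__all__ = [
    "METRIC_NAMES",
    "GLCMConfig",
    "quantize",
    "cooccurrence",
    "glcm_metrics",
    "windowed_glcm",
]

#: Fixed band order of every texture product.
METRIC_NAMES = (
    "mean",
    "variance",
    "correlation",
    "contrast",
    "homogeneity",
    "dissimilarity",
    "asm",
    "entropy",
)

DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class GLCMConfig:
    """Texture-engine parameters.

    window is the moving-window edge in pixels (odd; 45 px = 140.625 m at
    3.125 m pixels); levels the number of gray levels after quantization;
    offsets the unit displacements averaged over.
    """

    window: int = 45
    levels: int = 32
    offsets: tuple = DEFAULT_OFFSETS
    metrics: tuple = METRIC_NAMES

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.offsets:
            raise ValueError("offsets must be nonempty")


def quantize(raster: Raster, levels: int = 32) -> Raster:
    """Equal-width quantization of the unmasked value range to ``levels`` bins.

    The minimum maps to level 0 and the maximum to ``levels - 1``; the
    mapping is monotone. A constant raster maps entirely to level 0.
    """
    valid = ~raster.mask
    if not valid.any():
        raise ValueError("cannot quantize an all-masked raster")
    vals = raster.data.astype(float)
    lo = vals[valid].min()
    hi = vals[valid].max()
    q = np.zeros(raster.data.shape, dtype=np.int32)
    if hi > lo:
        q[valid] = np.minimum(
            ((vals[valid] - lo) / (hi - lo) * levels).astype(np.int64), levels - 1
        )
    return Raster(q, raster.mask.copy(), raster.pixel_size, raster.origin,
                  {**raster.meta, "levels": levels})


def cooccurrence(
    window: np.ndarray,
    offset: tuple[int, int],
    levels: int | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix of one window.

    Each valid pixel pair separated by ``offset`` is counted in both orders;
    the matrix therefore equals its transpose and sums to 1. Pairs touching
    a masked pixel are excluded.
    """
    window = np.asarray(window)
    dr, dc = offset
    H, W = window.shape
    if levels is None:
        levels = int(window.max()) + 1
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("window too small along the offset direction")
    a = window[r0:r1, c0:c1]
    b = window[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if mask is not None:
        ok = ~mask[r0:r1, c0:c1] & ~mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a, b = a[ok], b[ok]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size == 0:
        raise ValueError("no valid pixel pairs in window")
    counts = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    np.add.at(counts, (b, a), 1)
    return counts / counts.sum()


def glcm_metrics(P: np.ndarray) -> dict[str, float]:
    """The eight texture metrics of one symmetric co-occurrence matrix.

    correlation is defined as 0 when the gray-level variance is 0 (a
    single-level window); 0·ln 0 is taken as 0 in the entropy sum.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    pi = P.sum(axis=1)
    mean = float((i * pi).sum())
    var = float(((i - mean) ** 2 * pi).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    if var > 0:
        corr = float((((ii - mean) * (jj - mean) * P).sum()) / var)
    else:
        corr = 0.0
    diff = ii - jj
    contrast = float((diff**2 * P).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    dissimilarity = float((np.abs(diff) * P).sum())
    asm = float((P**2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return {
        "mean": mean,
        "variance": var,
        "correlation": corr,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "dissimilarity": dissimilarity,
        "asm": asm,
        "entropy": entropy,
    }


def _xlogx(m: np.ndarray) -> np.ndarray:
    out = np.zeros(m.shape, dtype=float)
    pos = m > 0
    out[pos] = m[pos] * np.log(m[pos])
    return out


def _integral(F: np.ndarray) -> np.ndarray:
    S = np.zeros((F.shape[0] + 1, F.shape[1] + 1), dtype=np.int64)
    np.cumsum(F, axis=0, out=S[1:, 1:], dtype=np.int64)
    np.cumsum(S[1:, 1:], axis=1, out=S[1:, 1:])
    return S


def _fast_offset_sums(q, valid, w, offset, centers):
    """Exact per-center accumulators for one displacement direction.

    Returns dict of arrays over the interior center grid: pair total n2
    (symmetric count), marginal sums Si/Sii, cross sum Sij, and the
    metric-specific sums. Built from integer integral images of level-pair
    indicator planes, so counts are exact.
    """
    H, W = q.shape
    dr, dc = offset
    h = w // 2
    r0, r1, c0, c1 = centers  # half-open center ranges

    # first-position rectangle bounds relative to the window center
    a0, a1 = -h + max(0, -dr), h - max(0, dr)
    b0, b1 = -h + max(0, -dc), h - max(0, dc)

    pr0, pr1 = max(0, -dr), H - max(0, dr)
    pc0, pc1 = max(0, -dc), W - max(0, dc)
    pair_ok = np.zeros((H, W), dtype=bool)
    pair_ok[pr0:pr1, pc0:pc1] = (
        valid[pr0:pr1, pc0:pc1]
        & valid[pr0 + dr : pr1 + dr, pc0 + dc : pc1 + dc]
    )
    qa = q
    qb = np.zeros_like(q)
    qb[pr0:pr1, pc0:pc1] = q[pr0 + dr : pr1 + dr, pc0 + dc : pc1 + dc]

    lo = np.where(qa < qb, qa, qb)
    hi = np.where(qa < qb, qb, qa)
    L = int(q.max()) + 1 if q.size else 1
    code = np.where(pair_ok, lo.astype(np.int64) * L + hi, -1)
    present = np.unique(code[code >= 0])

    def box(F):
        S = _integral(F)
        return (
            S[r0 + a1 + 1 : r1 + a1 + 1, c0 + b1 + 1 : c1 + b1 + 1]
            - S[r0 + a0 : r1 + a0, c0 + b1 + 1 : c1 + b1 + 1]
            - S[r0 + a1 + 1 : r1 + a1 + 1, c0 + b0 : c1 + b0]
            + S[r0 + a0 : r1 + a0, c0 + b0 : c1 + b0]
        )

    shape = (r1 - r0, c1 - c0)
    acc = {
        k: np.zeros(shape, dtype=float)
        for k in ("n2", "Si", "Sii", "Sij", "Scon", "Shom", "Sdis", "Sent", "Sasm")
    }
    for key in present:
        i, j = int(key) // L, int(key) % L
        m = box((code == key).astype(np.int64)).astype(float)
        if i == j:
            acc["n2"] += 2 * m
            acc["Si"] += 2 * i * m
            acc["Sii"] += 2 * i * i * m
            acc["Sij"] += 2 * i * i * m
            acc["Shom"] += 2 * m
            acc["Sent"] += _xlogx(2 * m)
            acc["Sasm"] += 4 * m * m
        else:
            d2 = (i - j) ** 2
            acc["n2"] += 2 * m
            acc["Si"] += (i + j) * m
            acc["Sii"] += (i * i + j * j) * m
            acc["Sij"] += 2 * i * j * m
            acc["Scon"] += 2 * d2 * m
            acc["Shom"] += 2 * m / (1.0 + d2)
            acc["Sdis"] += 2 * abs(i - j) * m
            acc["Sent"] += 2 * _xlogx(m)
            acc["Sasm"] += 2 * m * m
    return acc


def _metrics_from_sums(acc):
    """Per-center metric planes from one offset's accumulators (NaN where
    the window has no valid pair)."""
    n2 = acc["n2"]
    ok = n2 > 0
    out = np.full((len(METRIC_NAMES),) + n2.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = acc["Si"] / n2
        var = acc["Sii"] / n2 - mean**2
        var = np.where(ok, np.maximum(var, 0.0), np.nan)
        cov = acc["Sij"] / n2 - mean**2
        corr = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
        out[0] = np.where(ok, mean, np.nan)
        out[1] = var
        out[2] = np.where(ok, corr, np.nan)
        out[3] = np.where(ok, acc["Scon"] / n2, np.nan)
        out[4] = np.where(ok, acc["Shom"] / n2, np.nan)
        out[5] = np.where(ok, acc["Sdis"] / n2, np.nan)
        out[6] = np.where(ok, acc["Sasm"] / n2**2, np.nan)
        out[7] = np.where(ok, np.log(np.where(ok, n2, 1.0)) - acc["Sent"] / n2, np.nan)
    return out


def windowed_glcm(raster: Raster, config: GLCMConfig | None = None,
                  engine: str = "fast") -> Raster:
    """Per-pixel texture metrics, averaged across displacement directions.

    Returns an 8-band raster in METRIC_NAMES order. A border one full
    window wide is trimmed to nodata to avoid edge artifacts; interior
    windows that contain masked pixels use only their valid pairs, and a
    window with no valid pair at any direction is nodata.
    """
    if config is None:
        config = GLCMConfig()
    H, W = raster.data.shape
    w = config.window
    if w > min(H, W):
        raise ValueError(f"window {w} exceeds raster extent {raster.data.shape}")
    if H <= 2 * w or W <= 2 * w:
        raise ValueError(
            f"raster {raster.data.shape} leaves no valid pixels after trimming a "
            f"{w}-px border; enlarge the raster or shrink the window"
        )
    q = quantize(raster, config.levels)
    valid = ~q.mask

    r0, r1, c0, c1 = w, H - w, w, W - w
    if engine == "fast":
        per_offset = []
        for offset in config.offsets:
            acc = _fast_offset_sums(q.data, valid, w, offset, (r0, r1, c0, c1))
            per_offset.append(_metrics_from_sums(acc))
        stack = np.stack(per_offset)  # (offsets, 8, rows, cols)
        with np.errstate(invalid="ignore"):
            interior = np.nanmean(stack, axis=0)
    elif engine == "naive":
        interior = _naive_windowed(q.data, valid, w, config.offsets, (r0, r1, c0, c1))
    else:
        raise ValueError(f"unknown engine {engine!r}")

    out = np.full((len(METRIC_NAMES), H, W), np.nan)
    out[:, r0:r1, c0:c1] = interior
    mask = ~np.isfinite(out)
    return Raster(out, mask, raster.pixel_size, raster.origin,
                  {**raster.meta, "bands": list(METRIC_NAMES), "window": w})


def _naive_windowed(qdata, valid, w, offsets, centers):
    """Literal per-window reference: extract each window, build each
    direction's co-occurrence matrix, evaluate the metric formulas, average."""
    r0, r1, c0, c1 = centers
    h = w // 2
    out = np.full((len(METRIC_NAMES), r1 - r0, c1 - c0), np.nan)
    for r in range(r0, r1):
        for c in range(c0, c1):
            win = qdata[r - h : r + h + 1, c - h : c + h + 1]
            wmask = ~valid[r - h : r + h + 1, c - h : c + h + 1]
            vals = []
            for offset in offsets:
                try:
                    P = cooccurrence(win, offset, levels=int(qdata.max()) + 1,
                                     mask=wmask)
                except ValueError:
                    continue
                m = glcm_metrics(P)
                vals.append([m[name] for name in METRIC_NAMES])
            if vals:
                out[:, r - r0, c - c0] = np.mean(vals, axis=0)
    return out
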