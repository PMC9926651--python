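"""Monte Carlo propagation of ACD and classification uncertainty.

Two simulations estimate the distribution of the site-mean aboveground
carbon density. In the "acd_only" mode each grid cell keeps its most
probable class (uncertainty from ACD sampling alone); in "acd_plus_class"
each iteration first redraws every cell's class from its predicted
probability vector and then samples ACD, so classification uncertainty is
propagated too. ACD for a cell is drawn uniformly with replacement from
the empirical site x class distribution; draws are independent across
cells and iterations (no spatial correlation model). The per-iteration
statistic is the mean over cells; a simulation returns all iteration means
plus their mean and SD.

Reproducibility: one RNG stream per simulation. The stream is consumed in
a fixed order — for acd_plus_class, all class draws (one uniform per cell
per iteration) first, then ACD draws grouped by class in intact/logged/
burned order; for acd_only, only the ACD draws, in the same class order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import PROB_COLS, argmax_class
from .landscape import CLASS_NAMES

__all__ = ["SimulationResult", "simulate", "compare"]

MODES = ("acd_only", "acd_plus_class")


@dataclass
class SimulationResult:
    site_id: str
    mode: str
    iteration_means: np.ndarray
    n_iter: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.iteration_means.mean())

    @property
    def sd(self) -> float:
        return float(self.iteration_means.std(ddof=1))

    def summary(self) -> dict:
        return {
            "site_id": self.site_id,
            "mode": self.mode,
            "mean": self.mean,
            "sd": self.sd,
            "n_iter": self.n_iter,
        }


def _dist_lookup(dists, site_id: str) -> dict[str, np.ndarray]:
    out = {}
    for d in dists:
        if d.site_id == site_id:
            out[d.dclass] = np.asarray(d.values, dtype=float)
    return out


def simulate(
    prob_cells: pd.DataFrame,
    dists,
    mode: str,
    n_iter: int = 10_000,
    seed: int = 0,
) -> SimulationResult:
    """Simulate the site-mean ACD distribution for one site.

    ``prob_cells`` holds one row per grid cell with columns ``site_id`` and
    ``p_intact``, ``p_logged``, ``p_burned``; ``dists`` is an iterable of
    ACDDistribution covering every class the simulation can reach.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    sites = prob_cells["site_id"].unique()
    if len(sites) != 1:
        raise ValueError("simulate expects cells from exactly one site")
    site_id = str(sites[0])

    P = prob_cells[list(PROB_COLS)].to_numpy(float)
    if not np.isfinite(P).all() or (P < -1e-9).any() or (P > 1 + 1e-9).any():
        raise ValueError("class probabilities must lie in [0, 1]")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("class probabilities must sum to 1 per cell")
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    M = P.shape[0]

    lookup = _dist_lookup(dists, site_id)
    if mode == "acd_only":
        reachable = set(np.unique(argmax_class(P)))
    else:
        reachable = {c for c in range(3) if (P[:, c] > 0).any()}
    for c in sorted(reachable):
        name = CLASS_NAMES[c]
        if name not in lookup or lookup[name].size == 0:
            raise ValueError(
                f"site {site_id!r}: reachable class {name!r} has an empty "
                "ACD distribution (apply substitution first)"
            )

    rng = np.random.default_rng(seed)
    if mode == "acd_plus_class":
        u = rng.random((n_iter, M))
        c1 = P[:, 0][None, :]
        c2 = (P[:, 0] + P[:, 1])[None, :]
        classes = (u >= c1).astype(np.int8) + (u >= c2).astype(np.int8)
    else:
        classes = np.broadcast_to(
            argmax_class(P).astype(np.int8), (n_iter, M)
        )

    acd = np.empty((n_iter, M))
    for c in range(3):
        sel = classes == c
        k = int(sel.sum())
        if k == 0:
            continue
        vals = lookup[CLASS_NAMES[c]]
        acd[sel] = vals[rng.integers(0, vals.size, size=k)]

    means = acd.mean(axis=1)
    return SimulationResult(site_id, mode, means, n_iter, seed)


def _overlap(a: np.ndarray, b: np.ndarray, bins: int = 60) -> float:
    """Histogram overlap coefficient of two equal-size samples in [0, 1]."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(ha, hb).sum() / a.size)


def compare(a: SimulationResult, b: SimulationResult) -> dict:
    """Contrast two uncertainty modes on the same site.

    Returns the difference of means (b - a), the ratio of SDs (b / a) and
    the overlap fraction of the two iteration-mean distributions.
    """
    if a.site_id != b.site_id:
        raise ValueError("simulations are for different sites")
    if a.n_iter != b.n_iter:
        raise ValueError("simulations use different iteration counts")
    return {
        "site_id": a.site_id,
        "mode_a": a.mode,
        "mode_b": b.mode,
        "mean_a": a.mean,
        "mean_b": b.mean,
        "mean_diff": b.mean - a.mean,
        "sd_a": a.sd,
        "sd_b": b.sd,
        "sd_ratio": b.sd / a.sd if a.sd > 0 else float("inf"),
        "overlap": _overlap(a.iteration_means, b.iteration_means),
    }
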