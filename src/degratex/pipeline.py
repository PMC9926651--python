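"""Stage orchestration: file plumbing, manifest, and the full analysis run.

Stages (in dependency order): simulate-data -> evi -> texture -> features
-> train -> assess, and simulate-data -> acd; montecarlo needs train and
acd. ``full-run`` chains everything. Every stage records its outputs (with
SHA-256 checksums), the seed and the configuration snapshot in
``manifest.json`` inside the output directory, so a run can be reproduced
bit-identically from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geoio
from .assessment import accuracy_ci, accuracy_metrics, format_matrix
from .biomass import (apply_substitution, build_distributions, class_map_for_grid,
                      resample_acd, summarize)
from .classifier import (PROB_COLS, DegradationModel, TrainingSpec)
from .features import build_feature_table, standardize_per_site
from .indices import BandSet, bands_from_evi, compute_evi
from .landscape import SiteConfig, generate_acd_plots, generate_landscape
from .montecarlo import compare, simulate
from .raster import Raster
from .texture import GLCMConfig, windowed_glcm

__all__ = ["DEFAULT_CONFIG", "load_config", "run_stage", "full_run", "load_distributions", "STAGES"]

#: Every tunable of the analysis with its standard default. The synthetic
#: block drives the generator; the scaled-down values there keep a desk-size
#: landscape consistent with the coarser grids used for its analysis.
DEFAULT_CONFIG: dict = {
    "sites": [
        {"site_id": "mixed", "class_fraction": [0.60, 0.25, 0.15],
         "acd_regime": "low"},
        {"site_id": "burnonly", "class_fraction": [0.80, 0.0, 0.20],
         "acd_regime": "low"},
        {"site_id": "loghigh", "class_fraction": [0.75, 0.25, 0.0],
         "acd_regime": "high"},
    ],
    "extent": [480, 480],
    "pixel_size": 3.125,
    "image_year": 2018,
    "glcm": {"window": 9, "levels": 32},
    "features": {"cell_px": 30},
    "acd": {"plot_px": 16, "resample_factor": 3},
    "classifier": {
        "train_frac": 0.5,
        "purity_bin_width": 0.2,
        "row_subsample": 0.8,
        "feature_subsample": 0.7,
        "early_stop_rounds": 5,
        "learning_rate": 0.2,
        "min_node_obs": 5,
        "max_depth": 4,
        "min_split_gain": 0.2,
        "n_partitions": 20,
    },
    "montecarlo": {"n_iter": 10000},
}

ACD_REGIMES = {
    "low": {"intact": (89.2, 10.2), "logged": (93.9, 16.3), "burned": (57.9, 35.0)},
    "high": {"intact": (185.3, 31.9), "logged": (156.8, 26.0)},
}

STAGES = ("simulate-data", "evi", "texture", "features", "train", "assess",
          "acd", "montecarlo", "full-run")

_REQUIRES = {
    "evi": ("simulate-data", ["{site}/bands.tif"]),
    "texture": ("evi", ["{site}/evi.tif"]),
    "features": ("texture", ["{site}/texture.tif"]),
    "train": ("features", ["cells.csv"]),
    "assess": ("train", ["probabilities.csv"]),
    "acd": ("simulate-data", ["{site}/acd_plots.tif"]),
    "montecarlo": ("acd", ["distributions.csv", "probabilities.csv"]),
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path):
        self.path = Path(outdir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"stages": {}, "substitutions": []}

    def record(self, stage: str, seed: int, config: dict, outputs: list[Path]):
        self.data["stages"][stage] = {
            "seed": seed,
            "config": config,
            "outputs": {
                str(p.relative_to(self.path.parent)): _sha256(p) for p in outputs
            },
        }
        self.path.write_text(json.dumps(self.data, indent=2, default=str))

    def setdefault(self, key, default):
        out = self.data.setdefault(key, default)
        return out


def _site_ids(cfg) -> list[str]:
    return [s["site_id"] for s in cfg["sites"]]


def _check_upstream(stage: str, outdir: Path, cfg: dict) -> None:
    if stage not in _REQUIRES:
        return
    upstream, patterns = _REQUIRES[stage]
    for pat in patterns:
        paths = (
            [outdir / pat.format(site=s) for s in _site_ids(cfg)]
            if "{site}" in pat
            else [outdir / pat]
        )
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs {p.name} from stage {upstream!r}; "
                    f"run {upstream!r} first"
                )


def _site_config(site: dict, cfg: dict, seed: int) -> SiteConfig:
    return SiteConfig(
        site_id=site["site_id"],
        extent=tuple(cfg["extent"]),
        pixel_size=cfg["pixel_size"],
        image_year=cfg["image_year"],
        class_fraction=tuple(site["class_fraction"]),
        acd_params=dict(ACD_REGIMES[site.get("acd_regime", "low")]),
        seed=seed,
    )


# ----------------------------------------------------------------- stages

def _stage_simulate(cfg, outdir: Path, seed: int) -> list[Path]:
    out = []
    rng = np.random.default_rng(seed)
    for site in cfg["sites"]:
        sdir = outdir / site["site_id"]
        sdir.mkdir(parents=True, exist_ok=True)
        sc = _site_config(site, cfg, int(rng.integers(0, 2**31 - 1)))
        evi, class_map, year_map, polys = generate_landscape(
            sc, min_window=cfg["glcm"]["window"]
        )
        bands = bands_from_evi(evi)
        stack = Raster(
            np.stack([bands.blue.data, bands.red.data, bands.nir.data]),
            np.stack([bands.blue.mask] * 3),
            evi.pixel_size, evi.origin,
            {**evi.meta, "bands": ["blue", "red", "nir"]},
        )
        acd_plots = generate_acd_plots(sc, class_map, plot_px=cfg["acd"]["plot_px"],
                                       seed=int(rng.integers(0, 2**31 - 1)))
        out += [
            geoio.write_raster(sdir / "bands.tif", stack),
            geoio.write_raster(sdir / "class_map.tif", class_map),
            geoio.write_raster(sdir / "year_map.tif", year_map),
            geoio.write_raster(sdir / "acd_plots.tif", acd_plots),
            geoio.write_polygons(sdir / "polygons.geojson", polys),
        ]
    return out


def _stage_evi(cfg, outdir: Path, seed: int) -> list[Path]:
    out = []
    for sid in _site_ids(cfg):
        sdir = outdir / sid
        stack = geoio.read_raster(sdir / "bands.tif")
        blue, red, nir = (
            Raster(stack.data[i], stack.mask[i], stack.pixel_size, stack.origin)
            for i in range(3)
        )
        evi = compute_evi(BandSet(blue, red, nir))
        evi.meta["site_id"] = sid
        out.append(geoio.write_raster(sdir / "evi.tif", evi))
    return out


def _stage_texture(cfg, outdir: Path, seed: int) -> list[Path]:
    gcfg = GLCMConfig(window=cfg["glcm"]["window"], levels=cfg["glcm"]["levels"])
    out = []
    for sid in _site_ids(cfg):
        sdir = outdir / sid
        evi = geoio.read_raster(sdir / "evi.tif")
        tex = windowed_glcm(evi, gcfg)
        tex.meta["site_id"] = sid
        out.append(geoio.write_raster(sdir / "texture.tif", tex))
    return out


def _stage_features(cfg, outdir: Path, seed: int) -> list[Path]:
    tables = []
    for sid in _site_ids(cfg):
        sdir = outdir / sid
        tex = geoio.read_raster(sdir / "texture.tif")
        class_map = geoio.read_raster(sdir / "class_map.tif")
        year_map = geoio.read_raster(sdir / "year_map.tif")
        tables.append(
            build_feature_table(tex, class_map, year_map, sid, cfg["image_year"],
                                cell_px=cfg["features"]["cell_px"])
        )
    cells = standardize_per_site(pd.concat(tables, ignore_index=True))
    path = outdir / "cells.csv"
    cells.to_csv(path, index=False)
    return [path]


def _stage_train(cfg, outdir: Path, seed: int) -> list[Path]:
    cells = pd.read_csv(outdir / "cells.csv")
    spec = TrainingSpec(**cfg["classifier"], seed=seed)
    results = DegradationModel(cells, spec).fit(seed=seed)
    probs = results.probabilities.copy()
    probs[["cell_row", "cell_col"]] = cells[["cell_row", "cell_col"]]
    p1 = outdir / "probabilities.csv"
    probs.to_csv(p1, index=False)
    p2 = outdir / "accuracies.csv"
    pd.DataFrame({"partition": np.arange(results.accuracies.size),
                  "accuracy": results.accuracies}).to_csv(p2, index=False)
    p3 = outdir / "model_summary.txt"
    p3.write_text(results.summary() + "\n")
    return [p1, p2, p3]


def _stage_assess(cfg, outdir: Path, seed: int) -> list[Path]:
    probs = pd.read_csv(outdir / "probabilities.csv").dropna(subset=list(PROB_COLS))
    from .classifier import argmax_class
    from .assessment import confusion_matrix

    pred = argmax_class(probs[list(PROB_COLS)].to_numpy())
    cm = confusion_matrix(pred, list(probs["ref_class"]))
    overall, users, producers = accuracy_metrics(cm)
    lo, hi = accuracy_ci(cm)
    accs = pd.read_csv(outdir / "accuracies.csv")["accuracy"]
    p1 = outdir / "confusion_matrix.csv"
    pd.DataFrame(cm, index=[f"pred_{c}" for c in ("intact", "logged", "burned")],
                 columns=[f"ref_{c}" for c in ("intact", "logged", "burned")]
                 ).to_csv(p1)
    p2 = outdir / "accuracy_report.txt"
    p2.write_text(
        format_matrix(cm)
        + f"\n95% CI (binomial): ({lo:.4f}, {hi:.4f})"
        + f"\npartition accuracy: {accs.mean():.4f} +/- {accs.std(ddof=1):.4f} (SD)\n"
    )
    return [p1, p2]


def _stage_acd(cfg, outdir: Path, seed: int, manifest: Manifest | None = None) -> list[Path]:
    factor = cfg["acd"]["resample_factor"]
    dists = []
    out = []
    for sid in _site_ids(cfg):
        sdir = outdir / sid
        plots = geoio.read_raster(sdir / "acd_plots.tif")
        coarse = resample_acd(plots, factor=factor)
        class_map = geoio.read_raster(sdir / "class_map.tif")
        cell_px = cfg["acd"]["plot_px"] * factor
        cls = class_map_for_grid(class_map, cell_px)
        nr, nc = coarse.data.shape
        dists += build_distributions(coarse, cls[:nr, :nc], sid)
        out.append(geoio.write_raster(sdir / "acd_coarse.tif", coarse))
    sub_log = {} if manifest is None else manifest.data
    dists = apply_substitution(dists, manifest=sub_log)
    rows = [
        {"site_id": d.site_id, "dclass": d.dclass, "value": v,
         "substituted_from": ",".join(d.substituted_from)}
        for d in dists
        for v in d.values
    ]
    p1 = outdir / "distributions.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    p2 = outdir / "acd_summary.csv"
    summarize(dists).to_csv(p2, index=False)
    return out + [p1, p2]


def load_distributions(outdir: str | Path):
    """Read the site x class ACD distributions written by the acd stage."""
    from .biomass import ACDDistribution

    df = pd.read_csv(Path(outdir) / "distributions.csv")
    dists = []
    for (sid, cls), grp in df.groupby(["site_id", "dclass"]):
        subs = grp["substituted_from"].iloc[0]
        subs = tuple(str(subs).split(",")) if isinstance(subs, str) and subs else ()
        dists.append(ACDDistribution(sid, cls, grp["value"].to_numpy(), subs))
    return dists


def _stage_montecarlo(cfg, outdir: Path, seed: int) -> list[Path]:
    probs = pd.read_csv(outdir / "probabilities.csv").dropna(subset=list(PROB_COLS))
    dists = load_distributions(outdir)
    n_iter = cfg["montecarlo"]["n_iter"]
    rng = np.random.default_rng(seed)
    rows, out = [], []
    for sid in _site_ids(cfg):
        cells = probs[probs["site_id"] == sid]
        if len(cells) == 0:
            continue
        res = {}
        for mode in ("acd_only", "acd_plus_class"):
            res[mode] = simulate(cells, dists, mode, n_iter=n_iter,
                                 seed=int(rng.integers(0, 2**31 - 1)))
            p = outdir / f"mc_{sid}_{mode}.csv"
            pd.DataFrame({"iteration_mean": res[mode].iteration_means}).to_csv(
                p, index=False
            )
            out.append(p)
        rep = compare(res["acd_only"], res["acd_plus_class"])
        rows.append(rep)
    p = outdir / "mc_summary.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    return out + [p]


_STAGE_FUNCS = {
    "simulate-data": _stage_simulate,
    "evi": _stage_evi,
    "texture": _stage_texture,
    "features": _stage_features,
    "train": _stage_train,
    "assess": _stage_assess,
    "acd": _stage_acd,
    "montecarlo": _stage_montecarlo,
}


def run_stage(stage: str, config: dict, outdir: str | Path, seed: int = 0) -> list[Path]:
    """Run one named stage; raises if an upstream artifact is missing."""
    if stage == "full-run":
        return full_run(config, outdir, seed)
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_upstream(stage, outdir, config)
    manifest = Manifest(outdir)
    if stage == "acd":
        outputs = _stage_acd(config, outdir, seed, manifest=manifest)
    else:
        outputs = _STAGE_FUNCS[stage](config, outdir, seed)
    manifest.record(stage, seed, config, outputs)
    return outputs


def full_run(config: dict, outdir: str | Path, seed: int = 0) -> list[Path]:
    """The whole analysis: synthetic sites through Monte Carlo summaries.

    Stage seeds are derived deterministically from the run seed, so a rerun
    with the same seed and config reproduces every artifact bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in _STAGE_FUNCS}
    outputs = []
    for stage in ("simulate-data", "evi", "texture", "features", "train",
                  "assess", "acd", "montecarlo"):
        outputs += run_stage(stage, config, outdir, seed=stage_seeds[stage])
    return outputs
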