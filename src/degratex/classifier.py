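"""Probabilistic forest-degradation classification.

A purity-weighted, class-balanced multinomial gradient-boosted tree model
(xgboost backend, softprob objective) predicts per grid cell the
probability of being intact, logged or burned. Observation weights make
the summed weight of each class equal before being multiplied by cell
purity, so imbalanced and impure reference cells contribute less to the
loss. The data are split 50/50 into train/test by stratified random
sampling on class x purity bin (0.2-wide bins), and the whole procedure is
repeated over many random partitions to expose partition-to-partition
accuracy variability; per-cell probabilities are averaged over the test
folds a cell lands in.

``DegradationModel(cells).fit(seed)`` returns a :class:`DegradationResults`
with the ensemble accuracy distribution, averaged probabilities, confusion
matrix, CIs and a ``summary()`` table; Monte Carlo carbon simulation hangs
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xgboost as xgb

from .landscape import CLASS_NAMES
from .features import feature_columns

__all__ = [
    "TrainingSpec",
    "compute_weights",
    "purity_bin",
    "stratified_partition",
    "fit_model",
    "fit_ensemble",
    "DegradationModel",
    "DegradationResults",
    "argmax_class",
]

PROB_COLS = tuple(f"p_{c}" for c in CLASS_NAMES)


@dataclass
class TrainingSpec:
    """Hyperparameters of the boosted classifier and its resampling design."""

    train_frac: float = 0.5
    purity_bin_width: float = 0.2
    row_subsample: float = 0.8
    feature_subsample: float = 0.7
    early_stop_rounds: int = 5
    learning_rate: float = 0.2
    min_node_obs: int = 5
    max_depth: int = 4
    min_split_gain: float = 0.2
    n_partitions: int = 100
    max_boost_rounds: int = 200
    validation_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_frac", "row_subsample", "feature_subsample",
                     "validation_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("early_stop_rounds", "max_depth", "n_partitions",
                     "min_node_obs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def compute_weights(cells: pd.DataFrame, classes=CLASS_NAMES) -> np.ndarray:
    """Class-balancing weights multiplied by cell purity.

    The base weight of class c with n_c cells out of N is N / (k * n_c)
    (k modeled classes), so every class's base weights sum to N/k; each
    cell's final weight is its base weight times its purity.
    """
    counts = cells["ref_class"].value_counts()
    for c in classes:
        if counts.get(c, 0) == 0:
            raise ValueError(f"class {c!r} has no cells; cannot balance weights")
    N, k = len(cells), len(classes)
    base = {c: N / (k * counts[c]) for c in classes}
    return (cells["ref_class"].map(base) * cells["purity"]).to_numpy(float)


def purity_bin(purity: np.ndarray, width: float = 0.2) -> np.ndarray:
    """Bin index with right-closed top bin: [0,.2), ..., [.8, 1.0]."""
    nbins = int(round(1.0 / width))
    return np.minimum((np.asarray(purity) / width).astype(int), nbins - 1)


def stratified_partition(cells: pd.DataFrame, spec: TrainingSpec, rng=None):
    """Random 50/50 train/test split stratified on class x purity bin.

    Within each stratum the cells are shuffled and split; an odd stratum
    puts its extra cell in train, and singleton strata go entirely to
    train. Returns (train, test) DataFrames.
    """
    if len(cells) == 0:
        raise ValueError("cannot partition an empty cell table")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bins = purity_bin(cells["purity"].to_numpy(), spec.purity_bin_width)
    train_idx: list[int] = []
    test_idx: list[int] = []
    strata = pd.DataFrame({"cls": cells["ref_class"].to_numpy(), "bin": bins})
    for _, idx in strata.groupby(["cls", "bin"], sort=True).groups.items():
        idx = np.asarray(idx)
        rng.shuffle(idx)
        n_train = int(np.ceil(spec.train_frac * len(idx)))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return (
        cells.iloc[sorted(train_idx)].reset_index(drop=True),
        cells.iloc[sorted(test_idx)].reset_index(drop=True),
    )


class FittedBooster:
    """One fitted boosting round set with its feature list."""

    def __init__(self, booster: xgb.Booster, features: list[str], best_iteration: int):
        self.booster = booster
        self.features = features
        self.best_iteration = best_iteration

    def predict_probabilities(self, cells: pd.DataFrame) -> np.ndarray:
        dm = xgb.DMatrix(cells[self.features].to_numpy(float),
                         feature_names=self.features)
        p = self.booster.predict(dm, iteration_range=(0, self.best_iteration + 1))
        return np.asarray(p, dtype=float)


def fit_model(train: pd.DataFrame, spec: TrainingSpec, seed: int = 0) -> FittedBooster:
    """Fit one weighted multinomial boosted-tree model with early stopping.

    A stratified carve-out (``validation_frac`` of the training half) serves
    as the early-stopping validation set; training halts once its multiclass
    error rate fails to improve for ``early_stop_rounds`` rounds.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    present = set(train["ref_class"].unique())
    missing = [c for c in CLASS_NAMES if c not in present]
    if missing:
        raise ValueError(f"class(es) {missing} absent from training data")

    rng = np.random.default_rng(seed)
    inner_spec = TrainingSpec(**{**asdict(spec), "train_frac": 1 - spec.validation_frac})
    core, val = stratified_partition(train, inner_spec, rng)
    if len(val) == 0:
        core, val = train, train

    feats = feature_columns(train)
    y = {c: i for i, c in enumerate(CLASS_NAMES)}
    dtrain = xgb.DMatrix(
        core[feats].to_numpy(float),
        label=core["ref_class"].map(y).to_numpy(),
        weight=compute_weights(core),
        feature_names=feats,
    )
    dval = xgb.DMatrix(
        val[feats].to_numpy(float),
        label=val["ref_class"].map(y).to_numpy(),
        weight=compute_weights(val),
        feature_names=feats,
    )
    params = {
        "objective": "multi:softprob",
        "num_class": len(CLASS_NAMES),
        "eta": spec.learning_rate,
        "max_depth": spec.max_depth,
        "min_child_weight": spec.min_node_obs,
        "gamma": spec.min_split_gain,
        "subsample": spec.row_subsample,
        "colsample_bytree": spec.feature_subsample,
        "eval_metric": "merror",
        "seed": int(rng.integers(0, 2**31 - 1)),
        "nthread": 1,
        "verbosity": 0,
    }
    booster = xgb.train(
        params,
        dtrain,
        num_boost_round=spec.max_boost_rounds,
        evals=[(dval, "validation")],
        early_stopping_rounds=spec.early_stop_rounds,
        verbose_eval=False,
    )
    best = getattr(booster, "best_iteration", None)
    if best is None:
        best = spec.max_boost_rounds - 1
    return FittedBooster(booster, feats, int(best))


def argmax_class(probs: np.ndarray) -> np.ndarray:
    """Most-probable class index; ties resolve burned > logged > intact."""
    rev = probs[..., ::-1]
    return probs.shape[-1] - 1 - rev.argmax(axis=-1)


def fit_ensemble(cells: pd.DataFrame, spec: TrainingSpec | None = None,
                 seed: int | None = None) -> "DegradationResults":
    """Split/fit/evaluate over ``spec.n_partitions`` random partitions."""
    return DegradationModel(cells, spec).fit(seed=seed)


class DegradationModel:
    """Probabilistic degradation classifier over a grid-cell feature table.

    Parameters
    ----------
    cells : DataFrame
        One row per grid cell: feature columns plus ``site_id``,
        ``ref_class`` and ``purity`` (already standardized per site).
    spec : TrainingSpec, optional
    """

    def __init__(self, cells: pd.DataFrame, spec: TrainingSpec | None = None):
        required = {"site_id", "ref_class", "purity"}
        if not required <= set(cells.columns):
            raise ValueError(f"cell table must contain columns {sorted(required)}")
        self.cells = cells.reset_index(drop=True)
        self.spec = spec or TrainingSpec()
        self.feature_names = feature_columns(self.cells)

    @classmethod
    def from_dataframe(cls, cells: pd.DataFrame, spec: TrainingSpec | None = None):
        return cls(cells, spec)

    def fit(self, seed: int | None = None) -> "DegradationResults":
        spec = self.spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        n = len(self.cells)
        accuracies = np.empty(spec.n_partitions)
        prob_sum = np.zeros((n, len(CLASS_NAMES)))
        prob_n = np.zeros(n, dtype=int)
        indexed = self.cells.assign(_row=np.arange(n))
        for k in range(spec.n_partitions):
            train, test = stratified_partition(indexed, spec, rng)
            model = fit_model(train, spec, seed=int(rng.integers(0, 2**31 - 1)))
            p = model.predict_probabilities(test)
            pred = argmax_class(p)
            truth = test["ref_class"].map(
                {c: i for i, c in enumerate(CLASS_NAMES)}
            ).to_numpy()
            accuracies[k] = float((pred == truth).mean())
            rows = test["_row"].to_numpy()
            prob_sum[rows] += p
            prob_n[rows] += 1
        seen = prob_n > 0
        probs = np.full((n, len(CLASS_NAMES)), np.nan)
        probs[seen] = prob_sum[seen] / prob_n[seen, None]
        prob_df = self.cells[["site_id", "ref_class", "purity"]].copy()
        for j, col in enumerate(PROB_COLS):
            prob_df[col] = probs[:, j]
        prob_df["n_test_folds"] = prob_n
        return DegradationResults(self, accuracies, prob_df, last_model=model)


class DegradationResults:
    """Ensemble fit results: accuracy distribution, averaged probabilities,
    confusion matrix and accuracy CIs."""

    def __init__(self, model: DegradationModel, accuracies: np.ndarray,
                 probabilities: pd.DataFrame, last_model: FittedBooster):
        self.model = model
        self.accuracies = np.asarray(accuracies)
        self.probabilities = probabilities
        self.last_model = last_model

    # -- accuracy ---------------------------------------------------------
    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.accuracies.size > 1 else 0.0

    def confusion_matrix(self):
        """Confusion matrix of the averaged-probability hard classification
        over cells seen in at least one test fold (rows predicted,
        columns reference)."""
        from .assessment import confusion_matrix

        df = self.probabilities.dropna(subset=list(PROB_COLS))
        pred = argmax_class(df[list(PROB_COLS)].to_numpy())
        truth = df["ref_class"].map({c: i for i, c in enumerate(CLASS_NAMES)}).to_numpy()
        return confusion_matrix(pred, truth)

    def overall_accuracy_ci(self, level: float = 0.95):
        from .assessment import accuracy_ci

        return accuracy_ci(self.confusion_matrix(), level=level)

    # -- simulation -------------------------------------------------------
    def simulate_carbon(self, dists, mode: str, n_iter: int = 10_000,
                        seed: int = 0, site_id: str | None = None):
        """Monte Carlo site-mean ACD under this fit's class probabilities.

        Delegates to :func:`degratex.montecarlo.simulate` using the averaged
        per-cell probabilities (optionally restricted to one site).
        """
        from .montecarlo import simulate

        df = self.probabilities.dropna(subset=list(PROB_COLS))
        if site_id is not None:
            df = df[df["site_id"] == site_id]
        return simulate(df, dists, mode=mode, n_iter=n_iter, seed=seed)

    def summary(self) -> str:
        from .assessment import accuracy_metrics

        cm = self.confusion_matrix()
        overall, users, producers = accuracy_metrics(cm)
        lo, hi = self.overall_accuracy_ci()
        lines = [
            "Probabilistic forest-degradation classification",
            "=" * 55,
            f"partitions: {self.accuracies.size}   cells: {len(self.model.cells)}",
            f"partition accuracy: {self.accuracy_mean:.4f} +/- {self.accuracy_sd:.4f} (SD)",
            f"overall accuracy (avg-prob hard map): {overall:.4f}  "
            f"95% CI ({lo:.4f}, {hi:.4f})",
            "",
            "class      user's   producer's",
        ]
        for i, c in enumerate(CLASS_NAMES):
            u = "   -  " if users[i] is None else f"{users[i]:.4f}"
            p = "   -  " if producers[i] is None else f"{producers[i]:.4f}"
            lines.append(f"{c:<10} {u}   {p}")
        return "\n".join(lines)
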