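"""Map-accuracy assessment of the hard (most-probable) classification.

Standard error-matrix measures: overall accuracy (proportion of area
mapped correctly), user's accuracy per class (complement of commission
error) and producer's accuracy per class (complement of omission error),
plus a normal-approximation binomial confidence interval on the overall
accuracy. Matrix convention: rows are predicted classes, columns reference
classes, in intact/logged/burned order.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .landscape import CLASS_NAMES

__all__ = ["confusion_matrix", "accuracy_metrics", "accuracy_ci", "format_matrix"]


def confusion_matrix(predicted, reference) -> np.ndarray:
    """3x3 count matrix, rows = predicted, columns = reference.

    Labels may be class indices (0/1/2) or class names.
    """
    name_to_code = {c: i for i, c in enumerate(CLASS_NAMES)}

    def encode(labels):
        out = np.asarray(
            [name_to_code.get(v, v) if isinstance(v, str) else v for v in labels]
        )
        if out.size and (out.min() < 0 or out.max() > 2):
            bad = sorted(set(out[(out < 0) | (out > 2)]))
            raise ValueError(f"labels outside the three classes: {bad}")
        return out.astype(int)

    pred = encode(predicted)
    ref = encode(reference)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference label arrays differ in length")
    cm = np.zeros((3, 3), dtype=np.int64)
    np.add.at(cm, (pred, ref), 1)
    return cm


def accuracy_metrics(cm: np.ndarray):
    """(overall, user's per class, producer's per class).

    overall = trace/total; user's(c) = cm[c,c]/row_total(c);
    producer's(c) = cm[c,c]/col_total(c). A class with an empty row or
    column gets None (undefined) for the corresponding measure.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    overall = float(np.trace(cm) / total)
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    users = [float(cm[i, i] / rows[i]) if rows[i] > 0 else None for i in range(3)]
    producers = [float(cm[i, i] / cols[i]) if cols[i] > 0 else None for i in range(3)]
    return overall, users, producers


def accuracy_ci(cm: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial CI on the overall accuracy,
    clipped to [0, 1]."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    if n <= 1:
        raise ValueError("need more than one observation for a CI")
    p = float(np.trace(cm) / n)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def format_matrix(cm: np.ndarray) -> str:
    """Plain-text error-matrix report with per-class accuracies."""
    overall, users, producers = accuracy_metrics(cm)
    head = "predicted\\reference" + "".join(f"{c:>9}" for c in CLASS_NAMES)
    lines = [head + "    user's"]
    for i, c in enumerate(CLASS_NAMES):
        row = "".join(f"{int(v):>9}" for v in cm[i])
        u = "     -" if users[i] is None else f"{users[i]:6.2f}"
        lines.append(f"{c:<19}{row}    {u}")
    prods = "".join(
        "        -" if p is None else f"{p:>9.2f}" for p in producers
    )
    label = "producer's"
    lines.append(f"{label:<19}{prods}")
    lines.append(f"overall accuracy: {overall:.4f}")
    return "\n".join(lines)
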