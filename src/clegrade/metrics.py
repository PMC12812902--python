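"""Per-examination classification metrics and cross-split aggregation.

All metrics derive from a 2x2 confusion matrix with high grade as the
positive class: accuracy, sensitivity (recall on high grade), specificity,
positive and negative predictive value. Values are kept at full precision
internally and displayed rounded to the nearest whole percent, the
convention used in clinical reporting. A metric whose denominator is zero
(e.g. sensitivity with no true high-grade examinations) is reported as
``None``, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

POSITIVE_LABEL = "high"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies; positive = high grade."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_matrix(self) -> np.ndarray:
        """2x2 matrix, rows = prediction (high, low), cols = truth (high, low)."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale metrics; None marks an undefined (0/0) metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def displayed(self) -> dict[str, int | None]:
        """Nearest-integer display values, the printed-table convention."""
        return {k: (None if v is None else round(v))
                for k, v in self.__dict__.items()}


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "UO":
        bad = set(arr) - {"high", "low"}
        if bad:
            raise ValueError(f"{name} contains non-binary values: {sorted(bad)}")
        return arr == POSITIVE_LABEL
    uniq = set(np.unique(arr))
    if not uniq <= {0, 1, True, False}:
        raise ValueError(f"{name} contains non-binary values: {sorted(uniq)}")
    return arr.astype(bool)


def confusion_from_predictions(predictions, labels) -> ConfusionCounts:
    """Tally a confusion matrix from per-examination predictions.

    Accepts "high"/"low" strings or 0/1 indicators (1 = high grade).
    """
    pred = _as_binary(predictions, "predictions")
    truth = _as_binary(labels, "labels")
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV as percentages."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero examinations")
    return MetricsReport(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


def aggregate_splits(split_accuracies) -> float:
    """Arithmetic mean of per-split accuracies (percent scale).

    The overall figure reported for a repeated-splits experiment; display
    rounding (nearest integer) is left to the caller via ``round``.
    """
    vals = np.asarray(list(split_accuracies), dtype=float)
    if vals.size == 0:
        raise ValueError("no split accuracies to aggregate")
    return float(vals.mean())


def export_confusion_matrix(counts: ConfusionCounts, out_path: str | Path) -> Path:
    """Write a 2x2 heatmap (PNG) and a CSV twin of the confusion counts.

    Orientation: ground truth on the x-axis, prediction on the y-axis, with
    cell shading proportional to count.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    mat = counts.as_matrix()

    df = pd.DataFrame(mat, index=["pred_high", "pred_low"],
                      columns=["true_high", "true_low"])
    df.to_csv(out_path.with_suffix(".csv"))

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(mat, cmap="Blues")
    ax.set_xticks([0, 1], ["High", "Low"])
    ax.set_yticks([0, 1], ["High", "Low"])
    ax.set_xlabel("Ground truth")
    ax.set_ylabel("Prediction")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(mat[i, j]), ha="center", va="center",
                    color="white" if mat[i, j] > mat.max() / 2 else "black")
    fig.colorbar(im, ax=ax, label="Count")
    fig.tight_layout()
    fig.savefig(out_path.with_suffix(".png"), dpi=150)
    plt.close(fig)
    return out_path.with_suffix(".csv")


def read_confusion_matrix(csv_path: str | Path) -> ConfusionCounts:
    df = pd.read_csv(csv_path, index_col=0)
    return ConfusionCounts(tp=int(df.loc["pred_high", "true_high"]),
                           fp=int(df.loc["pred_high", "true_low"]),
                           fn=int(df.loc["pred_low", "true_high"]),
                           tn=int(df.loc["pred_low", "true_low"]))
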