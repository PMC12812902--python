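"""Dataset splitting, loss, and optimization for the grading models.

Splitting follows the study protocol — a random train/test partition of the
sequence corpus, repeated over several seeds — with two refinements exposed
as options: splits are stratified by grade label by default (both classes
must appear on both sides, which a small unstratified split can violate),
and grouping by case is available so that all sequences of one patient land
on one side, avoiding case-level leakage. Sequence-level splitting, the
study's own protocol, remains the default grouping.

Training minimizes cross-entropy with the Adam optimizer; everything is
seeded so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam, Tensor
from .backbone import FeatureSequence
from .temporal import (
    LABEL_TO_INDEX,
    FrameHead,
    GradePrediction,
    SequenceGradeModel,
    TemporalModelConfig,
)

_PROB_FLOOR = 1e-12    # clamp for -log p so a confident wrong call stays finite


@dataclass(frozen=True)
class SplitSpec:
    split_id: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 100
    seed: int = 0
    patience: int | None = None     # early stop on train loss plateau; None = off

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _largest_remainder_allocation(counts: np.ndarray, total: int) -> np.ndarray:
    """Integer per-class train counts whose sum is exactly ``total``."""
    frac = counts * total / counts.sum()
    base = np.floor(frac).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(frac - base))
    base[order[:rem]] += 1
    return base


def make_splits(manifest: pd.DataFrame, train_fraction: float, n_splits: int,
                seed: int, grouping: str = "sequence",
                stratify: bool = True) -> list[SplitSpec]:
    """Random train/test partitions of the manifest.

    ``grouping='sequence'`` partitions sequence ids directly, with train
    size round(train_fraction * N). ``grouping='case'`` keeps every
    sequence of one case on the same side (sizes then only approximate the
    fraction). Stratification keeps the grade ratio on both sides. Each
    split must contain both classes on both sides.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if grouping not in ("sequence", "case"):
        raise ValueError(f"grouping must be 'sequence' or 'case', got {grouping!r}")

    root = np.random.SeedSequence(seed)
    splits = []
    for k in range(n_splits):
        rng = np.random.default_rng(root.spawn(1)[0])
        if grouping == "sequence":
            n_train = round(train_fraction * len(manifest))
            if stratify:
                labels = manifest["label"].to_numpy()
                classes, counts = np.unique(labels, return_counts=True)
                alloc = _largest_remainder_allocation(counts, n_train)
                train_ids: list[str] = []
                for cls, n_c in zip(classes, alloc):
                    ids = manifest.loc[labels == cls, "sequence_id"].to_numpy()
                    perm = rng.permutation(len(ids))
                    train_ids.extend(ids[perm[:n_c]])
            else:
                ids = manifest["sequence_id"].to_numpy()
                perm = rng.permutation(len(ids))
                train_ids = list(ids[perm[:n_train]])
            train_set = set(train_ids)
            test_ids = [s for s in manifest["sequence_id"] if s not in train_set]
        else:
            cases = manifest[["case_id", "label"]].drop_duplicates()
            case_ids = cases["case_id"].to_numpy()
            if stratify:
                chosen: list[str] = []
                labels = cases["label"].to_numpy()
                classes, counts = np.unique(labels, return_counts=True)
                alloc = _largest_remainder_allocation(
                    counts, round(train_fraction * len(case_ids)))
                for cls, n_c in zip(classes, alloc):
                    ids = case_ids[labels == cls]
                    perm = rng.permutation(len(ids))
                    chosen.extend(ids[perm[:n_c]])
                train_cases = set(chosen)
            else:
                perm = rng.permutation(len(case_ids))
                train_cases = set(case_ids[perm[:round(train_fraction * len(case_ids))]])
            in_train = manifest["case_id"].isin(train_cases)
            train_ids = list(manifest.loc[in_train, "sequence_id"])
            test_ids = list(manifest.loc[~in_train, "sequence_id"])

        for side, ids in (("train", train_ids), ("test", test_ids)):
            side_labels = set(manifest.set_index("sequence_id").loc[ids, "label"])
            if len(side_labels) < 2:
                raise ValueError(f"split {k}: {side} side is missing a class")
        splits.append(SplitSpec(split_id=k, train_ids=tuple(train_ids),
                                test_ids=tuple(test_ids), seed=seed))
    return splits


def cross_entropy_loss(prediction: GradePrediction, label: str) -> float:
    """-log p(true class), clamped at 1e-12 to stay finite."""
    if label not in LABEL_TO_INDEX:
        raise ValueError(f"unknown label {label!r}")
    p = prediction.prob_high if label == "high" else prediction.prob_low
    return float(-np.log(max(p, _PROB_FLOOR)))


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(len(self.epoch_loss)),
                             "loss": self.epoch_loss,
                             "accuracy": self.epoch_accuracy})


def _batch_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from (B, 2) logits and integer class labels."""
    logp = logits.log_softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / len(labels))


def train_model(features: list[FeatureSequence], split: SplitSpec | None,
                model_config: TemporalModelConfig = TemporalModelConfig(),
                train_config: TrainConfig = TrainConfig(),
                ) -> tuple[SequenceGradeModel, TrainHistory]:
    """Fit the sequence grading model on the training side of a split.

    ``split=None`` trains on all provided sequences. Per-epoch mean loss and
    training accuracy are recorded; a non-finite loss aborts with a
    diagnostic rather than silently diverging.
    """
    train_feats = _select_training_side(features, split)
    labels = np.array([LABEL_TO_INDEX[f.label] for f in train_feats])
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")

    model = SequenceGradeModel(train_feats[0].dim, model_config,
                               seed=train_config.seed)
    stacked = np.concatenate([f.features for f in train_feats], axis=0)
    model.set_normalizer(stacked.mean(axis=0), stacked.std(axis=0))
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    history = TrainHistory()
    best_loss, since_best = np.inf, 0

    for _epoch in range(train_config.max_epochs):
        model.train()
        order = rng.permutation(len(train_feats))
        total_loss, n_correct = 0.0, 0
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            feats = [train_feats[i].features for i in idx]
            logits = model.forward_batch(feats)
            loss = _batch_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {_epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data) * len(idx)
            n_correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        history.epoch_loss.append(total_loss / len(order))
        history.epoch_accuracy.append(n_correct / len(order))
        if train_config.patience is not None:
            if history.epoch_loss[-1] < best_loss - 1e-6:
                best_loss, since_best = history.epoch_loss[-1], 0
            else:
                since_best += 1
                if since_best > train_config.patience:
                    break
    model.eval()
    return model, history


def train_frame_baseline(features: list[FeatureSequence], split: SplitSpec | None,
                         train_config: TrainConfig = TrainConfig(),
                         hidden_dim: int = 32) -> tuple[FrameHead, TrainHistory]:
    """Fit the frame-based baseline head on individual frames.

    Every frame inherits its sequence's grade label; frames are shuffled and
    batched independently of their sequence of origin.
    """
    train_feats = _select_training_side(features, split)
    X = np.concatenate([f.features for f in train_feats], axis=0)
    y = np.concatenate([np.full(f.n_frames, LABEL_TO_INDEX[f.label], dtype=int)
                        for f in train_feats])
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")

    head = FrameHead(X.shape[1], hidden_dim=hidden_dim, seed=train_config.seed)
    head.set_normalizer(X.mean(axis=0), X.std(axis=0))
    X = (X - head.feature_mean) / head.feature_std
    opt = Adam(head.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    history = TrainHistory()
    batch = max(train_config.batch_size, 32)

    for _epoch in range(train_config.max_epochs):
        head.train()
        order = rng.permutation(len(y))
        total_loss, n_correct = 0.0, 0
        for start in range(0, len(order), batch):
            idx = order[start:start + batch]
            logits = head(Tensor(X[idx]))
            loss = _batch_cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"baseline diverged at epoch {_epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data) * len(idx)
            n_correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history.epoch_loss.append(total_loss / len(order))
        history.epoch_accuracy.append(n_correct / len(order))
    head.eval()
    return head, history


def _select_training_side(features: list[FeatureSequence],
                          split: SplitSpec | None) -> list[FeatureSequence]:
    if split is None:
        chosen = list(features)
    else:
        train_set = set(split.train_ids)
        test_set = set(split.test_ids)
        if train_set & test_set:
            raise ValueError("train and test sets overlap")
        chosen = [f for f in features if f.sequence_id in train_set]
    if not chosen:
        raise ValueError("empty training set")
    if any(f.label is None for f in chosen):
        raise ValueError("training sequences must carry labels")
    return chosen
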