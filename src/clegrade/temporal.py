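"""Sequence-level tumor grading: the temporal model and the frame baseline.

The sequence model mirrors how a neuropathologist reads a CLE stream — as an
ordered progression, not a bag of stills:

    per-frame embeddings
      -> linear projection to the model width
      -> + positional encoding (sinusoidal by default)
      -> transformer encoder (2 blocks of multi-head self-attention + FFN)
      -> 1-D convolution along the temporal axis
      -> masked global average pooling to one global temporal embedding
      -> fully connected layer -> softmax over {high, low}

Variable-length sequences are padded to the batch maximum with a boolean
mask; padded positions are excluded from attention keys, zeroed before the
temporal convolution and excluded from pooling, so they can never change
the prediction for the real frames.

The frame-based baseline applies a small classification head to each frame
embedding independently and aggregates per-frame votes into one
per-examination label (majority vote by default, ties broken toward
high grade); it is frame-permutation invariant — the property the sequence
model deliberately gives up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import FeatureSequence
from .preprocessing import CLESequence

CLASSES = ("low", "high")            # class index 0 = low, 1 = high
LABEL_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class TemporalModelConfig:
    n_encoder_layers: int = 2
    n_heads: int = 4
    model_dim: int = 128
    feedforward_dim: int = 256
    conv_kernel: int = 3
    conv_channels: int = 64
    dropout: float = 0.1
    positional_encoding: str = "sinusoidal"      # "sinusoidal" | "learned"
    max_len: int = 512
    n_classes: int = 2

    def __post_init__(self):
        if self.model_dim % self.n_heads != 0:
            raise ValueError("model_dim must be divisible by n_heads")
        if self.conv_kernel % 2 == 0 or self.conv_kernel < 1:
            raise ValueError("conv_kernel must be odd and positive")
        if self.n_classes != 2:
            raise ValueError("the grading task is binary: n_classes must be 2")
        if self.positional_encoding not in ("sinusoidal", "learned"):
            raise ValueError("positional_encoding must be 'sinusoidal' or 'learned'")


@dataclass
class GradePrediction:
    """Softmax output for one examination sequence."""

    prob_high: float
    prob_low: float
    logits: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.logits).all():
            raise ValueError("non-finite logits")
        if abs(self.prob_high + self.prob_low - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")

    @property
    def label(self) -> str:
        return "high" if self.prob_high >= self.prob_low else "low"


def add_positional_encoding(features, mode: str = "sinusoidal",
                            max_len: int = 512,
                            learned_table: np.ndarray | None = None):
    """Add position-dependent offsets to a (T, D) feature matrix.

    Sinusoidal mode uses pe[p, 2i] = sin(p / 10000^(2i/D)) and
    pe[p, 2i+1] = cos(p / 10000^(2i/D)); distinct positions always receive
    distinct offsets. Accepts a raw (T, D) array or a
    :class:`~clegrade.backbone.FeatureSequence` (returned in kind).
    """
    if isinstance(features, FeatureSequence):
        out = add_positional_encoding(features.features, mode=mode,
                                      max_len=max_len, learned_table=learned_table)
        return FeatureSequence(out, sequence_id=features.sequence_id,
                               case_id=features.case_id, roi_id=features.roi_id,
                               label=features.label)
    features = np.asarray(features, dtype=np.float64)
    T, D = features.shape
    if T > max_len:
        raise ValueError(f"sequence length {T} exceeds max_len {max_len}")
    if mode == "sinusoidal":
        pe = nn.sinusoidal_positional_encoding(T, D)
    elif mode == "learned":
        if learned_table is None:
            raise ValueError("learned mode requires a position table")
        pe = learned_table[:T]
    else:
        raise ValueError(f"unknown positional encoding mode {mode!r}")
    return features + pe


class SequenceGradeModel(nn.Module):
    """Transformer-encoder + temporal-convolution grading model."""

    def __init__(self, input_dim: int, config: TemporalModelConfig = TemporalModelConfig(),
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.input_dim = input_dim
        self.proj = nn.Linear(input_dim, config.model_dim, rng)
        self.encoder_layers = [
            nn.TransformerEncoderLayer(config.model_dim, config.n_heads,
                                       config.feedforward_dim, config.dropout, rng)
            for _ in range(config.n_encoder_layers)
        ]
        self.temporal_conv = nn.TemporalConv1d(config.model_dim, config.conv_channels,
                                               config.conv_kernel, rng)
        self.head = nn.Linear(config.conv_channels, config.n_classes, rng)
        if config.positional_encoding == "learned":
            self.pos_table = Tensor(rng.normal(0, 0.02,
                                               size=(config.max_len, config.model_dim)),
                                    requires_grad=True)
        else:
            self.pos_table = None
        # optional input standardization (fit on the training set)
        self.feature_mean: np.ndarray | None = None
        self.feature_std: np.ndarray | None = None

    def set_normalizer(self, mean: np.ndarray, std: np.ndarray) -> None:
        """Per-dimension z-scoring applied to incoming frame features."""
        self.feature_mean = np.asarray(mean, dtype=np.float64)
        self.feature_std = np.maximum(np.asarray(std, dtype=np.float64), 1e-8)

    def _normalize(self, f: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return f
        return (f - self.feature_mean) / self.feature_std

    # ---- stages ---------------------------------------------------------

    def embed_positions(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        """Project and add positional encoding to the true (unpadded) positions."""
        B, T, _ = x.shape
        h = self.proj(x)
        if self.config.positional_encoding == "sinusoidal":
            pe = nn.sinusoidal_positional_encoding(T, self.config.model_dim)
            valid = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
            h = h + Tensor(pe[None] * valid[:, :, None])
        else:
            valid = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
            h = h + self.pos_table[:T].reshape(1, T, self.config.model_dim) \
                * Tensor(valid[:, :, None])
        return h

    def encode_temporal(self, h: Tensor, lengths: np.ndarray) -> Tensor:
        """Contextualize frame embeddings; padded positions are masked out of
        attention keys and cannot influence valid positions."""
        T = h.shape[1]
        pad_mask = np.arange(T)[None, :] >= lengths[:, None]
        for layer in self.encoder_layers:
            h = layer(h, key_padding_mask=pad_mask)
        return h

    def aggregate_temporal(self, h: Tensor, lengths: np.ndarray) -> Tensor:
        """Temporal convolution then masked global average pooling."""
        T = h.shape[1]
        valid = (np.arange(T)[None, :] < lengths[:, None]).astype(float)[:, :, None]
        h = h * Tensor(valid)                         # zero padded frames
        c = self.temporal_conv(h)
        c = c * Tensor(valid)
        return c.sum(axis=1) * Tensor(1.0 / lengths[:, None])

    def logits(self, features: Tensor, lengths: np.ndarray) -> Tensor:
        h = self.embed_positions(features, lengths)
        h = self.encode_temporal(h, lengths)
        g = self.aggregate_temporal(h, lengths)
        return self.head(g)

    def forward_batch(self, feature_list: list[np.ndarray]) -> Tensor:
        """Pad a list of (T_i, D) matrices to a batch and return (B, 2) logits."""
        if not feature_list:
            raise ValueError("empty batch")
        lengths = np.array([f.shape[0] for f in feature_list])
        if lengths.min() < 1:
            raise ValueError("sequences must contain at least one frame")
        Tmax = int(lengths.max())
        D = feature_list[0].shape[1]
        batch = np.zeros((len(feature_list), Tmax, D))
        for i, f in enumerate(feature_list):
            batch[i, :f.shape[0]] = self._normalize(f)
        return self.logits(Tensor(batch), lengths)

    def predict(self, features: FeatureSequence) -> GradePrediction:
        self.eval()
        logits = self.forward_batch([features.features]).data[0]
        return prediction_from_logits(logits)


class FrameHead(nn.Module):
    """Per-frame classification head for the frame-based baseline."""

    def __init__(self, input_dim: int, hidden_dim: int = 32, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(input_dim, hidden_dim, rng)
        self.fc2 = nn.Linear(hidden_dim, 2, rng)
        self.feature_mean: np.ndarray | None = None
        self.feature_std: np.ndarray | None = None

    def set_normalizer(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.feature_mean = np.asarray(mean, dtype=np.float64)
        self.feature_std = np.maximum(np.asarray(std, dtype=np.float64), 1e-8)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def logits_np(self, features: np.ndarray) -> np.ndarray:
        """Per-frame logits with the fitted input standardization applied."""
        f = np.asarray(features, dtype=np.float64)
        if self.feature_mean is not None:
            f = (f - self.feature_mean) / self.feature_std
        return self(Tensor(f)).data


def prediction_from_logits(logits: np.ndarray) -> GradePrediction:
    logits = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(logits).all():
        raise ValueError("non-finite logits")
    shifted = logits - logits.max()
    p = np.exp(shifted)
    p /= p.sum()
    return GradePrediction(prob_high=float(p[LABEL_TO_INDEX["high"]]),
                           prob_low=float(p[LABEL_TO_INDEX["low"]]),
                           logits=logits)


def classify(embedding: np.ndarray, head: nn.Linear) -> GradePrediction:
    """Fully connected layer + softmax on a global temporal embedding."""
    logits = head(Tensor(np.asarray(embedding)[None, :])).data[0]
    return prediction_from_logits(logits)


def predict_sequence(features: FeatureSequence, model: SequenceGradeModel) -> GradePrediction:
    """One per-examination prediction from a frame-feature sequence."""
    return model.predict(features)


def predict_frame_baseline(features: FeatureSequence, frame_model: FrameHead,
                           aggregation: str = "majority") -> GradePrediction:
    """Frame-independent predictions combined into one examination label.

    ``majority``: argmax per frame, majority vote, tie -> high grade (the
    screening-oriented tie-break). ``mean_prob``: average the per-frame
    softmax distributions. Both rules are frame-permutation invariant.
    """
    if features.n_frames == 0:
        raise ValueError("empty sequence")
    frame_model.eval()
    logits = frame_model.logits_np(features.features)             # (T, 2)
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    if aggregation == "majority":
        votes_high = int((probs[:, LABEL_TO_INDEX["high"]] >= 0.5).sum())
        votes_low = features.n_frames - votes_high
        p_high = votes_high / features.n_frames
        # tie -> high grade; encode the decision in the returned probabilities
        if votes_high == votes_low:
            p_high = 0.5 + 1e-9
        mean_logits = logits.mean(axis=0)
        return GradePrediction(prob_high=min(1.0, p_high),
                               prob_low=max(0.0, 1.0 - min(1.0, p_high)),
                               logits=mean_logits)
    if aggregation == "mean_prob":
        mean_p = probs.mean(axis=0)
        return GradePrediction(prob_high=float(mean_p[LABEL_TO_INDEX["high"]]),
                               prob_low=float(mean_p[LABEL_TO_INDEX["low"]]),
                               logits=logits.mean(axis=0))
    raise ValueError(f"unknown aggregation {aggregation!r}")
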