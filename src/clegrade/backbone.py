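"""Per-frame visual feature extraction.

Each frame of a sequence is encoded independently into a fixed-length
embedding; temporal information enters only in the downstream temporal
model, so feature extraction is frame-permutation equivariant by
construction.

The four ImageNet-pretrained families used in the field (Inception-ResNet-V2,
ResNet50, VGG16, vision transformer) require downloaded weights; requesting
one without a local weight source raises :class:`BackboneUnavailableError`.
The ``tiny_test_cnn`` family — three strided conv blocks, global average
pooling, a 32-dimensional embedding — is self-contained, seeded, and carries
the whole test and experiment pipeline without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

PRETRAINED_FAMILIES = ("inception_resnet_v2", "resnet50", "vgg16", "vision_transformer")
FAMILIES = PRETRAINED_FAMILIES + ("tiny_test_cnn",)

TINY_CNN_DIM = 32


class BackboneUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneSpec:
    family: str = "tiny_test_cnn"
    weights: str = "random"            # "pretrained" | "random"
    frozen: bool = True
    input_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown backbone family {self.family!r}; "
                             f"choose one of {FAMILIES}")
        if self.weights not in ("pretrained", "random"):
            raise ValueError(f"weights must be 'pretrained' or 'random', got {self.weights!r}")

    @property
    def embedding_dim(self) -> int:
        if self.family == "tiny_test_cnn":
            return TINY_CNN_DIM
        return {"inception_resnet_v2": 1536, "resnet50": 2048,
                "vgg16": 4096, "vision_transformer": 768}[self.family]


@dataclass
class FeatureSequence:
    """T per-frame embeddings of dimension D, with sequence metadata."""

    features: np.ndarray               # (T, D)
    sequence_id: str = ""
    case_id: str = ""
    roi_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError(f"features must be (T, D), got shape {self.features.shape}")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


class TinyTestCNN(nn.Module):
    """3 strided conv blocks -> global average pool -> 32-d embedding.

    Random (seeded) weights; intended as a frozen feature extractor whose
    activations still respond to local image structure.
    """

    def __init__(self, seed: int = 0, in_channels: int = 3):
        super().__init__()
        rng = np.random.default_rng(seed)
        # valid (unpadded) convs: zero padding would fabricate strong border
        # edges on bright-background CLE frames and contaminate CAMs
        self.conv1 = nn.Conv2d(in_channels, 8, 3, rng, stride=2, padding=0)
        self.conv2 = nn.Conv2d(8, 16, 3, rng, stride=2, padding=0)
        self.conv3 = nn.Conv2d(16, TINY_CNN_DIM, 3, rng, stride=2, padding=0)

    def features_map(self, x: Tensor) -> Tensor:
        """Last conv block activation, pre-pooling (the CAM target layer).

        Frames are centred at their mean intensity first: CLE content is a
        deviation from the bright fluorescein background (dark silhouettes),
        and centring lets rectified channels of either weight sign fire on
        it rather than on the background itself.
        """
        x = x - Tensor(x.data.mean(axis=(2, 3), keepdims=True))
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        return self.conv3(h).relu()

    def __call__(self, x: Tensor) -> Tensor:
        return self.features_map(x).mean(axis=(2, 3))


def build_backbone(spec: BackboneSpec) -> TinyTestCNN:
    if spec.family != "tiny_test_cnn":
        raise BackboneUnavailableError(
            f"backbone family {spec.family!r} needs pretrained weights that are "
            "not bundled with this package; use 'tiny_test_cnn' or provide a "
            "local weight source")
    return TinyTestCNN(seed=spec.seed)


def extract_features(batch: np.ndarray, spec: BackboneSpec,
                     model: TinyTestCNN | None = None,
                     sequence_id: str = "", case_id: str = "", roi_id: str = "",
                     label: str | None = None) -> FeatureSequence:
    """Encode a (T, C, H, W) model-input batch into a T x D feature matrix.

    Frames are processed independently; identical frames yield identical
    embedding rows and permuting frames permutes rows identically.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 4:
        raise ValueError(f"expected (T, C, H, W) batch, got shape {batch.shape}")
    if batch.shape[-1] != spec.input_size or batch.shape[-2] != spec.input_size:
        raise ValueError(f"batch spatial size {batch.shape[-2:]} does not match "
                         f"spec.input_size={spec.input_size}")
    if model is None:
        model = build_backbone(spec)
    model.eval()
    out = model(Tensor(batch)).data
    if not np.isfinite(out).all():
        raise FloatingPointError("backbone produced non-finite activations")
    return FeatureSequence(out, sequence_id=sequence_id, case_id=case_id,
                           roi_id=roi_id, label=label)
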