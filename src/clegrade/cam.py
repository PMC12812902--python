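"""Gradient-weighted class activation maps (Grad-CAM).

For a CNN backbone the relevance of each spatial location to a class
prediction is computed from the last convolutional block: channel weights
are the spatial means of the class-score gradient on that activation, the
map is their weighted channel sum, rectified, min-max normalized to [0, 1]
and bilinearly upsampled to the input frame. A constant (information-free)
relevance map normalizes to all-zeros rather than dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .nn import Tensor
from .backbone import TinyTestCNN
from .temporal import LABEL_TO_INDEX, FrameHead
from .preprocessing import CLEFrame


@dataclass
class CAMMap:
    """Per-frame relevance heatmap in [0, 1] at input-frame resolution."""

    relevance: np.ndarray
    frame_index: int
    predicted_class: str

    def __post_init__(self):
        r = np.asarray(self.relevance, dtype=np.float64)
        if r.min() < 0 or r.max() > 1 + 1e-12:
            raise ValueError("relevance must lie in [0, 1]")
        if r.max() > 0 and abs(r.max() - 1.0) > 1e-9:
            raise ValueError("a nonzero relevance map must attain max 1")
        self.relevance = r


def _normalize_map(cam: np.ndarray) -> np.ndarray:
    cam = np.maximum(cam, 0.0)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


def compute_cam(backbone: TinyTestCNN, head: FrameHead, frame: CLEFrame,
                target_class: str = "high", channels: int = 3) -> CAMMap:
    """Grad-CAM for one frame under a backbone + frame-head classifier.

    The gradient of the target-class logit is taken with respect to the
    backbone's last conv activation; its spatial mean per channel weights
    the activation channels.
    """
    if target_class not in LABEL_TO_INDEX:
        raise ValueError(f"unknown class {target_class!r}")
    backbone.eval()
    head.eval()

    x = Tensor(np.repeat(frame.data[None, None], channels, axis=1))
    amap = backbone.features_map(x)              # 1, C, h, w — CAM target layer
    pooled = amap.mean(axis=(2, 3))
    if head.feature_mean is not None:            # head was fit on z-scored features
        pooled = (pooled - Tensor(head.feature_mean)) * Tensor(1.0 / head.feature_std)
    logits = head(pooled)
    cls = LABEL_TO_INDEX[target_class]
    seed = np.zeros(logits.shape)
    seed[0, cls] = 1.0
    logits.backward(seed)
    grad = amap.grad[0]                          # C, h, w
    acts = amap.data[0]

    weights = grad.mean(axis=(1, 2))             # C
    cam = np.tensordot(weights, acts, axes=(0, 0))
    cam = _normalize_map(cam)
    H, W = frame.data.shape
    cam = _sk_resize(cam, (H, W), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    cam = np.clip(cam, 0.0, 1.0)
    if cam.max() > 0:
        cam = cam / cam.max()

    probs = np.exp(logits.data[0] - logits.data[0].max())
    probs /= probs.sum()
    predicted = "high" if probs[LABEL_TO_INDEX["high"]] >= probs[LABEL_TO_INDEX["low"]] \
        else "low"
    return CAMMap(relevance=cam, frame_index=frame.frame_index,
                  predicted_class=predicted)


def cam_center_of_mass(cam: CAMMap) -> tuple[float, float]:
    """(row, col) center of mass of the relevance map; frame center if zero."""
    r = cam.relevance
    total = r.sum()
    if total == 0:
        return ((r.shape[0] - 1) / 2.0, (r.shape[1] - 1) / 2.0)
    ii, jj = np.meshgrid(np.arange(r.shape[0]), np.arange(r.shape[1]), indexing="ij")
    return (float((ii * r).sum() / total), float((jj * r).sum() / total))


def overlay_cam(frame: CLEFrame, cam: CAMMap, colormap: str = "jet",
                alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend the relevance heatmap over the grayscale frame.

    Returns an (H, W, 3) uint8 RGB image; warm colors mark high relevance.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if frame.data.shape != cam.relevance.shape:
        raise ValueError(f"frame shape {frame.data.shape} does not match "
                         f"CAM shape {cam.relevance.shape}")
    cmap = plt.get_cmap(colormap)
    heat = cmap(cam.relevance)[..., :3]
    gray = np.repeat(frame.data[..., None], 3, axis=2)
    blended = (1 - alpha) * gray + alpha * heat
    return np.round(np.clip(blended, 0, 1) * 255).astype(np.uint8)


def save_cam(frame: CLEFrame, cam: CAMMap, out_dir: str | Path,
             stem: str = "cam") -> tuple[Path, Path]:
    """Write the overlay PNG and the raw relevance map (CSV) side by side."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overlay_path = out / f"{stem}_frame{cam.frame_index:03d}_overlay.png"
    raw_path = out / f"{stem}_frame{cam.frame_index:03d}_map.csv"
    iio.imwrite(overlay_path, overlay_cam(frame, cam))
    np.savetxt(raw_path, cam.relevance, delimiter=",", fmt="%.6f")
    return overlay_path, raw_path
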