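"""Frame standardization: intensity normalization, resizing, model-input assembly.

CLE devices deliver 8- or 16-bit grayscale frames. Intensities are mapped to
[0, 1] by fixed-scale division with the dtype maximum — never per-image
min-max — so that genuine brightness differences between frames (the
fluorescein signal itself is diagnostic) survive preprocessing. Frames are
then resized with bilinear interpolation to the side length the visual
backbone expects, and grayscale is replicated across channels to satisfy
RGB-trained backbone contracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass
class CLEFrame:
    """One grayscale CLE frame with intensities in [0, 1]."""

    data: np.ndarray
    frame_index: int = 0
    artifact_flag: bool | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or min(self.data.shape) < 1:
            raise ValueError(f"frame must be a 2-D grid, got shape {self.data.shape}")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("frame intensities must lie in [0, 1]; normalize first")


@dataclass
class CLESequence:
    """An ordered CLE examination stream — the unit of classification."""

    frames: list[CLEFrame]
    sequence_id: str
    case_id: str = ""
    roi_id: str = ""
    label: str | None = None          # "high" | "low" | None (unknown)
    frame_interval_s: float = 1.3

    def __post_init__(self):
        if not self.frames:
            raise ValueError("sequence must contain at least one frame")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")
        if self.label is not None and self.label not in ("high", "low"):
            raise ValueError(f"label must be 'high', 'low' or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        """(T, H, W) array of frame intensities."""
        return np.stack([f.data for f in self.frames])


def normalize_intensity(raw_frame: np.ndarray, bit_depth: int = 8,
                        frame_index: int = 0,
                        artifact_flag: bool | None = None) -> CLEFrame:
    """Map integer pixel values onto [0, 1] by dividing by the dtype maximum.

    Fixed-scale normalization keeps inter-frame brightness comparable; an
    already dim frame stays dim.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"unsupported bit depth {bit_depth}; expected 8 or 16")
    raw = np.asarray(raw_frame)
    scale = float(2 ** bit_depth - 1)
    if raw.min() < 0 or raw.max() > scale:
        raise ValueError(f"raw values outside [0, {int(scale)}] for bit depth {bit_depth}")
    return CLEFrame(raw.astype(np.float64) / scale, frame_index=frame_index,
                    artifact_flag=artifact_flag)


def resize_frame(frame: CLEFrame, target: int, pad_value: float | None = None) -> CLEFrame:
    """Bilinear resize to a square ``target`` x ``target`` grid.

    Non-square inputs are resized preserving aspect ratio and padded
    symmetrically to square. ``pad_value`` defaults to the frame's median
    intensity (an estimate of the fluorescein background level).
    """
    if target < 1:
        raise ValueError(f"target side length must be positive, got {target}")
    data = frame.data
    H, W = data.shape
    if H != W:
        if pad_value is None:
            pad_value = float(np.median(data))
        scale = target / max(H, W)
        h, w = max(1, round(H * scale)), max(1, round(W * scale))
        resized = _sk_resize(data, (h, w), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
        out = np.full((target, target), pad_value)
        top, left = (target - h) // 2, (target - w) // 2
        out[top:top + h, left:left + w] = resized
    else:
        out = _sk_resize(data, (target, target), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    out = np.clip(out, 0.0, 1.0)
    return CLEFrame(out, frame_index=frame.frame_index,
                    artifact_flag=frame.artifact_flag)


def preprocess_sequence(sequence: CLESequence, input_size: int) -> CLESequence:
    """Resize every frame of a sequence; order and metadata pass through."""
    frames = [resize_frame(f, input_size) for f in sequence.frames]
    return CLESequence(frames, sequence.sequence_id, sequence.case_id,
                       sequence.roi_id, sequence.label, sequence.frame_interval_s)


def to_model_input(sequence: CLESequence, channels: int = 3) -> np.ndarray:
    """Assemble a (T, C, H, W) batch, replicating grayscale across channels."""
    if channels < 1:
        raise ValueError(f"channels must be positive, got {channels}")
    if len(sequence) == 0:
        raise ValueError("cannot build model input from an empty sequence")
    stack = sequence.stack()                       # T, H, W
    return np.repeat(stack[:, None, :, :], channels, axis=1)
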