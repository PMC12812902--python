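"""Synthetic confocal laser endomicroscopy (CLE) sequence simulator.

Intraoperative CLE with intravenous fluorescein produces grayscale streams
(~1 frame / 1.3 s) in which the dye brightens the extracellular background
and cells appear as dark round silhouettes of varying size, shape and
density. The simulator reproduces that phenomenology so the grading models
can be trained and evaluated without patient data:

* a flat fluorescein background with Gaussian sensor noise;
* tumor-cell silhouettes: anti-aliased dark filled ellipses whose density,
  size spread and eccentricity encode hypercellularity and pleomorphism —
  held static across the frames of one sequence;
* red-blood-cell (RBC) silhouettes: small uniform discs that translate
  coherently across consecutive frames (toroidal wrap keeps their count
  constant), mimicking blood flowing through the field of view;
* motion artifacts: whole-frame directional smears affecting a configurable
  fraction of frames (about half, in practice);
* optional high-grade extras: irregular dark necrotic patches and bright
  branching microvascular structures.

Every sequence is generated from an integer seed; identical configuration
and seed reproduce every pixel and annotation bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .preprocessing import CLEFrame, CLESequence

__all__ = [
    "SimulatorConfig", "GradeProfile", "FrameAnnotation", "GroundTruthAnnotation",
    "render_frame", "simulate_sequence", "generate_dataset",
    "default_config", "high_grade_profile", "low_grade_profile",
    "rbc_confound_profiles", "write_dataset", "load_dataset",
]

_MOTION_BLUR_FRACTION = 1 / 8   # blur kernel length as a fraction of frame size


@dataclass(frozen=True)
class SimulatorConfig:
    """Generative parameters for one CLE sequence.

    Densities are expected silhouette counts per pixel^2; intensities live in
    [0, 1]; lengths are in pixels; velocities in pixels per frame.
    """

    frame_size: int = 128
    n_frames: int = 30
    frame_interval_s: float = 1.3
    background_level: float = 0.6
    background_noise_sd: float = 0.03
    cell_density: float = 40 / 128 ** 2
    cell_radius_mean: float = 4.0
    cell_radius_sd: float = 0.4
    cell_eccentricity_sd: float = 0.05
    silhouette_contrast: float = 0.35
    rbc_density: float = 8 / 128 ** 2
    rbc_radius: float = 1.5
    rbc_flow_velocity: float = 5.0
    motion_artifact_prob: float = 0.5
    vessel_proliferation: bool = False
    necrosis: bool = False
    cell_cluster_radius: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.frame_size < 32:
            raise ValueError(f"frame_size must be >= 32, got {self.frame_size}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        for name in ("cell_density", "rbc_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("background_level", "silhouette_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.motion_artifact_prob <= 1.0:
            raise ValueError("motion_artifact_prob must lie in [0, 1]")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be nonnegative")

    def replace(self, **overrides) -> "SimulatorConfig":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class GradeProfile:
    """A tumor grade plus the generative parameters that grade determines.

    High grade raises cellularity and the size/shape spread (pleomorphism)
    and may switch on necrotic patches and vascular proliferation; low grade
    keeps density normal-to-mild with near-uniform cells. Overrides touch
    only generative parameters, never the seed.
    """

    label: str
    config_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in ("high", "low"):
            raise ValueError(f"label must be 'high' or 'low', got {self.label!r}")
        if "seed" in self.config_overrides:
            raise ValueError("a grade profile must not override the seed")

    def apply(self, config: SimulatorConfig) -> SimulatorConfig:
        return config.replace(**self.config_overrides)


@dataclass
class FrameAnnotation:
    """Ground truth for one frame: silhouette geometry and the artifact flag."""

    tumor_cells: np.ndarray      # (N, 5): x, y, rx, ry, theta
    rbcs: np.ndarray             # (M, 2): x, y (radius is config.rbc_radius)
    artifact: bool = False


@dataclass
class GroundTruthAnnotation:
    """Per-frame annotations for a simulated sequence."""

    frames: list[FrameAnnotation]
    label: str
    necrosis_patches: np.ndarray | None = None   # (K, 5) ellipses
    vessel_paths: list[np.ndarray] = field(default_factory=list)

    def tumor_cell_counts(self) -> np.ndarray:
        return np.array([len(f.tumor_cells) for f in self.frames])

    def rbc_counts(self) -> np.ndarray:
        return np.array([len(f.rbcs) for f in self.frames])


# ---------------------------------------------------------------------------
# rendering


def _ellipse_coverage(canvas: np.ndarray, x: float, y: float, rx: float,
                      ry: float, theta: float, wrap: bool = False) -> None:
    """Accumulate (max) the soft coverage of one filled ellipse into canvas.

    Coverage falls from 1 inside to 0 outside over a ~1 px anti-aliasing band.
    With ``wrap`` the ellipse re-enters at the opposite edge (toroidal frame).
    """
    n = canvas.shape[0]
    centers = [(x, y)]
    if wrap:
        r = max(rx, ry) + 1.5
        xs = [x] + ([x - n] if x > n - r else []) + ([x + n] if x < r else [])
        ys = [y] + ([y - n] if y > n - r else []) + ([y + n] if y < r else [])
        centers = [(cx, cy) for cx in xs for cy in ys]
    ct, st = np.cos(theta), np.sin(theta)
    for cx, cy in centers:
        r = max(rx, ry) + 1.5
        i0, i1 = max(0, int(cy - r)), min(n, int(np.ceil(cy + r)) + 1)
        j0, j1 = max(0, int(cx - r)), min(n, int(np.ceil(cx + r)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        dx, dy = jj - cx, ii - cy
        u = (dx * ct + dy * st) / rx
        v = (-dx * st + dy * ct) / ry
        d = np.sqrt(u * u + v * v)
        cov = np.clip(0.5 + (1.0 - d) * min(rx, ry), 0.0, 1.0)
        np.maximum(canvas[i0:i1, j0:j1], cov, out=canvas[i0:i1, j0:j1])


def _render_vessels(n: int, paths: list[np.ndarray]) -> np.ndarray:
    """Bright tubular structures: soft discs stamped along each polyline."""
    canvas = np.zeros((n, n))
    for path in paths:
        for x, y in path:
            _ellipse_coverage(canvas, x, y, 1.8, 1.8, 0.0)
    return canvas


def render_frame(config: SimulatorConfig, annotation: FrameAnnotation,
                 rng: np.random.Generator | None = None,
                 necrosis_patches: np.ndarray | None = None,
                 vessel_paths: list[np.ndarray] | None = None) -> CLEFrame:
    """Compose one CLE frame from a silhouette layout.

    Assembly order: flat fluorescein background, bright vessels, dark
    necrotic patches, dark cell/RBC silhouettes (darker than the local
    background by ~``silhouette_contrast``), Gaussian noise, then an
    optional whole-frame directional smear for artifact frames. Intensities
    are clipped to [0, 1], never wrapped.
    """
    n = config.frame_size
    frame = np.full((n, n), config.background_level)

    if vessel_paths:
        frame += 0.25 * _render_vessels(n, vessel_paths)

    if necrosis_patches is not None and len(necrosis_patches):
        cov = np.zeros((n, n))
        for x, y, rx, ry, theta in necrosis_patches:
            _ellipse_coverage(cov, x, y, rx, ry, theta)
        frame -= 0.3 * cov

    # the frame is toroidal for every silhouette type: a shape crossing one
    # edge re-enters opposite, so tumor cells and RBCs have identical
    # edge statistics and silhouette counts are conserved exactly
    cov = np.zeros((n, n))
    for x, y, rx, ry, theta in annotation.tumor_cells:
        _ellipse_coverage(cov, x, y, rx, ry, theta, wrap=True)
    for x, y in annotation.rbcs:
        _ellipse_coverage(cov, x, y, config.rbc_radius, config.rbc_radius,
                          0.0, wrap=True)
    frame -= config.silhouette_contrast * cov
    frame = np.clip(frame, 0.0, 1.0)

    if config.background_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        frame = frame + rng.normal(0.0, config.background_noise_sd, size=frame.shape)
        frame = np.clip(frame, 0.0, 1.0)

    if annotation.artifact:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        axis = int(rng.integers(0, 2))
        k = max(3, int(n * _MOTION_BLUR_FRACTION))
        frame = uniform_filter1d(frame, size=k, axis=axis, mode="nearest")
        frame = np.clip(frame, 0.0, 1.0)

    return CLEFrame(frame, artifact_flag=annotation.artifact)


# ---------------------------------------------------------------------------
# sequence simulation


def _sample_tumor_cells(config: SimulatorConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.frame_size
    count = rng.poisson(config.cell_density * n * n)
    if config.cell_cluster_radius is not None and count:
        margin = config.cell_cluster_radius + config.cell_radius_mean
        cx, cy = rng.uniform(margin, n - margin, size=2)
        ang = rng.uniform(0, 2 * np.pi, size=count)
        rad = config.cell_cluster_radius * np.sqrt(rng.uniform(0, 1, size=count))
        xs, ys = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
    else:
        xs = rng.uniform(0, n, size=count)
        ys = rng.uniform(0, n, size=count)
    rx = np.maximum(0.6, rng.normal(config.cell_radius_mean, config.cell_radius_sd,
                                    size=count))
    ecc = 1.0 + rng.normal(0.0, config.cell_eccentricity_sd, size=count)
    ry = np.maximum(0.6, rx * np.clip(ecc, 0.3, 3.0))
    theta = rng.uniform(0, np.pi, size=count)
    return np.column_stack([xs, ys, rx, ry, theta]) if count else np.empty((0, 5))


def _sample_necrosis(config: SimulatorConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.frame_size
    k = int(rng.integers(1, 4))
    xs = rng.uniform(0, n, size=k)
    ys = rng.uniform(0, n, size=k)
    rx = rng.uniform(0.08 * n, 0.2 * n, size=k)
    ry = rx * rng.uniform(0.5, 1.0, size=k)
    theta = rng.uniform(0, np.pi, size=k)
    return np.column_stack([xs, ys, rx, ry, theta])


def _sample_vessels(config: SimulatorConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Branching bright curves as jittered random walks from a root point."""
    n = config.frame_size
    paths = []
    n_roots = int(rng.integers(1, 3))
    for _ in range(n_roots):
        x, y = rng.uniform(0.2 * n, 0.8 * n, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        for _branch in range(int(rng.integers(1, 3))):
            pts, bx, by, h = [], x, y, heading + rng.normal(0, 0.8)
            for _ in range(int(0.4 * n)):
                bx += np.cos(h)
                by += np.sin(h)
                h += rng.normal(0, 0.25)
                if not (0 <= bx < n and 0 <= by < n):
                    break
                pts.append((bx, by))
            if pts:
                paths.append(np.array(pts))
    return paths


def simulate_sequence(config: SimulatorConfig, profile: GradeProfile,
                      sequence_id: str = "seq_0000", case_id: str = "",
                      roi_id: str = "") -> tuple[CLESequence, GroundTruthAnnotation]:
    """Generate one labeled CLE sequence plus its ground-truth annotation.

    Tumor-cell silhouettes are static across frames (only noise varies);
    the RBC field translates rigidly by ``rbc_flow_velocity`` px/frame along
    a per-sequence flow direction with toroidal wrap-around, so the RBC
    count is conserved; frames are independently flagged as motion
    artifacts with probability ``motion_artifact_prob``.
    """
    cfg = profile.apply(config)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.frame_size

    tumor = _sample_tumor_cells(cfg, rng)
    necrosis = _sample_necrosis(cfg, rng) if cfg.necrosis else None
    vessels = _sample_vessels(cfg, rng) if cfg.vessel_proliferation else []

    m = rng.poisson(cfg.rbc_density * n * n)
    rbc0 = rng.uniform(0, n, size=(m, 2)) if m else np.empty((0, 2))
    flow_dir = rng.uniform(0, 2 * np.pi)
    step = cfg.rbc_flow_velocity * np.array([np.cos(flow_dir), np.sin(flow_dir)])

    artifact = rng.random(cfg.n_frames) < cfg.motion_artifact_prob

    ann_frames, frames = [], []
    for t in range(cfg.n_frames):
        rbcs = np.mod(rbc0 + t * step, n) if m else rbc0
        fa = FrameAnnotation(tumor_cells=tumor, rbcs=rbcs, artifact=bool(artifact[t]))
        frame = render_frame(cfg, fa, rng=rng, necrosis_patches=necrosis,
                             vessel_paths=vessels)
        frame.frame_index = t
        frames.append(frame)
        ann_frames.append(fa)

    seq = CLESequence(frames, sequence_id=sequence_id, case_id=case_id,
                      roi_id=roi_id, label=profile.label,
                      frame_interval_s=cfg.frame_interval_s)
    gt = GroundTruthAnnotation(ann_frames, label=profile.label,
                               necrosis_patches=necrosis, vessel_paths=vessels)
    return seq, gt


# ---------------------------------------------------------------------------
# presets


def default_config(**overrides) -> SimulatorConfig:
    return SimulatorConfig(**overrides)


def low_grade_profile() -> GradeProfile:
    """Normal-to-mildly increased cellularity, near-uniform cell geometry."""
    return GradeProfile("low", {
        "cell_density": 40 / 128 ** 2,
        "cell_radius_sd": 0.4,
        "cell_eccentricity_sd": 0.05,
    })


def high_grade_profile() -> GradeProfile:
    """Hypercellularity, pleomorphism, necrotic patches, vascular proliferation."""
    return GradeProfile("high", {
        "cell_density": 100 / 128 ** 2,
        "cell_radius_sd": 1.6,
        "cell_eccentricity_sd": 0.3,
        "necrosis": True,
        "vessel_proliferation": True,
    })


def rbc_confound_profiles(total_density: float = 30 / 64 ** 2,
                          static_fraction_low: float = 1 / 3,
                          flow_velocity: float = 6.0,
                          radius: float = 2.5) -> tuple[GradeProfile, GradeProfile]:
    """A stress-test pair separable only through temporal motion.

    Both grades show the same expected silhouette count per frame and
    identical silhouette geometry (uniform discs of one radius). In the
    high-grade profile every silhouette is a static tumor cell
    (hypercellularity); in the low-grade profile two thirds of them are
    red blood cells flowing across the field — frame-by-frame statistics
    are indistinguishable, so any frame-based classifier sits at chance,
    while the temporal signature (static vs flowing) remains learnable.
    """
    common = {
        "cell_radius_sd": 0.0,
        "cell_eccentricity_sd": 0.0,
        "cell_radius_mean": radius,
        "rbc_radius": radius,
        "motion_artifact_prob": 0.0,
        "necrosis": False,
        "vessel_proliferation": False,
    }
    high = GradeProfile("high", {**common,
                                 "cell_density": total_density,
                                 "rbc_density": 0.0})
    low = GradeProfile("low", {**common,
                               "cell_density": total_density * static_fraction_low,
                               "rbc_density": total_density * (1 - static_fraction_low),
                               "rbc_flow_velocity": flow_velocity})
    return high, low


# ---------------------------------------------------------------------------
# dataset assembly and I/O


def generate_dataset(n_cases: int, sequences_per_case: int, class_balance: float,
                     config: SimulatorConfig, seed: int,
                     profiles: tuple[GradeProfile, GradeProfile] | None = None,
                     ) -> tuple[list[CLESequence], list[GroundTruthAnnotation],
                                pd.DataFrame]:
    """Simulate a labeled corpus of CLE sequences.

    Each case is wholly one grade; ``class_balance`` is the fraction of
    high-grade cases (rounded to a whole case, at least one per class).
    Sequence seeds derive deterministically from ``seed`` so regeneration
    is bit-identical. Returns sequences, annotations and a manifest with
    one row per sequence.
    """
    if n_cases < 2:
        raise ValueError(f"need at least 2 cases, got {n_cases}")
    if not 0.0 < class_balance < 1.0:
        raise ValueError(f"class_balance must lie in (0, 1), got {class_balance}")
    n_high = round(class_balance * n_cases)
    if n_high == 0 or n_high == n_cases:
        raise ValueError("class_balance leaves one class with zero cases")
    if profiles is None:
        profiles = (high_grade_profile(), low_grade_profile())
    high_profile, low_profile = profiles
    if {high_profile.label, low_profile.label} != {"high", "low"}:
        raise ValueError("profiles must cover both grades")
    if high_profile.label == "low":
        high_profile, low_profile = low_profile, high_profile

    root = np.random.SeedSequence(seed)
    seqs: list[CLESequence] = []
    anns: list[GroundTruthAnnotation] = []
    rows = []
    k = 0
    for c in range(n_cases):
        profile = high_profile if c < n_high else low_profile
        case_id = f"case_{c:03d}"
        for s in range(sequences_per_case):
            child = root.spawn(1)[0]
            seq_seed = int(child.generate_state(1)[0] % (2 ** 31))
            sequence_id = f"seq_{k:04d}"
            roi_id = f"{case_id}_roi_{s // 2:02d}"
            seq, gt = simulate_sequence(config.replace(seed=seq_seed), profile,
                                        sequence_id=sequence_id, case_id=case_id,
                                        roi_id=roi_id)
            seqs.append(seq)
            anns.append(gt)
            rows.append({"sequence_id": sequence_id, "case_id": case_id,
                         "roi_id": roi_id, "label": profile.label,
                         "n_frames": len(seq), "path": ""})
            k += 1
    manifest = pd.DataFrame(rows)
    return seqs, anns, manifest


def write_dataset(sequences: list[CLESequence],
                  annotations: list[GroundTruthAnnotation],
                  manifest: pd.DataFrame, out_dir: str | Path,
                  bit_depth: int = 8) -> Path:
    """Write per-sequence frame directories, manifest.csv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for i, seq in enumerate(sequences):
        seq_dir = out / seq.sequence_id
        seq_dir.mkdir(exist_ok=True)
        for f in seq.frames:
            if bit_depth == 8:
                img = np.round(f.data * 255).astype(np.uint8)
                iio.imwrite(seq_dir / f"frame_{f.frame_index:03d}.png", img)
            elif bit_depth == 16:
                img = np.round(f.data * 65535).astype(np.uint16)
                iio.imwrite(seq_dir / f"frame_{f.frame_index:03d}.tiff", img)
            else:
                raise ValueError(f"unsupported bit depth {bit_depth}")
        manifest.loc[manifest["sequence_id"] == seq.sequence_id, "path"] = seq.sequence_id
    manifest.to_csv(out / "manifest.csv", index=False)

    gt_payload = []
    for seq, gt in zip(sequences, annotations):
        gt_payload.append({
            "sequence_id": seq.sequence_id,
            "label": gt.label,
            "frames": [{
                "tumor_cells": fa.tumor_cells.round(4).tolist(),
                "rbcs": fa.rbcs.round(4).tolist(),
                "artifact": fa.artifact,
            } for fa in gt.frames],
        })
    (out / "ground_truth.json").write_text(json.dumps(gt_payload))
    return out


def load_dataset(data_dir: str | Path, bit_depth: int = 8,
                 ) -> tuple[list[CLESequence], pd.DataFrame]:
    """Read a dataset written by :func:`write_dataset`."""
    from .preprocessing import normalize_intensity

    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    sequences = []
    for _, row in manifest.iterrows():
        seq_dir = data_dir / row["path"]
        frames = []
        for i, fp in enumerate(sorted(seq_dir.glob("frame_*"))):
            raw = iio.imread(fp)
            frames.append(normalize_intensity(raw, bit_depth=bit_depth, frame_index=i))
        sequences.append(CLESequence(frames, sequence_id=row["sequence_id"],
                                     case_id=row["case_id"], roi_id=row["roi_id"],
                                     label=row["label"]))
    return sequences, manifest
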