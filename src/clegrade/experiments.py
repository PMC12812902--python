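"""End-to-end desk-scale experiments on simulated CLE data.

These runners wire the full pipeline — simulate, preprocess, extract frozen
backbone features, split, train, evaluate per examination — at sizes chosen
for a single CPU: 64 px frames, 10-frame sequences, the self-contained test
CNN backbone and a narrow temporal model. Two standard experiments are
provided:

* ``run_separation_benchmark``: strongly separated high/low grade profiles
  (hypercellularity + pleomorphism vs mild uniform cellularity); measures
  how well the sequence model recovers the generative grade.
* ``run_confound_benchmark``: the RBC-confound preset, where per-frame
  statistics are identical between grades and only silhouette motion
  differs; compares the sequence model against the frame-based
  majority-vote baseline per examination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import BackboneSpec, FeatureSequence, build_backbone, extract_features
from .metrics import compute_metrics, confusion_from_predictions
from .preprocessing import CLESequence, to_model_input
from .synthetic import (
    SimulatorConfig,
    generate_dataset,
    high_grade_profile,
    low_grade_profile,
    rbc_confound_profiles,
)
from .temporal import (
    FrameHead,
    SequenceGradeModel,
    TemporalModelConfig,
    predict_frame_baseline,
    predict_sequence,
)
from .training import TrainConfig, make_splits, train_frame_baseline, train_model

DESK_FRAME_SIZE = 64
DESK_N_FRAMES = 10

DESK_MODEL_CONFIG = TemporalModelConfig(
    n_encoder_layers=2, n_heads=4, model_dim=32, feedforward_dim=64,
    conv_kernel=3, conv_channels=32, dropout=0.0,
)


def desk_config(**overrides) -> SimulatorConfig:
    """Desk-scale simulator configuration (64 px, 10 frames)."""
    base = dict(frame_size=DESK_FRAME_SIZE, n_frames=DESK_N_FRAMES,
                cell_density=15 / 64 ** 2, cell_radius_mean=3.5,
                rbc_density=4 / 64 ** 2, rbc_flow_velocity=4.0)
    base.update(overrides)
    return SimulatorConfig(**base)


def features_from_sequences(sequences: list[CLESequence],
                            spec: BackboneSpec) -> list[FeatureSequence]:
    """Frozen-backbone feature extraction for a list of sequences."""
    model = build_backbone(spec)
    out = []
    for seq in sequences:
        batch = to_model_input(seq, channels=3)
        out.append(extract_features(batch, spec, model=model,
                                    sequence_id=seq.sequence_id,
                                    case_id=seq.case_id, roi_id=seq.roi_id,
                                    label=seq.label))
    return out


@dataclass
class ExperimentResult:
    sequence_accuracy: float           # percent, per examination
    baseline_accuracy: float | None    # percent, per examination (frame model)
    baseline_frame_accuracy: float | None  # percent, per individual frame
    n_train: int
    n_test: int


def _evaluate(model: SequenceGradeModel, feats, ids) -> float:
    by_id = {f.sequence_id: f for f in feats}
    preds = [predict_sequence(by_id[i], model).label for i in ids]
    truth = [by_id[i].label for i in ids]
    counts = confusion_from_predictions(preds, truth)
    return compute_metrics(counts).accuracy


def _evaluate_baseline(head: FrameHead, feats, ids) -> tuple[float, float]:
    by_id = {f.sequence_id: f for f in feats}
    preds, truth, frame_hits, frame_total = [], [], 0, 0
    from .temporal import LABEL_TO_INDEX
    for i in ids:
        f = by_id[i]
        preds.append(predict_frame_baseline(f, head).label)
        truth.append(f.label)
        logits = head.logits_np(f.features)
        frame_hits += int((logits.argmax(axis=1) == LABEL_TO_INDEX[f.label]).sum())
        frame_total += f.n_frames
    exam_acc = compute_metrics(confusion_from_predictions(preds, truth)).accuracy
    return exam_acc, 100.0 * frame_hits / frame_total


def run_experiment(sequences: list[CLESequence], seed: int,
                   train_fraction: float = 0.75,
                   model_config: TemporalModelConfig = DESK_MODEL_CONFIG,
                   epochs: int = 100, learning_rate: float = 5e-3,
                   with_baseline: bool = True) -> ExperimentResult:
    """Split, train the sequence model (and optionally the frame baseline),
    and report per-examination test accuracies."""
    import pandas as pd

    spec = BackboneSpec(family="tiny_test_cnn", input_size=sequences[0].frames[0].data.shape[0],
                        seed=seed)
    feats = features_from_sequences(sequences, spec)
    manifest = pd.DataFrame([{"sequence_id": s.sequence_id, "case_id": s.case_id,
                              "label": s.label} for s in sequences])
    split = make_splits(manifest, train_fraction, 1, seed)[0]

    tc = TrainConfig(learning_rate=learning_rate, batch_size=10,
                     max_epochs=epochs, seed=seed)
    model, _ = train_model(feats, split, model_config, tc)
    seq_acc = _evaluate(model, feats, split.test_ids)

    base_exam = base_frame = None
    if with_baseline:
        head, _ = train_frame_baseline(feats, split, tc)
        base_exam, base_frame = _evaluate_baseline(head, feats, split.test_ids)

    return ExperimentResult(sequence_accuracy=seq_acc, baseline_accuracy=base_exam,
                            baseline_frame_accuracy=base_frame,
                            n_train=len(split.train_ids), n_test=len(split.test_ids))


def run_separation_benchmark(seed: int, n_cases: int = 16,
                             sequences_per_case: int = 5,
                             epochs: int = 100) -> ExperimentResult:
    """Separated grade profiles; 16 balanced cases x 5 sequences = 80
    sequences, 60 train / 20 test."""
    seqs, _, _ = generate_dataset(n_cases, sequences_per_case, 0.5,
                                  desk_config(), seed,
                                  profiles=(high_grade_profile(), low_grade_profile()))
    return run_experiment(seqs, seed, epochs=epochs, with_baseline=False)


def run_confound_benchmark(seed: int, n_cases: int = 16,
                           sequences_per_case: int = 5,
                           epochs: int = 100) -> ExperimentResult:
    """RBC-confound preset; identical per-frame statistics between grades."""
    high, low = rbc_confound_profiles()
    seqs, _, _ = generate_dataset(n_cases, sequences_per_case, 0.5,
                                  desk_config(), seed, profiles=(high, low))
    return run_experiment(seqs, seed, epochs=epochs, with_baseline=True)
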