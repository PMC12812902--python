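"""Simulator correctness: rendering, dynamics, determinism, calibration."""

import numpy as np
import pytest

from clegrade.experiments import desk_config
from clegrade.synthetic import (
    FrameAnnotation,
    GradeProfile,
    SimulatorConfig,
    generate_dataset,
    load_dataset,
    rbc_confound_profiles,
    render_frame,
    simulate_sequence,
    write_dataset,
)

NEUTRAL = GradeProfile("low", {})


def test_empty_scene_is_constant_background():
    cfg = SimulatorConfig(frame_size=32, n_frames=1, cell_density=0.0,
                          rbc_density=0.0, background_noise_sd=0.0,
                          motion_artifact_prob=0.0, background_level=0.55)
    seq, _ = simulate_sequence(cfg, NEUTRAL)
    np.testing.assert_allclose(seq.frames[0].data, 0.55)


def test_silhouette_center_darker_by_contrast():
    cfg = SimulatorConfig(frame_size=32, n_frames=1, background_noise_sd=0.0,
                          background_level=0.7, silhouette_contrast=0.3)
    ann = FrameAnnotation(tumor_cells=np.array([[16.0, 16.0, 4.0, 4.0, 0.0]]),
                          rbcs=np.empty((0, 2)))
    frame = render_frame(cfg, ann)
    assert frame.data[16, 16] == pytest.approx(0.7 - 0.3, abs=1e-9)
    assert frame.data[2, 2] == pytest.approx(0.7)


def test_degenerate_size_distribution_gives_identical_radii():
    cfg = SimulatorConfig(frame_size=64, n_frames=1, cell_radius_sd=0.0,
                          cell_eccentricity_sd=0.0, cell_radius_mean=3.0,
                          seed=3)
    _, gt = simulate_sequence(cfg, NEUTRAL)
    cells = gt.frames[0].tumor_cells
    assert len(cells) > 0
    np.testing.assert_allclose(cells[:, 2], 3.0)
    np.testing.assert_allclose(cells[:, 3], 3.0)


def test_poisson_count_calibration():
    """Mean annotated silhouette count over replicates matches lambda*A."""
    lam_per_px = 15 / 64 ** 2
    cfg = desk_config(n_frames=1, cell_density=lam_per_px, rbc_density=0.0)
    counts = []
    for i in range(200):
        _, gt = simulate_sequence(cfg.replace(seed=20_000 + i), NEUTRAL)
        counts.append(len(gt.frames[0].tumor_cells))
    lam = lam_per_px * 64 ** 2
    se = np.sqrt(lam / len(counts))
    assert abs(np.mean(counts) - lam) < 3 * se


def test_intensities_clipped_to_unit_interval():
    cfg = SimulatorConfig(frame_size=32, n_frames=3, background_level=0.15,
                          silhouette_contrast=0.9, background_noise_sd=0.2,
                          seed=5)
    seq, _ = simulate_sequence(cfg, NEUTRAL)
    stack = seq.stack()
    assert stack.min() >= 0.0 and stack.max() <= 1.0


def test_static_scene_frames_identical():
    cfg = SimulatorConfig(frame_size=32, n_frames=5, rbc_flow_velocity=0.0,
                          motion_artifact_prob=0.0, background_noise_sd=0.0)
    seq, _ = simulate_sequence(cfg, NEUTRAL)
    stack = seq.stack()
    for t in range(1, 5):
        np.testing.assert_array_equal(stack[t], stack[0])


def test_tumor_cells_static_and_count_conserved():
    cfg = desk_config(n_frames=8, seed=11)
    _, gt = simulate_sequence(cfg, NEUTRAL)
    first = gt.frames[0].tumor_cells
    for fa in gt.frames[1:]:
        np.testing.assert_array_equal(fa.tumor_cells, first)
    assert len(set(gt.rbc_counts())) == 1      # toroidal wrap conserves RBCs


def test_rbc_flow_shifts_cross_correlation_peak():
    """Circular cross-correlation between consecutive RBC-only frames peaks
    at the flow displacement (brute-force over integer lags)."""
    v = 6.0
    cfg = SimulatorConfig(frame_size=64, n_frames=2, cell_density=0.0,
                          rbc_density=40 / 64 ** 2, rbc_flow_velocity=v,
                          background_noise_sd=0.0, motion_artifact_prob=0.0,
                          seed=21)
    seq, gt = simulate_sequence(cfg, NEUTRAL)
    a = seq.frames[0].data - seq.frames[0].data.mean()
    b = seq.frames[1].data - seq.frames[1].data.mean()

    best, best_lag = -np.inf, None
    for di in range(-8, 9):
        for dj in range(-8, 9):
            score = float((a * np.roll(b, (-di, -dj), axis=(0, 1))).sum())
            if score > best:
                best, best_lag = score, (di, dj)

    # true displacement from the annotations (x = col, y = row)
    d = gt.frames[1].rbcs[0] - gt.frames[0].rbcs[0]
    d = (d + 32) % 64 - 32
    true_lag = (d[1], d[0])
    assert np.hypot(best_lag[0] - true_lag[0], best_lag[1] - true_lag[1]) <= 1.0
    assert np.hypot(*true_lag) == pytest.approx(v, abs=1e-6)


def test_artifact_fraction_matches_probability():
    """~half of frames carry motion artifacts, as seen clinically."""
    cfg = SimulatorConfig(frame_size=32, n_frames=400, motion_artifact_prob=0.5,
                          cell_density=0.0, rbc_density=0.0, seed=8)
    _, gt = simulate_sequence(cfg, NEUTRAL)
    frac = np.mean([fa.artifact for fa in gt.frames])
    se = np.sqrt(0.25 / 400)
    assert abs(frac - 0.5) < 3 * se


def test_sequence_determinism_bitwise():
    cfg = desk_config(seed=42)
    s1, g1 = simulate_sequence(cfg, NEUTRAL)
    s2, g2 = simulate_sequence(cfg, NEUTRAL)
    np.testing.assert_array_equal(s1.stack(), s2.stack())
    for a, b in zip(g1.frames, g2.frames):
        np.testing.assert_array_equal(a.tumor_cells, b.tumor_cells)
        np.testing.assert_array_equal(a.rbcs, b.rbcs)
        assert a.artifact == b.artifact


class TestGenerateDataset:
    def test_balanced_16_cases(self):
        _, _, manifest = generate_dataset(16, 1, 0.5, desk_config(n_frames=1),
                                          seed=0)
        by_case = manifest.drop_duplicates("case_id")
        assert (by_case["label"] == "high").sum() == 8
        assert (by_case["label"] == "low").sum() == 8

    def test_minimal_dataset(self):
        _, _, manifest = generate_dataset(2, 1, 0.5, desk_config(n_frames=1),
                                          seed=0)
        assert len(manifest) == 2
        assert manifest["case_id"].nunique() == 2

    def test_cases_are_grade_pure(self):
        _, _, manifest = generate_dataset(4, 3, 0.5, desk_config(n_frames=1),
                                          seed=1)
        assert (manifest.groupby("case_id")["label"].nunique() == 1).all()

    def test_regeneration_is_bit_identical(self):
        cfg = desk_config(n_frames=2)
        s1, _, m1 = generate_dataset(2, 2, 0.5, cfg, seed=17)
        s2, _, m2 = generate_dataset(2, 2, 0.5, cfg, seed=17)
        assert m1.equals(m2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.stack(), b.stack())

    def test_degenerate_balance_rejected(self):
        with pytest.raises(ValueError, match="zero cases"):
            generate_dataset(2, 1, 0.01, desk_config(n_frames=1), seed=0)


def test_write_load_round_trip_and_byte_identity(tmp_path):
    cfg = desk_config(n_frames=2)
    seqs, anns, manifest = generate_dataset(2, 1, 0.5, cfg, seed=23)
    d1 = write_dataset(seqs, anns, manifest, tmp_path / "a")
    d2 = write_dataset(seqs, anns, manifest, tmp_path / "b")
    f1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    f2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
    assert f1 == f2
    for rel in f1:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    loaded, mani = load_dataset(d1)
    assert len(loaded) == len(seqs)
    # 8-bit quantization bounds the reconstruction error
    assert np.abs(loaded[0].stack() - seqs[0].stack()).max() <= 0.5 / 255


def test_zero_separation_is_at_chance():
    """With identical generative profiles a nearest-centroid probe on mean
    intensity scores within 5 points of chance."""
    cfg = desk_config(n_frames=1)
    same = (GradeProfile("high", {}), GradeProfile("low", {}))
    seqs, _, manifest = generate_dataset(100, 10, 0.5, cfg, seed=31,
                                         profiles=same)
    x = np.array([s.stack().mean() for s in seqs])
    y = np.array([s.label == "high" for s in seqs])
    train = np.arange(len(x)) % 2 == 0
    mu_hi, mu_lo = x[train & y].mean(), x[train & ~y].mean()
    pred = np.abs(x[~train] - mu_hi) < np.abs(x[~train] - mu_lo)
    acc = 100.0 * (pred == y[~train]).mean()
    assert abs(acc - 50.0) <= 5.0


def test_confound_counts_not_separable_by_frame_statistics():
    """On the RBC-confound preset a logistic fit on per-frame silhouette
    counts performs at chance (the classes differ only in motion)."""
    from sklearn.linear_model import LogisticRegression

    high, low = rbc_confound_profiles()
    cfg = desk_config(n_frames=10)
    seqs, anns, manifest = generate_dataset(50, 2, 0.5, cfg, seed=37,
                                            profiles=(high, low))
    X = np.array([gt.tumor_cell_counts() + gt.rbc_counts() for gt in anns])
    y = np.array([s.label == "high" for s in seqs])
    train = np.arange(len(y)) % 2 == 0
    clf = LogisticRegression(max_iter=1000).fit(X[train], y[train])
    acc = 100.0 * clf.score(X[~train], y[~train])
    assert acc <= 60.0


def test_profile_cannot_override_seed():
    with pytest.raises(ValueError, match="seed"):
        GradeProfile("high", {"seed": 1})


@pytest.mark.parametrize("kwargs", [
    {"frame_size": 16}, {"n_frames": 0}, {"cell_density": -1.0},
    {"background_level": 1.5}, {"motion_artifact_prob": 2.0},
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulatorConfig(**kwargs)
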