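"""The sequence grading model: positional encoding, attention, aggregation,
classification head, and the frame-based baseline."""

import math

import numpy as np
import pytest

from clegrade import nn
from clegrade.nn import Tensor
from clegrade.backbone import FeatureSequence
from clegrade.temporal import (
    FrameHead,
    SequenceGradeModel,
    TemporalModelConfig,
    add_positional_encoding,
    predict_frame_baseline,
    predict_sequence,
    prediction_from_logits,
)

SMALL = TemporalModelConfig(n_encoder_layers=2, n_heads=2, model_dim=16,
                            feedforward_dim=32, conv_kernel=3, conv_channels=8,
                            dropout=0.0)


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        out = add_positional_encoding(np.zeros((1, 8)))
        np.testing.assert_allclose(out[0, 0::2], 0.0, atol=1e-12)
        np.testing.assert_allclose(out[0, 1::2], 1.0, atol=1e-12)

    def test_closed_form_sinusoids(self):
        """pe[p, 2i] = sin(p / 10000^(2i/D)), recomputed independently."""
        D, T = 12, 7
        out = add_positional_encoding(np.zeros((T, D)))
        for p in range(T):
            for i in range(D // 2):
                angle = p / 10000 ** (2 * i / D)
                assert out[p, 2 * i] == pytest.approx(math.sin(angle), abs=1e-10)
                assert out[p, 2 * i + 1] == pytest.approx(math.cos(angle), abs=1e-10)

    def test_identical_rows_become_distinct(self, rng):
        row = rng.normal(size=8)
        out = add_positional_encoding(np.stack([row] * 6))
        assert not np.allclose(out[0], out[5])

    def test_length_beyond_max_len_rejected(self):
        with pytest.raises(ValueError, match="max_len"):
            add_positional_encoding(np.zeros((20, 4)), max_len=10)

    def test_feature_sequence_round_trip(self, rng):
        fs = FeatureSequence(rng.normal(size=(4, 6)), sequence_id="s1", label="high")
        out = add_positional_encoding(fs)
        assert isinstance(out, FeatureSequence)
        assert out.sequence_id == "s1" and out.label == "high"


class TestAttentionClosedForms:
    def test_single_token_attention_is_value_path(self, rng):
        """With T=1 the attention weight is 1, so the output must equal
        W_o(W_v x + b_v) + b_o computed by hand."""
        att = nn.MultiHeadSelfAttention(8, 2, rng)
        x = rng.normal(size=(1, 1, 8))
        out = att(Tensor(x)).data
        v = x[0, 0] @ att.w_v.weight.data + att.w_v.bias.data
        expected = v @ att.w_o.weight.data + att.w_o.bias.data
        np.testing.assert_allclose(out[0, 0], expected, atol=1e-10)

    def test_masked_keys_cannot_influence_valid_positions(self, rng):
        att = nn.MultiHeadSelfAttention(8, 2, rng)
        x = rng.normal(size=(1, 3, 8))
        x_padded = np.concatenate([x, rng.normal(size=(1, 4, 8))], axis=1)
        mask = np.array([[False] * 3 + [True] * 4])
        out_ref = att(Tensor(x)).data
        out_pad = att(Tensor(x_padded), key_padding_mask=mask).data
        np.testing.assert_allclose(out_pad[:, :3], out_ref, atol=1e-10)


class TestAggregation:
    def test_identity_kernel1_conv_reduces_to_temporal_mean(self, rng):
        """conv_kernel=1 with an identity filter and zero bias makes the
        aggregation stage a plain temporal average."""
        cfg = TemporalModelConfig(n_encoder_layers=1, n_heads=2, model_dim=6,
                                  feedforward_dim=8, conv_kernel=1,
                                  conv_channels=6, dropout=0.0)
        model = SequenceGradeModel(6, cfg, seed=0)
        model.temporal_conv.weight.data[...] = np.eye(6)[None]
        model.temporal_conv.bias.data[...] = 0.0
        x = rng.normal(size=(1, 5, 6))
        out = model.aggregate_temporal(Tensor(x), np.array([5])).data
        np.testing.assert_allclose(out[0], x[0].mean(axis=0), atol=1e-10)

    def test_time_constant_input_matches_single_frame(self, rng):
        """With a kernel-1 convolution, a time-constant sequence pools to the
        same embedding as the single frame alone (stationarity)."""
        row = rng.normal(size=(8,))
        cfg1 = TemporalModelConfig(n_encoder_layers=1, n_heads=2, model_dim=8,
                                   feedforward_dim=8, conv_kernel=1,
                                   conv_channels=4, dropout=0.0)
        m = SequenceGradeModel(8, cfg1, seed=1)
        out6 = m.aggregate_temporal(Tensor(np.stack([row] * 6)[None]),
                                    np.array([6])).data
        out1 = m.aggregate_temporal(Tensor(row[None, None]), np.array([1])).data
        np.testing.assert_allclose(out6, out1, atol=1e-10)

    def test_zero_input_zero_bias_gives_zero_embedding(self):
        model = SequenceGradeModel(8, SMALL, seed=2)
        model.temporal_conv.bias.data[...] = 0.0
        out = model.aggregate_temporal(Tensor(np.zeros((1, 4, 16))),
                                       np.array([4])).data
        np.testing.assert_array_equal(out, 0.0)


class TestClassification:
    @pytest.mark.parametrize("logits,expected_high", [
        ((0.0, 0.0), 0.5),
        ((0.0, math.log(3)), 0.75),       # index 1 = high grade
        ((math.log(3), 0.0), 0.25),
    ])
    def test_softmax_closed_forms(self, logits, expected_high):
        pred = prediction_from_logits(np.array(logits))
        assert pred.prob_high == pytest.approx(expected_high, abs=1e-10)
        assert pred.prob_high + pred.prob_low == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_always_normalized(self, rng):
        for _ in range(50):
            pred = prediction_from_logits(rng.normal(scale=10, size=2))
            assert pred.prob_high + pred.prob_low == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= pred.prob_high <= 1.0

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            prediction_from_logits(np.array([np.nan, 0.0]))


class TestSequenceModel:
    def test_deterministic_prediction(self, rng):
        model = SequenceGradeModel(8, SMALL, seed=3)
        fs = FeatureSequence(rng.normal(size=(7, 8)))
        p1, p2 = predict_sequence(fs, model), predict_sequence(fs, model)
        assert p1.prob_high == p2.prob_high

    def test_single_frame_sequence_supported(self, rng):
        model = SequenceGradeModel(8, SMALL, seed=3)
        pred = predict_sequence(FeatureSequence(rng.normal(size=(1, 8))), model)
        assert pred.label in ("high", "low")

    def test_order_sensitivity(self, rng):
        """Reversing the frame order changes the sequence model's output —
        temporal order genuinely enters the prediction."""
        model = SequenceGradeModel(8, SMALL, seed=4)
        feats = rng.normal(size=(9, 8))
        p_fwd = predict_sequence(FeatureSequence(feats), model)
        p_rev = predict_sequence(FeatureSequence(feats[::-1].copy()), model)
        assert abs(p_fwd.prob_high - p_rev.prob_high) > 1e-8

    def test_padding_mask_non_interference(self, rng):
        """Batching a short sequence with a long one must not change the
        short sequence's logits."""
        model = SequenceGradeModel(8, SMALL, seed=5)
        model.eval()
        short = rng.normal(size=(4, 8))
        long = rng.normal(size=(11, 8))
        alone = model.forward_batch([short]).data[0]
        batched = model.forward_batch([short, long]).data[0]
        np.testing.assert_allclose(batched, alone, atol=1e-5)

    def test_empty_batch_rejected(self):
        model = SequenceGradeModel(8, SMALL, seed=5)
        with pytest.raises(ValueError, match="empty"):
            model.forward_batch([])


class TestFrameBaseline:
    def _head_voting(self, votes):
        """A stub head whose per-frame logits realize the given votes."""
        head = FrameHead(2, hidden_dim=2, seed=0)
        feats = np.array([[1.0, 0.0] if v == "high" else [0.0, 1.0]
                          for v in votes])
        # identity-ish head: logit_high = x0, logit_low = x1
        head.fc1.weight.data[...] = np.eye(2)
        head.fc1.bias.data[...] = 0.0
        head.fc2.weight.data[...] = np.array([[0.0, 1.0], [1.0, 0.0]])
        head.fc2.bias.data[...] = 0.0
        return head, FeatureSequence(feats)

    def test_majority_vote(self):
        head, fs = self._head_voting(["high", "high", "low"])
        assert predict_frame_baseline(fs, head).label == "high"
        head, fs = self._head_voting(["low", "low", "high"])
        assert predict_frame_baseline(fs, head).label == "low"

    def test_tie_breaks_toward_high_grade(self):
        head, fs = self._head_voting(["high", "low"])
        assert predict_frame_baseline(fs, head).label == "high"

    def test_permutation_invariance(self, rng):
        head = FrameHead(8, seed=1)
        feats = rng.normal(size=(10, 8))
        perm = rng.permutation(10)
        p1 = predict_frame_baseline(FeatureSequence(feats), head)
        p2 = predict_frame_baseline(FeatureSequence(feats[perm]), head)
        assert p1.prob_high == pytest.approx(p2.prob_high, abs=1e-12)
        assert p1.label == p2.label

    def test_mean_prob_aggregation(self, rng):
        head = FrameHead(8, seed=2)
        fs = FeatureSequence(rng.normal(size=(5, 8)))
        pred = predict_frame_baseline(fs, head, aggregation="mean_prob")
        assert pred.prob_high + pred.prob_low == pytest.approx(1.0, abs=1e-9)


def test_model_dim_head_divisibility_enforced():
    with pytest.raises(ValueError, match="divisible"):
        TemporalModelConfig(model_dim=10, n_heads=4)


def test_even_conv_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        TemporalModelConfig(conv_kernel=2)
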