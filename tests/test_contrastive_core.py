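"""Oracle and property tests for the contrastive distillation core."""

import numpy as np
import pytest

from cdseg._nn import Tensor
from cdseg.contrastive_core import (
    BiasConfig,
    correspondence_loss,
    correspondence_loss_from_features,
    cosine_similarity_map,
    distillation_loss,
    sample_triplet,
    self_correspondence_histogram,
    spatial_center,
)
from cdseg.segmentation_model import ModelConfig, build_head

from conftest import center_oracle, correspondence_loss_oracle, cosine_map_oracle


class TestCosineSimilarityMap:
    def test_self_similarity_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((3, 4, 4)) + 0.1
        x = cosine_similarity_map(f, f)
        for h in range(4):
            for w in range(4):
                assert x[h, w, h, w] == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_vectors_give_zero(self):
        fx = np.zeros((2, 1, 1))
        fy = np.zeros((2, 1, 1))
        fx[:, 0, 0] = (1.0, 0.0)
        fy[:, 0, 0] = (0.0, 1.0)
        assert cosine_similarity_map(fx, fy)[0, 0, 0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_zero_vector_defined_as_zero_similarity(self):
        fx = np.zeros((2, 1, 1))
        fy = np.ones((2, 1, 1))
        assert cosine_similarity_map(fx, fy)[0, 0, 0, 0] == 0.0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = int(rng.integers(1, 5))
            h, w, i, j = (int(v) for v in rng.integers(1, 5, size=4))
            fx = rng.standard_normal((c, h, w))
            fy = rng.standard_normal((c, i, j))
            got = cosine_similarity_map(fx, fy)
            assert np.abs(got - cosine_map_oracle(fx, fy)).max() < 1e-5

    def test_entries_bounded_by_cosine_range(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            fx = rng.standard_normal((4, 3, 3)) * rng.uniform(0.1, 50)
            x = cosine_similarity_map(fx, fx)
            assert x.min() >= -1 - 1e-6 and x.max() <= 1 + 1e-6

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channel mismatch"):
            cosine_similarity_map(np.ones((2, 2, 2)), np.ones((3, 2, 2)))


class TestSpatialCenter:
    def test_constant_tensor_maps_to_zero(self):
        assert np.allclose(spatial_center(np.full((2, 2, 3, 3), 7.0)), 0.0)

    def test_hand_arithmetic_case(self):
        x = np.zeros((1, 1, 1, 2))
        x[0, 0, :, :] = [1.0, 3.0]
        assert np.allclose(spatial_center(x)[0, 0], [-1.0, 1.0])

    def test_per_position_means_vanish_and_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 2, 4, 5))
        s = spatial_center(x)
        assert np.abs(s.mean(axis=(2, 3))).max() < 1e-6
        assert np.abs(spatial_center(s) - s).max() < 1e-6
        assert np.abs(s - center_oracle(x)).max() < 1e-12


class TestCorrespondenceLoss:
    def _random_instance(self, rng):
        c = int(rng.integers(2, 4))
        fx = rng.standard_normal((c, 2, 2))
        fy = rng.standard_normal((c, 2, 2))
        hx = rng.standard_normal((c + 1, 2, 2))
        hy = rng.standard_normal((c + 1, 2, 2))
        return fx, fy, hx, hy

    def test_matches_unrolled_scalar_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            fx, fy, hx, hy = self._random_instance(rng)
            b = float(rng.uniform(-0.5, 1.0))
            got = correspondence_loss_from_features(fx, fy, hx, hy, b)
            assert got == pytest.approx(
                correspondence_loss_oracle(fx, fy, hx, hy, b), abs=1e-5
            )

    def test_closed_gate_gives_zero_loss(self):
        # head features chosen so every student similarity is <= 0
        fx = np.ones((2, 1, 1))
        hx = np.zeros((2, 1, 2))
        hx[:, 0, 0] = (1.0, 0.0)
        hx[:, 0, 1] = (-1.0, 0.0)
        # student pairs: (+1,-1) cross sims are -1, self sims 1 -> use cross pair
        hy = -hx
        got = correspondence_loss_from_features(fx, fx, hx[:, :, :1], hy[:, :, :1], 0.2)
        assert got == 0.0

    def test_linear_in_bias_with_fixed_features(self):
        rng = np.random.default_rng(9)
        fx, fy, hx, hy = self._random_instance(rng)
        b, delta = 0.1, 0.37
        v0 = correspondence_loss_from_features(fx, fy, hx, hy, b)
        v1 = correspondence_loss_from_features(fx, fy, hx, hy, b + delta)
        gate_mean = np.mean(np.maximum(cosine_map_oracle(hx, hy), 0.0))
        assert v1 - v0 == pytest.approx(delta * gate_mean, abs=1e-10)

    def test_bias_monotonicity(self):
        rng = np.random.default_rng(10)
        fx, fy, hx, hy = self._random_instance(rng)
        vals = [
            correspondence_loss_from_features(fx, fy, hx, hy, b)
            for b in (-0.5, 0.0, 0.5, 1.0)
        ]
        if np.mean(np.maximum(cosine_map_oracle(hx, hy), 0.0)) > 0:
            assert all(b2 >= b1 for b1, b2 in zip(vals, vals[1:]))

    def test_scale_invariance_of_features(self):
        rng = np.random.default_rng(11)
        fx, fy, hx, hy = self._random_instance(rng)
        v0 = correspondence_loss_from_features(fx, fy, hx, hy, 0.3)
        v1 = correspondence_loss_from_features(7.3 * fx, fy, 7.3 * hx, 7.3 * hy, 0.3)
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_gradient_reaches_head_only(self, small_backbone):
        rng = np.random.default_rng(12)
        head = build_head(ModelConfig(head_channels=8), small_backbone.spec.channels, seed=1)
        x = rng.standard_normal((16, 16))
        y = rng.standard_normal((16, 16))
        before = small_backbone.spec.parameter_digest
        loss = correspondence_loss(x, y, 0.1, small_backbone, head)
        loss.backward()
        assert any(p.grad is not None and np.any(p.grad != 0) for p in head.parameters())
        assert small_backbone.spec.parameter_digest == before


class TestDistillationLoss:
    def test_compositional_identity(self, small_backbone):
        rng = np.random.default_rng(13)
        head = build_head(ModelConfig(head_channels=8), small_backbone.spec.channels, seed=4)
        anchor = rng.standard_normal((16, 16))
        pos = [rng.standard_normal((16, 16)) for _ in range(2)]
        neg = rng.standard_normal((16, 16))
        biases = BiasConfig()
        total = distillation_loss(anchor, pos, neg, biases, small_backbone, head)
        expected = (
            float(correspondence_loss(anchor, anchor, biases.b_self, small_backbone, head).data)
            + 0.5
            * sum(
                float(correspondence_loss(anchor, p, biases.b_pos, small_backbone, head).data)
                for p in pos
            )
            + float(correspondence_loss(anchor, neg, biases.b_neg, small_backbone, head).data)
        )
        assert float(total.data) == pytest.approx(expected, abs=1e-6)

    def test_empty_positives_drops_term_with_warning(self, small_backbone, caplog):
        rng = np.random.default_rng(14)
        head = build_head(ModelConfig(head_channels=8), small_backbone.spec.channels, seed=4)
        anchor = rng.standard_normal((16, 16))
        neg = rng.standard_normal((16, 16))
        biases = BiasConfig()
        import logging

        with caplog.at_level(logging.WARNING, logger="cdseg.contrastive_core"):
            total = distillation_loss(anchor, [], neg, biases, small_backbone, head)
        assert "no positives" in caplog.text
        expected = float(
            correspondence_loss(anchor, anchor, biases.b_self, small_backbone, head).data
        ) + float(correspondence_loss(anchor, neg, biases.b_neg, small_backbone, head).data)
        assert float(total.data) == pytest.approx(expected, abs=1e-6)


class TestSampleTriplet:
    def test_interior_anchor(self):
        t = sample_triplet(3, 10)
        assert set(t.positives) == {2, 4}
        assert t.negative == 8
        assert not t.degenerate

    def test_boundary_anchor_keeps_single_positive(self):
        t = sample_triplet(0, 10)
        assert t.positives == (1,)
        assert t.negative == 5

    def test_modular_wrap_for_negative(self):
        t = sample_triplet(7, 9)
        assert set(t.positives) == {6, 8}
        assert t.negative == 2

    @pytest.mark.parametrize("n", range(1, 13))
    def test_full_contract_for_all_anchor_positions(self, n):
        for i in range(n):
            t = sample_triplet(i, n)
            assert t.anchor == i
            assert set(t.positives) == {j for j in (i - 1, i + 1) if 0 <= j < n}
            assert t.negative == (i + n // 2) % n
            assert t.degenerate == (n < 4)
            if n >= 4:
                assert t.anchor not in t.positives
                assert t.negative != t.anchor
                assert t.negative not in t.positives

    def test_out_of_range_anchor_raises(self):
        with pytest.raises(IndexError):
            sample_triplet(10, 10)
        with pytest.raises(IndexError):
            sample_triplet(-1, 10)


class TestSelfCorrespondenceHistogram:
    def test_counts_conserve_total_entries(self, small_backbone):
        rng = np.random.default_rng(15)
        head = build_head(ModelConfig(head_channels=8), small_backbone.spec.channels, seed=0)
        slices = [rng.standard_normal((16, 16)) for _ in range(3)]
        counts, edges = self_correspondence_histogram(slices, small_backbone, head)
        assert counts.sum() == 3 * (2 * 2) ** 2  # (h*w*i*j) per 16/8=2 grid
        assert len(edges) == len(counts) + 1

    def test_constant_feature_map_concentrates_at_one(self, small_backbone):
        head = build_head(ModelConfig(head_channels=8), small_backbone.spec.channels, seed=0)

        class ConstantHead:
            def __call__(self, x):
                return Tensor(np.ones((1, 4, x.shape[2], x.shape[3])))

        counts, edges = self_correspondence_histogram(
            [np.zeros((16, 16))], small_backbone, ConstantHead()
        )
        top_bin = np.digitize(1.0, edges) - 1
        assert counts[min(top_bin, len(counts) - 1)] == counts.sum()


class TestBiasConfig:
    def test_rejects_repulsion_below_attraction(self):
        with pytest.raises(ValueError):
            BiasConfig(b_pos=0.5, b_neg=0.1)
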