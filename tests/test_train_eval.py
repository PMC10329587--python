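"""Metrics oracles, statistics, splits, and training-loop contracts."""

import numpy as np
import pytest
from scipy import stats

from cdseg.imaging_io import PreprocessConfig
from cdseg.objectives import LossWeights
from cdseg.phantom_gen import PhantomConfig, generate_phantom
from cdseg.segmentation_model import ModelConfig, SegmentationModel
from cdseg.train_eval import (
    TrainConfig,
    compare_methods,
    dice,
    holdout_split,
    infer_volume,
    surface_distances,
    train,
)

from conftest import surface_distance_oracle


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        assert dice(a, b) == 0.0

    def test_hand_count_case(self):
        a = np.zeros((1, 2, 4), bool)
        b = np.zeros((1, 2, 4), bool)
        a[0, 0] = True  # |A| = 4
        b[0, :, :2] = True  # |B| = 4, overlap 2
        assert dice(a, b) == pytest.approx(0.5)

    def test_symmetry_and_empty_convention(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5, 5)) > 0.6
        b = rng.random((5, 5, 5)) > 0.6
        assert dice(a, b) == dice(b, a)
        empty = np.zeros((5, 5, 5), bool)
        assert dice(empty, empty) == 1.0
        assert dice(empty, a) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestSurfaceDistances:
    def test_identical_masks_give_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert surface_distances(m, m, (1, 1, 1)) == (0.0, 0.0)

    def test_two_point_closed_form(self):
        a = np.zeros((8, 3, 3), bool)
        b = np.zeros((8, 3, 3), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True  # 3 voxels apart along z
        assert surface_distances(a, b, (1.0, 1.0, 1.0)) == (3.0, 3.0)
        assert surface_distances(a, b, (2.0, 1.0, 1.0)) == (6.0, 6.0)

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(1)
        for trial in range(6):
            shape = tuple(rng.integers(5, 13, size=3))
            a = np.zeros(shape, bool)
            b = np.zeros(shape, bool)
            # random small boxes, guaranteed nonempty
            for m in (a, b):
                z, y, x = (rng.integers(0, s - 2) for s in shape)
                dz, dy, dx = (int(rng.integers(1, 4)) for _ in range(3))
                m[z : z + dz, y : y + dy, x : x + dx] = True
            spacing = tuple(rng.uniform(0.5, 3.0, size=3))
            got = surface_distances(a, b, spacing)
            want = surface_distance_oracle(a, b, spacing)
            assert got[0] == pytest.approx(want[0], abs=1e-6)
            assert got[1] == pytest.approx(want[1], abs=1e-6)

    def test_symmetric_and_spacing_linear(self):
        rng = np.random.default_rng(2)
        a = np.zeros((7, 7, 7), bool)
        b = np.zeros((7, 7, 7), bool)
        a[1:3, 1:4, 2:5] = True
        b[3:6, 2:5, 1:3] = True
        s = (1.5, 0.8, 2.0)
        assert surface_distances(a, b, s) == surface_distances(b, a, s)
        assd1, mssd1 = surface_distances(a, b, s)
        assd3, mssd3 = surface_distances(a, b, tuple(3 * v for v in s))
        assert assd3 == pytest.approx(3 * assd1, rel=1e-9)
        assert mssd3 == pytest.approx(3 * mssd1, rel=1e-9)
        assert assd1 <= mssd1

    def test_empty_mask_is_undefined_not_zero(self):
        m = np.zeros((4, 4, 4), bool)
        full = ~m.copy()
        with pytest.raises(ValueError, match="undefined surface distance"):
            surface_distances(m, full, (1, 1, 1))


class TestCompareMethods:
    def test_identical_series_degenerate_p_one(self):
        r = compare_methods([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert r.degenerate and r.p_value == 1.0

    def test_matches_closed_form_paired_t(self):
        a = np.array([0.91, 0.88, 0.93, 0.90, 0.87])
        b = np.array([0.89, 0.86, 0.90, 0.91, 0.85])
        d = a - b
        n = len(d)
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t_stat), df=n - 1)
        r = compare_methods(a, b)
        assert r.t_statistic == pytest.approx(t_stat, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_constant_comparator_at_mean_gives_p_one(self):
        a = [0.8, 0.9, 1.0]
        r = compare_methods(a, float(np.mean(a)))
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            compare_methods([0.9, 0.8], [0.9, 0.8, 0.7])


class TestHoldoutSplit:
    def test_five_per_dataset_reserved(self):
        vols = {"a": list(range(12)), "b": list(range(100, 112))}
        train_set, test_set = holdout_split(vols, n_test=5, seed=0)
        assert len(test_set) == 10
        assert len(train_set) == 14
        assert not set(train_set) & set(test_set)

    def test_deterministic_under_seed(self):
        vols = {"a": list(range(20))}
        assert holdout_split(vols, seed=3) == holdout_split(vols, seed=3)

    def test_small_dataset_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="reserving"):
            train_set, test_set = holdout_split({"tiny": list(range(4))}, n_test=5, seed=0)
        assert len(test_set) == 1
        assert len(train_set) == 3

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            holdout_split({"none": []})


def _tiny_phantoms(n, z=8, seed0=30):
    cfg = PhantomConfig(shape=(z, 32, 32), spacing_mm=(3.0, 1.5, 1.5))
    return [generate_phantom(cfg, seed0 + i) for i in range(n)]


def _tiny_model(backbone):
    cfg = ModelConfig(head_channels=8, decoder_channels=(8, 8, 8, 8, 8), dropout_rate=0.0)
    return SegmentationModel(backbone, cfg, seed=1)


_PRE32 = PreprocessConfig(target_slice_size=(32, 32), intensity_window=None)


class TestTrainLoop:
    def test_single_epoch_history_row(self, small_backbone):
        vols = _tiny_phantoms(2)
        model = _tiny_model(small_backbone)
        hist = train(
            model, vols, [], TrainConfig(max_epochs=1, batch_size=4, seed=0),
            preprocess=_PRE32, monitor_fn=lambda m: 0.5,
        )
        assert len(hist) == 1
        assert {"epoch", "cd", "focal", "tversky", "logiou", "entropy", "total",
                "monitor_dice", "lr"} <= set(hist.columns)

    def test_plateau_reduces_lr_exactly_once(self, small_backbone):
        vols = _tiny_phantoms(1)
        model = _tiny_model(small_backbone)
        cfg = TrainConfig(
            max_epochs=5, batch_size=8, plateau_patience_epochs=3, seed=0,
            lr_reduction_factor=0.1,
        )
        hist = train(model, vols, [], cfg, preprocess=_PRE32, monitor_fn=lambda m: 0.42)
        lrs = hist["lr"].to_numpy()
        assert np.allclose(lrs[:3], cfg.initial_lr)
        assert np.allclose(lrs[3:], cfg.initial_lr * 0.1)

    def test_backbone_digest_unchanged_and_trainables_change(self, small_backbone):
        from cdseg._nn import parameter_digest

        vols = _tiny_phantoms(1)
        model = _tiny_model(small_backbone)
        bb_before = small_backbone.spec.parameter_digest
        head_dec_before = model.trainable_digest()
        train(
            model, vols, [], TrainConfig(max_epochs=1, batch_size=8, seed=0),
            preprocess=_PRE32, monitor_fn=lambda m: 0.0,
        )
        assert parameter_digest(small_backbone.weights + small_backbone.biases) == bb_before
        assert model.trainable_digest() != head_dec_before

    def test_no_masks_rejected(self, small_backbone):
        vols = _tiny_phantoms(1)
        vols[0].mask = None
        with pytest.raises(ValueError, match="mask"):
            train(_tiny_model(small_backbone), vols, [], TrainConfig(max_epochs=1), preprocess=_PRE32)

    def test_degenerate_short_volumes_skip_contrastive(self, small_backbone, caplog):
        import logging

        # build a 3-slice volume (too short for triplets) by cropping a phantom
        rec = generate_phantom(PhantomConfig(shape=(8, 32, 32)), seed=40)
        from cdseg.imaging_io import VolumeRecord

        short = VolumeRecord(
            voxels=rec.voxels[:3], spacing_mm=rec.spacing_mm, affine=rec.affine,
            mask=rec.mask[:3],
        )
        model = _tiny_model(small_backbone)
        with caplog.at_level(logging.WARNING, logger="cdseg.train_eval"):
            hist = train(
                model, [short], [], TrainConfig(max_epochs=1, batch_size=4, seed=0),
                preprocess=_PRE32, monitor_fn=lambda m: 0.0,
            )
        assert "contrastive term skipped" in caplog.text
        assert np.allclose(hist["cd"], 0.0)


class TestInference:
    def test_output_shape_and_idempotence(self, small_backbone):
        vols = _tiny_phantoms(1)
        model = _tiny_model(small_backbone)
        m1 = infer_volume(model, vols[0], _PRE32)
        m2 = infer_volume(model, vols[0], _PRE32)
        assert m1.shape == vols[0].voxels.shape
        np.testing.assert_array_equal(m1, m2)
        assert set(np.unique(m1)) <= {0, 1}
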