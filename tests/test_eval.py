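"""Metrics: confusion matrices, PA/IoU/MIoU oracles, evaluation, overlays."""

import numpy as np
import pytest

from fissureseg.augment import apply_dihedral
from fissureseg.data_io import Sample
from fissureseg.eval import (
    accumulate,
    compare_configs,
    confusion,
    evaluate,
    miou,
    overlay,
    per_class_iou,
    pixel_accuracy,
)
from fissureseg.net import ModelConfig
from fissureseg.train import TrainConfig


def _brute_force_metrics(pred, true, c):
    """Independent set-overlap computation of PA and per-class IoU."""
    pa = float(np.mean(pred == true))
    ious = []
    for cls in range(c):
        p = pred == cls
        t = true == cls
        union = np.logical_or(p, t).sum()
        if union:
            ious.append(np.logical_and(p, t).sum() / union)
    return pa, float(np.mean(ious))


class TestConfusion:
    def test_identical_masks_diagonal(self):
        m = np.array([[0, 1], [1, 0]])
        cm = confusion(m, m, 2)
        np.testing.assert_array_equal(cm, [[2, 0], [0, 2]])

    def test_hand_counted_fixture(self):
        """All-background prediction vs 4 fissure pixels in a 4x4 mask."""
        true = np.zeros((4, 4), int)
        true[0, :4] = 1
        pred = np.zeros((4, 4), int)
        np.testing.assert_array_equal(confusion(pred, true, 2), [[12, 0], [4, 0]])

    def test_additivity_equals_concatenation(self):
        rng = np.random.default_rng(0)
        a_p, a_t = rng.integers(0, 2, (2, 8, 8))
        b_p, b_t = rng.integers(0, 2, (2, 8, 8))
        joint = confusion(np.c_[a_p, b_p], np.c_[a_t, b_t], 2)
        np.testing.assert_array_equal(
            accumulate(confusion(a_p, a_t, 2), confusion(b_p, b_t, 2)), joint
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2), int), np.zeros((3, 3), int), 2)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 5), np.zeros((2, 2), int), 2)


class TestPaMiou:
    def test_perfect_prediction(self):
        cm = np.diag([10, 5, 3])
        assert pixel_accuracy(cm) == 1.0
        assert miou(cm) == 1.0

    def test_fixture_arithmetic(self):
        cm = np.array([[12, 0], [4, 0]])
        assert pixel_accuracy(cm) == pytest.approx(0.75)
        iou = per_class_iou(cm)
        assert iou[0] == pytest.approx(0.75)
        assert iou[1] == pytest.approx(0.0)
        assert miou(cm) == pytest.approx(0.375)

    def test_zero_union_class_excluded(self):
        cm = np.zeros((3, 3), int)
        cm[0, 0] = 8
        cm[1, 1] = 2
        assert miou(cm) == pytest.approx(1.0)  # class 2 absent everywhere

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pixel_accuracy(np.zeros((2, 2), int))

    @pytest.mark.parametrize("case", range(100))
    def test_matches_brute_force_on_random_pairs(self, case):
        rng = np.random.default_rng(case)
        pred = rng.integers(0, 2, (16, 16))
        true = rng.integers(0, 2, (16, 16))
        cm = confusion(pred, true, 2)
        pa_ref, miou_ref = _brute_force_metrics(pred, true, 2)
        assert pixel_accuracy(cm) == pa_ref
        assert miou(cm) == pytest.approx(miou_ref, rel=1e-12)

    def test_dihedral_invariance(self):
        rng = np.random.default_rng(7)
        pred = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        true = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        base = confusion(pred, true, 2)
        s = Sample(np.zeros((8, 8, 3), np.uint8), pred, "p")
        t = Sample(np.zeros((8, 8, 3), np.uint8), true, "t")
        for kind in ("rot90", "hflip", "hflip_rot270"):
            cm = confusion(apply_dihedral(s, kind).mask, apply_dihedral(t, kind).mask, 2)
            assert pixel_accuracy(cm) == pixel_accuracy(base)
            assert miou(cm) == pytest.approx(miou(base))

    def test_class_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        pred = rng.integers(0, 3, (10, 10))
        true = rng.integers(0, 3, (10, 10))
        perm = np.array([2, 0, 1])
        cm = confusion(pred, true, 3)
        cm_p = confusion(perm[pred], perm[true], 3)
        np.testing.assert_allclose(np.sort(per_class_iou(cm)), np.sort(per_class_iou(cm_p)))
        assert miou(cm) == pytest.approx(miou(cm_p))
        # both scores stay in [0, 1]; note MIoU <= PA does NOT hold in general
        assert 0.0 <= miou(cm) <= 1.0 and 0.0 <= pixel_accuracy(cm) <= 1.0


class _OracleModel:
    """Callable predictor returning the true masks (set at construction)."""

    def __init__(self, masks):
        self.masks = np.asarray(masks)

    def __call__(self, images):
        return self.masks


class TestEvaluate:
    def _config(self):
        return TrainConfig(learning_rate=1e-3, input_size=(64, 64))

    def test_oracle_predictor_scores_perfectly(self, small_dataset):
        masks = np.stack([s.mask for s in small_dataset])
        report = evaluate(_OracleModel(masks), small_dataset, self._config(), num_classes=2)
        assert report.pixel_accuracy == 1.0
        assert report.miou == 1.0
        assert report.n_images == len(small_dataset)

    def test_duplicated_dataset_same_report(self, small_dataset):
        masks = np.stack([s.mask for s in small_dataset])
        a = evaluate(_OracleModel(masks), small_dataset, self._config(), num_classes=2)
        doubled = list(small_dataset) + list(small_dataset)
        b = evaluate(
            _OracleModel(np.concatenate([masks, masks])), doubled, self._config(), num_classes=2
        )
        assert a.pixel_accuracy == b.pixel_accuracy
        assert a.miou == pytest.approx(b.miou)

    def test_matches_manual_confusion_accumulation(self, small_dataset):
        rng = np.random.default_rng(3)
        preds = rng.integers(0, 2, (len(small_dataset), 64, 64)).astype(np.uint8)
        report = evaluate(_OracleModel(preds), small_dataset, self._config(), num_classes=2)
        total = accumulate(
            *[confusion(preds[i], s.mask, 2) for i, s in enumerate(small_dataset)]
        )
        assert report.pixel_accuracy == pytest.approx(pixel_accuracy(total))
        assert report.miou == pytest.approx(miou(total))

    def test_unlabeled_sample_rejected(self, small_dataset):
        bad = [Sample(small_dataset[0].image, None, "x")]
        with pytest.raises(ValueError):
            evaluate(_OracleModel(np.zeros((1, 64, 64))), bad, self._config())

    def test_per_image_option_differs_in_general(self, small_dataset):
        rng = np.random.default_rng(5)
        preds = rng.integers(0, 2, (len(small_dataset), 64, 64)).astype(np.uint8)
        agg = evaluate(_OracleModel(preds), small_dataset, self._config(), num_classes=2)
        per = evaluate(
            _OracleModel(preds), small_dataset, self._config(), num_classes=2, per_image=True
        )
        assert 0.0 <= per.miou <= 1.0
        assert per.n_images == agg.n_images


class TestOverlay:
    def test_alpha_zero_returns_original(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        mask = rng.integers(0, 2, (8, 8))
        np.testing.assert_array_equal(overlay(img, mask, alpha=0.0), img)

    def test_alpha_one_paints_mask_pixels(self):
        img = np.zeros((4, 4, 3), np.uint8)
        mask = np.zeros((4, 4), int)
        mask[1, 1] = 1
        out = overlay(img, mask, color=(10, 20, 30), alpha=1.0)
        np.testing.assert_array_equal(out[1, 1], [10, 20, 30])
        assert (out[mask == 0] == 0).all()

    def test_empty_mask_returns_original(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (6, 6, 3), dtype=np.uint8)
        np.testing.assert_array_equal(overlay(img, np.zeros((6, 6), int)), img)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            overlay(np.zeros((2, 2, 3)), np.zeros((2, 2)), alpha=1.5)


class TestCompareConfigs:
    def test_single_config_single_seed(self, small_params):
        grid = [("plain", ModelConfig(encoder="plain_unet", use_gcn=False, use_br=False,
                                      base_channels=8, input_size=(64, 64)))]
        tcfg = TrainConfig(learning_rate=1e-3, batch_size=4, input_size=(64, 64),
                           epochs=1, seed=0)
        table = compare_configs(grid, (small_params, 6, 3), tcfg, n_seeds=1)
        assert list(table["model"]) == ["plain"]
        assert 0.0 <= table["miou_mean"].iloc[0] <= 1.0
        assert table["miou_sd"].iloc[0] == 0.0

    def test_identical_configs_identical_rows(self, small_params):
        mc = ModelConfig(encoder="plain_unet", use_gcn=False, use_br=False,
                         base_channels=8, input_size=(64, 64))
        tcfg = TrainConfig(learning_rate=1e-3, batch_size=4, input_size=(64, 64),
                           epochs=1, seed=0)
        table = compare_configs([("a", mc), ("b", mc)], (small_params, 6, 3), tcfg)
        assert table["miou_mean"].iloc[0] == table["miou_mean"].iloc[1]
        assert table["pa_mean"].iloc[0] == table["pa_mean"].iloc[1]
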