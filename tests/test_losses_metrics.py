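"""Hybrid losses, deep supervision arithmetic, and the evaluation metric
suite against pixel-enumeration oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfda_unet import (MetricReport, confusion_counts, hd95, hybrid_loss,
                       deep_supervision_loss, predict_labels,
                       segmentation_metrics)
from mfda_unet import engine as eg
from mfda_unet.engine import Tensor
from mfda_unet.losses_metrics import (AUX_WEIGHTS, write_reports_csv,
                                      write_reports_json)
from mfda_unet.network import SegOutput


class TestHybridLoss:
    def test_perfect_prediction_limit(self):
        target = np.array([[[1, 1], [0, 0]]])
        logits = np.where(target[:, None].astype(bool), 50.0, -50.0)
        loss = hybrid_loss(logits, target, "bce_dice").item()
        assert loss < 0.06  # BCE -> 0; smoothed Dice residual only

    def test_zero_logits_bce_is_ln2(self):
        target = np.array([[[1, 0], [0, 1]]])
        logits = np.zeros((1, 1, 2, 2))
        loss = hybrid_loss(logits, target, "bce_dice").item()
        # pixel term: ln 2 exactly; dice term: 1 - (2*0.5*2+1)/(2+2+1) = 0.4
        want = 0.5 * math.log(2.0) + 0.5 * 0.4
        assert loss == pytest.approx(want, rel=1e-12)

    def test_soft_dice_hand_evaluated_toy(self):
        """p = (0.8, 0.6, 0.4, 0.2), g = (1, 1, 0, 0), s = 1:
        dice loss = 1 - (2*1.4 + 1)/(2 + 2 + 1) = 0.24."""
        p = np.array([0.8, 0.6, 0.4, 0.2]).reshape(1, 1, 2, 2)
        g = np.array([1, 1, 0, 0]).reshape(1, 1, 2, 2).astype(float)
        from mfda_unet.losses_metrics import soft_dice_loss
        loss = soft_dice_loss(Tensor(p), g).item()
        assert loss == pytest.approx(0.24, abs=1e-12)

    def test_multiclass_mode_and_label_validation(self):
        logits = np.zeros((1, 3, 2, 2))
        target = np.array([[[0, 1], [2, 0]]])
        assert hybrid_loss(logits, target, "ce_dice").item() > 0
        with pytest.raises(ValueError):
            hybrid_loss(logits, np.array([[[0, 3], [0, 0]]]), "ce_dice")
        with pytest.raises(ValueError):
            hybrid_loss(logits, target, "bce_dice")  # needs 1 channel
        with pytest.raises(ValueError):
            hybrid_loss(logits, target, "nope")


class TestDeepSupervision:
    def test_no_aux_equals_hybrid(self, rng):
        logits = rng.standard_normal((1, 1, 4, 4))
        target = (rng.random((1, 4, 4)) > 0.5).astype(int)
        out = SegOutput(main_logits=Tensor(logits), aux_logits=[])
        assert deep_supervision_loss(out, target, "bce_dice").item() == \
            pytest.approx(hybrid_loss(logits, target, "bce_dice").item())

    def test_aux_identical_to_main_scales_linearly(self, rng):
        logits = rng.standard_normal((1, 1, 4, 4))
        target = (rng.random((1, 4, 4)) > 0.5).astype(int)
        out = SegOutput(main_logits=Tensor(logits),
                        aux_logits=[Tensor(logits)] * 3)
        h = hybrid_loss(logits, target, "bce_dice").item()
        want = (1 + sum(AUX_WEIGHTS[:3])) * h
        assert deep_supervision_loss(out, target, "bce_dice").item() == \
            pytest.approx(want, rel=1e-12)

    def test_distinct_aux_weighted_sum(self, rng):
        target = (rng.random((1, 4, 4)) > 0.5).astype(int)
        mains = [rng.standard_normal((1, 1, 4, 4)) for _ in range(4)]
        out = SegOutput(main_logits=Tensor(mains[0]),
                        aux_logits=[Tensor(m) for m in mains[1:]])
        vals = [hybrid_loss(m, target, "bce_dice").item() for m in mains]
        want = vals[0] + sum(0.5 ** (k + 1) * v
                             for k, v in enumerate(vals[1:]))
        assert deep_supervision_loss(out, target, "bce_dice").item() == \
            pytest.approx(want, rel=1e-12)


class TestConfusionCounts:
    def test_perfect_and_inverted(self):
        t = np.array([[0, 1], [1, 0]])
        tp, fp, tn, fn = confusion_counts(t, t, 1)
        assert (fp, fn) == (0, 0) and tp + tn == 4
        tp, fp, tn, fn = confusion_counts(1 - t, t, 1)
        assert (tp, tn) == (0, 0)

    def test_matches_pixel_enumeration(self, rng):
        pred = rng.integers(0, 3, size=(4, 4))
        target = rng.integers(0, 3, size=(4, 4))
        for cls in range(3):
            tp = fp = tn = fn = 0
            for i in range(4):
                for j in range(4):
                    p, t = pred[i, j] == cls, target[i, j] == cls
                    tp += p and t
                    fp += p and not t
                    fn += t and not p
                    tn += (not p) and (not t)
            assert confusion_counts(pred, target, cls) == (tp, fp, tn, fn)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)), 0)


class TestSegmentationMetrics:
    def test_perfect_prediction_all_hundred(self, rng):
        t = rng.integers(0, 3, size=(8, 8))
        r = segmentation_metrics(t, t, 3)
        for v in r.mean.values():
            assert v == 100.0

    def test_all_background_prediction(self):
        target = np.zeros((4, 4), dtype=int)
        target[:2] = 1
        pred = np.zeros((4, 4), dtype=int)
        r = segmentation_metrics(pred, target, 2)
        assert r.per_class[1]["sen"] == 0.0
        assert r.per_class[1]["spe"] == 100.0
        assert r.per_class[1]["dsc"] == 0.0

    def test_closed_form_counts(self):
        """TP=45, FP=5, FN=5, TN=45: IoU = 45/55 ~ 81.8 %, DSC = 90 %."""
        target = np.zeros(100, dtype=int)
        target[:50] = 1
        pred = target.copy()
        pred[:5] = 0    # 5 false negatives
        pred[50:55] = 1  # 5 false positives
        r = segmentation_metrics(pred.reshape(10, 10),
                                 target.reshape(10, 10), 2)
        assert r.per_class[1]["iou"] == pytest.approx(100 * 45 / 55, abs=1e-9)
        assert r.per_class[1]["dsc"] == pytest.approx(90.0, abs=1e-9)
        assert r.per_class[1]["acc"] == pytest.approx(90.0, abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_dsc_iou_identity_exact_rational(self, seed):
        """DSC = 2 IoU / (1 + IoU) per class, checked in exact arithmetic."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        pred = rng.integers(0, k, size=(12, 12))
        target = rng.integers(0, k, size=(12, 12))
        for cls in range(k):
            tp, fp, tn, fn = confusion_counts(pred, target, cls)
            if tp + fp + fn == 0:
                continue
            iou = Fraction(tp, tp + fp + fn)
            dsc = Fraction(2 * tp, 2 * tp + fp + fn)
            assert dsc == 2 * iou / (1 + iou)

    def test_symmetry_of_dsc(self, rng):
        a = rng.integers(0, 2, size=(8, 8))
        b = rng.integers(0, 2, size=(8, 8))
        ra = segmentation_metrics(a, b, 2)
        rb = segmentation_metrics(b, a, 2)
        assert ra.per_class[1]["dsc"] == rb.per_class[1]["dsc"]

    def test_matches_enumeration_oracle_many_seeds(self):
        """Rates agree with direct formula evaluation on random maps."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(2, 4))
            shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
            pred = rng.integers(0, k, size=shape)
            target = rng.integers(0, k, size=shape)
            r = segmentation_metrics(pred, target, k)
            total = pred.size
            for cls in range(k):
                tp, fp, tn, fn = confusion_counts(pred, target, cls)
                if tp + fp + fn:
                    assert r.per_class[cls]["iou"] == \
                        pytest.approx(100 * tp / (tp + fp + fn))
                    assert r.per_class[cls]["dsc"] == \
                        pytest.approx(100 * 2 * tp / (2 * tp + fp + fn))
                assert r.per_class[cls]["acc"] == \
                    pytest.approx(100 * (tp + tn) / total)


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert hd95(m, m) == 0.0

    def test_single_pixels_offset_3_4(self):
        """Two single-pixel masks offset by (3, 4): distance exactly 5."""
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[1, 1] = True
        b[4, 5] = True
        assert hd95(a, b) == 5.0
        assert hd95(b, a) == 5.0  # symmetric

    def test_brute_force_oracle(self, rng):
        """95th percentile of pooled directed distances, all pairs."""
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        got = hd95(a, b)
        from mfda_unet.losses_metrics import _boundary
        pa, pb = np.argwhere(_boundary(a)), np.argwhere(_boundary(b))
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        pooled = np.concatenate([d.min(1), d.min(0)])
        assert got == pytest.approx(np.percentile(pooled, 95))

    def test_spacing_scales_distances(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[0, 3] = True
        assert hd95(a, b, spacing=(1.0, 2.0)) == 6.0

    def test_empty_mask_returns_nan_not_exception(self):
        m = np.zeros((4, 4), bool)
        full = np.ones((4, 4), bool)
        assert math.isnan(hd95(m, full))
        assert math.isnan(hd95(full, m))


class TestPredictionAndTraining:
    def test_predict_labels_conventions(self):
        binary = np.array([[[[0.2, -0.2]]]]).reshape(1, 1, 1, 2)
        np.testing.assert_array_equal(predict_labels(binary), [[[1, 0]]])
        multi = np.zeros((1, 3, 1, 1))
        multi[0, 2] = 5.0
        np.testing.assert_array_equal(predict_labels(multi), [[[2]]])

    def test_loss_decreases_under_gradient_descent(self, rng):
        """Monotone-trend property on a fixed random batch, 50 steps."""
        eg.manual_seed(9)
        layer = eg.Conv2d(1, 1, 3, padding=1)
        images = rng.random((2, 1, 8, 8))
        target = (rng.random((2, 8, 8)) > 0.5).astype(int)
        opt = eg.AdamW(layer.parameters(), lr=1e-2, weight_decay=0.0)
        losses = []
        for _ in range(50):
            loss = hybrid_loss(layer(Tensor(images)), target, "bce_dice")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < losses[0]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_report_serialization(self, tmp_path, rng):
        t = rng.integers(0, 2, size=(8, 8))
        reports = [segmentation_metrics(t, t, 2),
                   segmentation_metrics(1 - t, t, 2)]
        write_reports_csv(tmp_path / "m.csv", reports)
        write_reports_json(tmp_path / "m.json", reports)
        import csv as csvmod
        import json as jsonmod
        rows = list(csvmod.reader(open(tmp_path / "m.csv")))
        assert rows[0][0] == "case" and rows[-1][0] == "mean"
        payload = jsonmod.load(open(tmp_path / "m.json"))
        assert set(payload["mean"]) == {"miou", "dsc", "acc", "sen", "spe"}
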