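"""Hybrid segmentation losses, deep supervision, and evaluation metrics.

Training losses combine a pixel-wise term with a soft Dice term, weighted
0.5/0.5: binary tasks use BCE on sigmoid probabilities of a single-channel
logit map, multi-class tasks use CE on softmax probabilities.  Soft Dice is
smoothed with s = 1.0 in numerator and denominator:

    L_dice = 1 - (2 sum(p g) + s) / (sum(p) + sum(g) + s)

averaged over classes and batch.  With deep supervision, auxiliary
(pre-upsampled) logit maps enter with geometrically decaying weights
w_k = 2^-(k+1), k = 0 at the level nearest full resolution.

Evaluation metrics are the standard segmentation suite — per-class IoU,
Dice (DSC), accuracy, sensitivity, specificity (all %), plus the 95 %
Hausdorff boundary distance (HD95).  Conventions:

* predictions: sigmoid >= 0.5 for binary, channel argmax for multi-class;
* a class absent from both prediction and target scores 100 % IoU/DSC and
  is excluded from means;
* means run over foreground classes, except binary mIoU which averages
  foreground and background IoU;
* HD95 pools both directed boundary distance sets before taking the 95th
  percentile; an empty mask yields NaN (undefined, excluded upstream).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from . import engine as eg
from .engine import Tensor
from .network import SegOutput

PIXEL_WEIGHT = 0.5
DICE_WEIGHT = 0.5
DICE_SMOOTH = 1.0
AUX_WEIGHTS = tuple(2.0 ** -(k + 1) for k in range(8))


# ---------------------------------------------------------------------------
# losses (differentiable)
# ---------------------------------------------------------------------------

def _as_t(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on logits:
    mean(softplus(x) - x*g)."""
    g = np.asarray(target, dtype=float)
    return eg.tmean(eg.softplus(logits) - logits * g)


def softmax_probs(logits: Tensor, axis: int = 1) -> Tensor:
    shift = logits.data.max(axis=axis, keepdims=True)  # detached max shift
    e = eg.exp(logits - shift)
    return e / eg.tsum(e, axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Multi-class CE over channel axis 1; target (B, H, W) integer labels."""
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - shift
    lse = eg.log(eg.tsum(eg.exp(z), axis=1, keepdims=True))
    logp = z - lse
    B, K, H, W = logits.shape
    onehot = np.zeros((B, K, H, W))
    bb, hh, ww = np.meshgrid(np.arange(B), np.arange(H), np.arange(W),
                             indexing="ij")
    onehot[bb, target, hh, ww] = 1.0
    return -eg.tmean(eg.tsum(logp * onehot, axis=1))


def soft_dice_loss(probs: Tensor, target_onehot: np.ndarray,
                   smooth: float = DICE_SMOOTH) -> Tensor:
    """1 - smoothed Dice, averaged over batch and class axes.

    ``probs`` and ``target_onehot`` are (B, K, H, W); sums run over pixels.
    """
    inter = eg.tsum(probs * target_onehot, axis=(2, 3))
    denom = eg.tsum(probs, axis=(2, 3)) + target_onehot.sum(axis=(2, 3))
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return eg.tmean(1.0 - dice)


def _target_onehot(target: np.ndarray, num_classes: int) -> np.ndarray:
    B, H, W = target.shape
    onehot = np.zeros((B, num_classes, H, W))
    bb, hh, ww = np.meshgrid(np.arange(B), np.arange(H), np.arange(W),
                             indexing="ij")
    onehot[bb, target, hh, ww] = 1.0
    return onehot


def hybrid_loss(logits, target: np.ndarray, mode: str) -> Tensor:
    """0.5 * (BCE or CE) + 0.5 * soft Dice on one logit map.

    ``mode`` is 'bce_dice' (binary: logits (B, 1, H, W), target in {0, 1})
    or 'ce_dice' (multi-class: logits (B, K, H, W), K >= 2, integer target).
    """
    logits = _as_t(logits)
    target = np.asarray(target)
    if target.ndim == logits.ndim:  # allow (B,1,H,W) binary targets
        target = target[:, 0] if target.shape[1] == 1 else target
    K = logits.shape[1]
    if target.min() < 0 or target.max() >= max(K, 2):
        raise ValueError(
            f"target labels must lie in [0, {max(K, 2)}), got "
            f"[{target.min()}, {target.max()}]")
    if mode == "bce_dice":
        if K != 1:
            raise ValueError("bce_dice requires single-channel logits")
        pixel = bce_with_logits(logits, target[:, None])
        probs = eg.sigmoid(logits)
        dice = soft_dice_loss(probs, target[:, None].astype(float))
    elif mode == "ce_dice":
        if K < 2:
            raise ValueError("ce_dice requires num_classes >= 2 logits")
        pixel = cross_entropy(logits, target)
        dice = soft_dice_loss(softmax_probs(logits), _target_onehot(target, K))
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    return PIXEL_WEIGHT * pixel + DICE_WEIGHT * dice


def deep_supervision_loss(out: SegOutput, target: np.ndarray, mode: str) -> Tensor:
    """hybrid(main) + sum_k 2^-(k+1) * hybrid(aux_k); aux maps are already
    at full resolution, so they share the full-resolution target."""
    total = hybrid_loss(out.main_logits, target, mode)
    for k, aux in enumerate(out.aux_logits):
        total = total + AUX_WEIGHTS[k] * hybrid_loss(aux, target, mode)
    return total


# ---------------------------------------------------------------------------
# hard predictions and counting metrics
# ---------------------------------------------------------------------------

def predict_labels(logits) -> np.ndarray:
    """Binary: sigmoid >= 0.5 (i.e. logit >= 0); multi-class: argmax."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    if arr.shape[1] == 1:
        return (arr[:, 0] >= 0.0).astype(np.int64)
    return arr.argmax(axis=1).astype(np.int64)


def confusion_counts(pred: np.ndarray, target: np.ndarray,
                     cls: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, TN, FN) pixel counts for class ``cls``."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred == cls
    t = target == cls
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return tp, fp, tn, fn


@dataclass
class MetricReport:
    """Per-class and mean segmentation rates (all in %), plus HD95."""

    per_class: dict[int, dict[str, float]]
    mean: dict[str, float]
    hd95: float = float("nan")

    def to_dict(self) -> dict:
        return {"per_class": {str(k): v for k, v in self.per_class.items()},
                "mean": self.mean, "hd95": self.hd95}


def _rate(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else 100.0


def segmentation_metrics(pred: np.ndarray, target: np.ndarray,
                         num_classes: int, spacing=(1.0, 1.0),
                         compute_hd95: bool = False) -> MetricReport:
    """Compute the metric suite from hard label maps (H, W) or (B, H, W)."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    total = pred.size
    per_class: dict[int, dict[str, float]] = {}
    absent: set[int] = set()
    for c in range(num_classes):
        tp, fp, tn, fn = confusion_counts(pred, target, c)
        if tp + fp + fn == 0:
            absent.add(c)
        per_class[c] = {
            "iou": _rate(tp, tp + fp + fn),
            "dsc": _rate(2 * tp, 2 * tp + fp + fn),
            "acc": _rate(tp + tn, total),
            "sen": _rate(tp, tp + fn),
            "spe": _rate(tn, tn + fp),
        }
    fg = [c for c in range(1, num_classes) if c not in absent]
    if not fg:
        fg_vals = {m: 100.0 for m in ("dsc", "acc", "sen", "spe")}
        fg_iou = 100.0
    else:
        fg_vals = {m: float(np.mean([per_class[c][m] for c in fg]))
                   for m in ("dsc", "acc", "sen", "spe")}
        fg_iou = float(np.mean([per_class[c]["iou"] for c in fg]))
    if num_classes == 2:
        # binary convention: mIoU averages foreground and background IoU
        miou = float(np.mean([per_class[0]["iou"], per_class[1]["iou"]]))
    else:
        miou = fg_iou
    mean = {"miou": miou, "dsc": fg_vals["dsc"], "acc": fg_vals["acc"],
            "sen": fg_vals["sen"], "spe": fg_vals["spe"]}
    report = MetricReport(per_class=per_class, mean=mean)
    if compute_hd95 and num_classes == 2 and pred.ndim == 2:
        report.hd95 = hd95(pred == 1, target == 1, spacing)
    return report


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

_CROSS = generate_binary_structure(2, 1)  # 4-connectivity


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 4-adjacent to non-mask (image border counts as outside)."""
    return mask & ~binary_erosion(mask, structure=_CROSS, border_value=0)


def hd95(pred_mask: np.ndarray, target_mask: np.ndarray,
         spacing=(1.0, 1.0)) -> float:
    """Symmetric 95th-percentile boundary distance, scaled by ``spacing``.

    Returns NaN (the undefined marker) if either mask is empty; callers
    exclude such cases from averages.
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    if pred_mask.shape != target_mask.shape:
        raise ValueError(
            f"shape mismatch: {pred_mask.shape} vs {target_mask.shape}")
    if not pred_mask.any() or not target_mask.any():
        return float("nan")
    sp = np.asarray(spacing, dtype=float)
    pb = np.argwhere(_boundary(pred_mask)) * sp
    tb = np.argwhere(_boundary(target_mask)) * sp
    d_pt, _ = cKDTree(tb).query(pb)
    d_tp, _ = cKDTree(pb).query(tb)
    return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

_COLS = ("miou", "dsc", "acc", "sen", "spe")


def write_reports_csv(path, reports: list[MetricReport],
                      case_ids: list[str] | None = None) -> None:
    """One row per case plus a final mean row (NaN-aware for HD95)."""
    case_ids = case_ids or [f"case_{i:04d}" for i in range(len(reports))]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case"] + [c.upper() for c in _COLS] + ["HD95"])
        for cid, r in zip(case_ids, reports):
            w.writerow([cid] + [f"{r.mean[c]:.4f}" for c in _COLS]
                       + [f"{r.hd95:.4f}"])
        means = {c: float(np.mean([r.mean[c] for r in reports])) for c in _COLS}
        hds = [r.hd95 for r in reports if np.isfinite(r.hd95)]
        hd = float(np.mean(hds)) if hds else float("nan")
        w.writerow(["mean"] + [f"{means[c]:.4f}" for c in _COLS] + [f"{hd:.4f}"])


def write_reports_json(path, reports: list[MetricReport],
                       case_ids: list[str] | None = None) -> None:
    case_ids = case_ids or [f"case_{i:04d}" for i in range(len(reports))]
    means = {c: float(np.mean([r.mean[c] for r in reports])) for c in _COLS}
    hds = [r.hd95 for r in reports if np.isfinite(r.hd95)]
    payload = {
        "cases": {cid: r.to_dict() for cid, r in zip(case_ids, reports)},
        "mean": means,
        "hd95_mean": float(np.mean(hds)) if hds else None,
        "hd95_undefined_cases": [cid for cid, r in zip(case_ids, reports)
                                 if not np.isfinite(r.hd95)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
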