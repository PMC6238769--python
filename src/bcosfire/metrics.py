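"""Pixel-wise evaluation against ground truth.

Confusion counts are accumulated over the field of view when a FOV mask is
supplied (standard practice for fundus images: pixels outside the camera
aperture carry no information).  Derived metrics:

    Se  = TP / (TP + FN)        sensitivity (recall on vessel pixels)
    Sp  = TN / (TN + FP)        specificity (recall on background)
    Acc = (TP + TN) / total     pixel accuracy
    AUC                         area under the ROC curve of the raw response

Zero-denominator metrics are flagged as undefined (``None``), never silent
NaN.  Dataset-level results sum counts over images before deriving metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts with derived metrics; undefined metrics are None."""

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    auc: float | None = None


def _as_bool(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    return arr > 0 if arr.dtype != np.bool_ else arr


def confusion(
    pred: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted mask against ground truth."""
    pred_b = _as_bool(pred, "pred")
    gt_b = _as_bool(gt, "gt")
    if pred_b.shape != gt_b.shape:
        raise ValueError(f"shape mismatch: pred {pred_b.shape} vs gt {gt_b.shape}")
    if fov is not None:
        fov_b = _as_bool(fov, "fov")
        if fov_b.shape != gt_b.shape:
            raise ValueError(f"shape mismatch: fov {fov_b.shape} vs gt {gt_b.shape}")
        pred_b, gt_b = pred_b[fov_b], gt_b[fov_b]
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred_b & gt_b)),
        fp=int(np.count_nonzero(pred_b & ~gt_b)),
        tn=int(np.count_nonzero(~pred_b & ~gt_b)),
        fn=int(np.count_nonzero(~pred_b & gt_b)),
    )


def derive_metrics(counts: ConfusionCounts, auc: float | None = None) -> EvaluationResult:
    """Sensitivity, specificity, and accuracy from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot derive metrics from zero evaluated pixels")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    return EvaluationResult(
        counts=counts,
        sensitivity=counts.tp / pos if pos else None,
        specificity=counts.tn / neg if neg else None,
        accuracy=(counts.tp + counts.tn) / counts.total,
        auc=auc,
    )


def auc(
    response: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None
) -> float:
    """Area under the ROC curve of a continuous response against ground truth.

    Equals the probability that a random vessel pixel outranks a random
    background pixel, with ties counting one half.
    """
    resp = np.asarray(response, dtype=np.float64)
    gt_b = _as_bool(gt, "gt")
    if resp.shape != gt_b.shape:
        raise ValueError(f"shape mismatch: response {resp.shape} vs gt {gt_b.shape}")
    if fov is not None:
        fov_b = _as_bool(fov, "fov")
        resp, gt_b = resp[fov_b], gt_b[fov_b]
    labels = gt_b.ravel()
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both vessel and background pixels in the FOV")
    return float(roc_auc_score(labels, resp.ravel()))


def evaluate_mask(
    pred: np.ndarray,
    gt: np.ndarray,
    fov: np.ndarray | None = None,
    response: np.ndarray | None = None,
) -> EvaluationResult:
    """Convenience wrapper: confusion counts plus metrics (and AUC if given)."""
    counts = confusion(pred, gt, fov)
    auc_value = auc(response, gt, fov) if response is not None else None
    return derive_metrics(counts, auc=auc_value)
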