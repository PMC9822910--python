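"""Counting-accuracy metrics: mean counting error and RMSE.

For R evaluation images with ground-truth counts C_gt and predicted counts
C_pred:

    MCE  = (1/R) * sum_i |C_gt_i - C_pred_i|
    RMSE = sqrt((1/R) * sum_i (C_gt_i - C_pred_i)**2)

Predicted counts enter un-rounded; RMSE >= MCE always, with equality iff
every absolute error is the same.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvaluationBatch", "mce", "rmse", "evaluate_model"]


@dataclass(frozen=True)
class EvaluationBatch:
    """Paired ground-truth and predicted counts for a batch of images."""

    ground_truth: tuple[float, ...]
    predicted: tuple[float, ...]

    def __post_init__(self) -> None:
        gt = np.asarray(self.ground_truth, dtype=float)
        pred = np.asarray(self.predicted, dtype=float)
        if gt.size == 0:
            raise ValueError("evaluation batch must contain at least one pair")
        if gt.shape != pred.shape:
            raise ValueError("ground truth and predictions must pair one-to-one")
        if (gt < 0).any():
            raise ValueError("ground-truth counts must be non-negative")

    @classmethod
    def from_pairs(cls, pairs) -> "EvaluationBatch":
        gt, pred = zip(*pairs)
        return cls(tuple(float(g) for g in gt), tuple(float(p) for p in pred))

    def errors(self) -> np.ndarray:
        return np.asarray(self.ground_truth, dtype=float) - np.asarray(
            self.predicted, dtype=float
        )


def mce(batch: EvaluationBatch) -> float:
    """Mean absolute counting error over the batch."""
    return float(np.abs(batch.errors()).mean())


def rmse(batch: EvaluationBatch) -> float:
    """Root mean squared counting error over the batch."""
    return float(np.sqrt((batch.errors() ** 2).mean()))


def evaluate_model(model, scenes) -> tuple[float, float]:
    """Run a counting model over annotated scenes; return (MCE, RMSE).

    ``model`` needs a ``predict_count(image) -> float`` method (the MFCNN
    provides it; any callable oracle wrapped accordingly works too).
    """
    if not scenes:
        raise ValueError("need at least one scene to evaluate")
    pairs = [(scene.count, model.predict_count(scene.image)) for scene in scenes]
    batch = EvaluationBatch.from_pairs(pairs)
    return mce(batch), rmse(batch)
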