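"""Registration quality metrics: point RMSE, image RMSE, correspondence
recall/precision/F1 and recall-accuracy curves."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsReport",
    "rmse_points",
    "rmse_images",
    "score_correspondences",
    "precision_recall_f1",
    "recall_accuracy_curve",
]


@dataclass
class MetricsReport:
    rmse_points: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    recall: float = 0.0
    precision: float = 0.0
    f1: float = 0.0
    rmse_image: float | None = None
    recall_accuracy: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rmse_points": self.rmse_points,
            "rmse_image": self.rmse_image,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "recall_accuracy": [list(p) for p in self.recall_accuracy],
        }


def _pair_distances(
    aligned: np.ndarray, truth_pairs, scene: np.ndarray
) -> np.ndarray:
    pairs = np.asarray([(s, m) for s, m in truth_pairs], dtype=int)
    return np.linalg.norm(scene[pairs[:, 0]] - aligned[pairs[:, 1]], axis=1)


def rmse_points(aligned: np.ndarray, truth_pairs, scene: np.ndarray) -> float:
    """Root mean square Euclidean distance over the ground-truth pairs.

    ``sqrt((1/J) sum_j ||x_j - y_j||^2)`` where y_j is the aligned model
    point paired with scene point x_j.
    """
    if len(truth_pairs) == 0:
        raise ValueError("truth_pairs must be non-empty")
    d = _pair_distances(np.asarray(aligned, float), truth_pairs, np.asarray(scene, float))
    return float(np.sqrt((d**2).mean()))


def rmse_images(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """RMSE between two intensity grids of identical shape."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).mean()))


def score_correspondences(
    predicted_pairs,
    truth_pairs,
    aligned: np.ndarray,
    scene: np.ndarray,
    threshold: float,
) -> tuple[int, int, int]:
    """Count true positives, false positives and false negatives.

    A truth pair is a true positive when its aligned-to-scene distance is
    within ``threshold``, a false negative otherwise.  A predicted pair not
    present in the truth set counts as a false positive (predictions may
    carry a trailing posterior, which is ignored).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = _pair_distances(np.asarray(aligned, float), truth_pairs, np.asarray(scene, float))
    tp = int((d <= threshold).sum())
    fn = len(truth_pairs) - tp
    truth_set = {(int(s), int(m)) for s, m in truth_pairs}
    fp = sum(1 for p in predicted_pairs if (int(p[0]), int(p[1])) not in truth_set)
    return tp, fp, fn


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """recall = tp/(tp+fn), precision = tp/(tp+fp), f1 = 2tp/(2tp+fp+fn).

    Undefined ratios (zero denominators) are reported as 0 with a warning.
    """
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("recall undefined (no ground-truth pairs); reporting 0", stacklevel=2)
        recall = 0.0
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("precision undefined (no predictions); reporting 0", stacklevel=2)
        precision = 0.0
    f1 = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return recall, precision, f1


def recall_accuracy_curve(
    aligned: np.ndarray,
    truth_pairs,
    scene: np.ndarray,
    thresholds,
    predicted_pairs=None,
) -> list[tuple[float, float]]:
    """Recall of ground-truth correspondences within each distance threshold.

    Distances are evaluated on the ground-truth pairing by default; pass
    ``predicted_pairs`` to restrict recall to truth pairs the method also
    predicted (stricter variant).  The curve is non-decreasing in the
    threshold.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    pairs = list(truth_pairs)
    if predicted_pairs is not None:
        pred = {(int(p[0]), int(p[1])) for p in predicted_pairs}
        pairs = [p for p in pairs if (int(p[0]), int(p[1])) in pred]
    j = len(truth_pairs)
    if not pairs:
        return [(float(t), 0.0) for t in thresholds]
    d = _pair_distances(np.asarray(aligned, float), pairs, np.asarray(scene, float))
    return [(float(t), float((d <= t).sum() / j)) for t in thresholds]
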