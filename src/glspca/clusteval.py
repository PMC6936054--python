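"""K-means clustering of the learned embedding and best-mapping accuracy.

Cluster labels are arbitrary, so comparing a predicted partition to truth
requires the label bijection that maximizes agreement.  That is a linear
assignment problem on the confusion matrix (Hungarian algorithm), which
gives the exact optimum; accuracy (ACC) is the matched fraction in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = ["ClusterEvaluation", "cluster_samples", "clustering_accuracy"]


@dataclass(frozen=True)
class ClusterEvaluation:
    """Predicted vs. truth labels with the optimal label mapping and ACC."""

    predicted: np.ndarray
    truth: np.ndarray
    mapping: dict[int, int]  # predicted label -> truth label
    acc: float
    confusion: np.ndarray  # truth x predicted counts

    @property
    def n_samples(self) -> int:
        return self.predicted.shape[0]


def cluster_samples(
    H: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    restarts: int = 50,
) -> np.ndarray:
    """K-means labels for the rows of the embedding H.

    Uses k-means++ initialization with ``restarts`` independent starts;
    deterministic for a fixed seed.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValueError("H must be 2-D (samples x components)")
    n = H.shape[0]
    if not 2 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [2, {n}], got {n_clusters}")
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=restarts,
        random_state=seed,
    )
    return km.fit_predict(H)


def clustering_accuracy(predicted: np.ndarray, truth: np.ndarray) -> ClusterEvaluation:
    """ACC under the best bijective mapping of predicted to truth labels.

    ACC = 100 * max_map sum_i 1[p_i == map(q_i)] / n, with the maximum
    over label bijections solved exactly by linear assignment on the
    confusion matrix (padded square when the two sides use different
    numbers of classes).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D of equal length, got "
            f"{predicted.shape} and {truth.shape}"
        )
    n = predicted.shape[0]
    if n == 0:
        raise ValueError("empty label vectors")
    pred_classes, pred_codes = np.unique(predicted, return_inverse=True)
    true_classes, true_codes = np.unique(truth, return_inverse=True)
    size = max(len(pred_classes), len(true_classes))
    confusion = np.zeros((size, size), dtype=int)
    np.add.at(confusion, (true_codes, pred_codes), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    matched = int(confusion[rows, cols].sum())
    mapping = {
        int(pred_classes[c]): int(true_classes[r])
        for r, c in zip(rows, cols)
        if c < len(pred_classes) and r < len(true_classes)
    }
    return ClusterEvaluation(
        predicted=predicted,
        truth=truth,
        mapping=mapping,
        acc=100.0 * matched / n,
        confusion=confusion[: len(true_classes), : len(pred_classes)],
    )
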