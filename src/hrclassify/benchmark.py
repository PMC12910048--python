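"""Evaluation metrics and comparison classifiers.

Besides the confusion-matrix metrics and rank-based AUC used to evaluate
the elastic-net model, three simpler transcriptomic HR classifiers are
provided for benchmarking: a two-means clustering of a gene signature
(clusters labelled by marker-gene expression, low = deficient), a
centroid-correlation rule (positive Pearson correlation with a deficient
centroid calls HRD), and a plain score threshold with an optional
exhaustive cutoff search.  Partition agreement is summarized by the
adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .exceptions import DegenerateLabelsError, UndefinedAUCError, UndefinedCorrelationError


@dataclass
class BenchmarkReport:
    """Confusion-matrix summary with HRD as the positive class."""

    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float  # NaN when no positive predictions
    recall: float
    misclassification: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "misclassification": self.misclassification,
            "auc": self.auc,
        }


@dataclass
class SignatureCentroids:
    """Class-mean expression vectors on the z-score scale."""

    gene_ids: list[str]
    hrd_centroid: np.ndarray
    hrp_centroid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hrd_centroid = np.asarray(self.hrd_centroid, float)
        if self.hrd_centroid.shape != (len(self.gene_ids),):
            raise ValueError("centroid length must equal gene list length")


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray) -> BenchmarkReport:
    """Accuracy, precision, recall and misclassification (1 = HRD = positive)."""
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    n = len(truth)
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    return BenchmarkReport(
        n=n,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        misclassification=1.0 - accuracy,
    )


def auc_score(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_HRD > score_HRP) with half-credit for ties."""
    truth = np.asarray(truth).astype(int)
    if np.unique(truth).size < 2:
        raise UndefinedAUCError("AUC undefined with a single class")
    return float(roc_auc_score(truth, np.asarray(scores, float)))


def kmeans_signature_classify(
    z: pd.DataFrame,
    signature: list[str],
    marker_genes: list[str],
    *,
    seed: int = 0,
    n_init: int = 25,
) -> np.ndarray:
    """Two-means clustering of a z-scored signature; low marker expression = HRD.

    ``z`` is genes x samples.  Clustering runs ``n_init`` random restarts
    keeping the lowest within-cluster sum of squares; the cluster whose
    centroid has the lower mean over ``marker_genes`` is labelled HRD.
    On an exact marker-mean tie, the first cluster is labelled HRP.
    """
    if not set(marker_genes) <= set(signature):
        raise ValueError("marker genes must be a subset of the signature")
    zs = z.reindex(signature).dropna(how="any")
    if zs.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    X = zs.to_numpy(float).T  # samples x genes
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(X)
    marker_idx = [zs.index.get_loc(g) for g in marker_genes if g in zs.index]
    marker_means = km.cluster_centers_[:, marker_idx].mean(axis=1)
    if marker_means[0] == marker_means[1]:
        hrd_cluster = 1  # tie: first cluster deemed HRP
    else:
        hrd_cluster = int(np.argmin(marker_means))
    return (km.labels_ == hrd_cluster).astype(int)


def centroid_correlation_classify(
    z: pd.DataFrame, centroids: SignatureCentroids
) -> np.ndarray:
    """Sign of Pearson correlation with the HRD centroid: r > 0 -> HRD, r <= 0 -> HRP."""
    zs = z.reindex(centroids.gene_ids).to_numpy(float)
    c = centroids.hrd_centroid
    if np.ptp(c) == 0:
        raise UndefinedCorrelationError("constant centroid")
    out = np.empty(zs.shape[1], dtype=int)
    c_cent = c - c.mean()
    for j in range(zs.shape[1]):
        v = zs[:, j]
        if np.ptp(v) == 0:
            raise UndefinedCorrelationError(f"constant sample vector at column {j}")
        r = float((v - v.mean()) @ c_cent)
        out[j] = 1 if r > 0 else 0
    return out


def score_threshold_classify(scores: np.ndarray, cutoff: float = 42.0) -> np.ndarray:
    """Score >= cutoff calls HRD (clinical genomic-scar convention)."""
    return (np.asarray(scores, float) >= cutoff).astype(int)


def optimize_score_threshold(
    scores: np.ndarray, truth: np.ndarray, grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Exhaustive integer-cutoff search maximizing accuracy (smallest winner)."""
    truth = np.asarray(truth).astype(int)
    if np.unique(truth).size < 2:
        raise DegenerateLabelsError("cutoff optimization needs both classes")
    if grid is None:
        grid = np.arange(1, 115)
    scores = np.asarray(scores, float)
    best_c, best_acc = float(grid[0]), -1.0
    for c in grid:
        acc = float(np.mean((scores >= c).astype(int) == truth))
        if acc > best_acc + 1e-12:
            best_c, best_acc = float(c), acc
    return best_c, best_acc


def adjusted_rand_index(partition_a: np.ndarray, partition_b: np.ndarray) -> float:
    """Pair-counting ARI with the permutation-model expected-index correction."""
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("partitions must share >= 2 samples")
    return float(adjusted_rand_score(a, b))
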