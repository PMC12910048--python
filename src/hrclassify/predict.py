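"""Scoring new samples with a persisted model bundle.

The prediction contract is deliberately per-sample: counts are subset to
the signature genes (absent genes zero-filled and reported), the library
size is recomputed over the signature genes only, log2-CPM uses a prior
count of 0.5 with norm factor 1 (no TMM against a reference cohort), and
z-scaling reuses the training statistics stored in the bundle.  The raw
linear-model probability is P(HRP); the reported probability of
deficiency is its complement, and P(HRD) >= threshold classifies HRD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateLabelsError
from .io import CountMatrix, ModelBundle
from .preprocess import StandardizationStats, apply_standardizer, log2_cpm, subset_with_zero_fill


@dataclass
class PredictionResult:
    """Per-sample probabilities and discrete calls."""

    sample_ids: list[str]
    p_hrd: np.ndarray
    p_hrp: np.ndarray
    status: np.ndarray  # 1 = HRD, 0 = HRP
    threshold_used: float
    missing_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "p_hrd": self.p_hrd,
                "p_hrp": self.p_hrp,
                "status": np.where(self.status == 1, "HRD", "HRP"),
                "threshold": self.threshold_used,
                "n_missing_genes": len(self.missing_genes),
            }
        )


def preprocess_for_prediction(
    counts: CountMatrix, bundle: ModelBundle, *, max_missing_fraction: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Subset/zero-fill, subset-library log2-CPM, stored-statistics z-scaling."""
    subset, missing = subset_with_zero_fill(
        counts, bundle.signature_gene_ids, max_missing_fraction=max_missing_fraction
    )
    norm = log2_cpm(subset, prior_count=0.5)  # library = sum over signature genes only
    stats = StandardizationStats(list(bundle.signature_gene_ids), bundle.gene_means, bundle.gene_sds)
    return apply_standardizer(norm, stats), missing


def predict_probability(
    z: pd.DataFrame, bundle: ModelBundle, *, missing_genes: list[str] | None = None
) -> PredictionResult:
    """Logistic scoring with probability inversion (P(HRD) = 1 - P(HRP))."""
    zmat = z.reindex(bundle.signature_gene_ids).to_numpy(float)
    if not np.isfinite(zmat).all():
        raise ValueError("z-score matrix contains non-finite or missing values")
    eta = bundle.intercept + bundle.coefficients @ zmat
    p_hrp = 1.0 / (1.0 + np.exp(-eta))
    p_hrd = 1.0 - p_hrp
    status = (p_hrd >= bundle.threshold).astype(int)
    return PredictionResult(
        sample_ids=[str(c) for c in z.columns],
        p_hrd=p_hrd,
        p_hrp=p_hrp,
        status=status,
        threshold_used=bundle.threshold,
        missing_genes=list(missing_genes or []),
    )


def classify(result: PredictionResult, threshold: float = 0.5) -> PredictionResult:
    """Re-threshold an existing prediction: status = HRD iff P(HRD) >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return PredictionResult(
        sample_ids=result.sample_ids,
        p_hrd=result.p_hrd,
        p_hrp=result.p_hrp,
        status=(result.p_hrd >= threshold).astype(int),
        threshold_used=threshold,
        missing_genes=result.missing_genes,
    )


def predict_samples(
    counts: CountMatrix,
    bundle: ModelBundle,
    *,
    threshold: float | None = None,
    max_missing_fraction: float = 0.5,
) -> PredictionResult:
    """End-to-end scoring of a count matrix with a model bundle."""
    z, missing = preprocess_for_prediction(
        counts, bundle, max_missing_fraction=max_missing_fraction
    )
    result = predict_probability(z, bundle, missing_genes=missing)
    if threshold is not None:
        result = classify(result, threshold)
    return result


def optimize_probability_threshold(
    p_hrd: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Grid-search the HRD probability cutoff maximizing accuracy.

    Thresholds 0.00 to 1.00 in steps of 0.01; among maximizers the
    smallest threshold is returned together with its accuracy.
    """
    p_hrd = np.asarray(p_hrd, float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise DegenerateLabelsError("threshold optimization needs both classes")
    grid = np.round(np.arange(0, 101) / 100.0, 2)
    best_t, best_acc = 0.0, -1.0
    for t in grid:
        acc = float(np.mean((p_hrd >= t).astype(int) == labels))
        if acc > best_acc + 1e-12:
            best_t, best_acc = float(t), acc
    return best_t, best_acc
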