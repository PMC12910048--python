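"""End-to-end orchestration: counts + labels -> trained model bundle.

Mirrors the training recipe stage by stage: coding/chromosome filter,
CPM expression filter, TMM factors, moderated differential expression,
signature selection, subset-library log2-CPM, z-scaling with persisted
statistics, cross-validated elastic-net fitting with one-SE selection,
and a final full-cohort fit exported as a model bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffexp, preprocess
from .io import CountMatrix, ModelBundle
from .train import (
    CVGrid,
    TrainingConfig,
    cross_validate_alpha_grid,
    select_alpha_one_se,
    train_final_model,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingResult:
    """Everything the training pipeline produces."""

    bundle: ModelBundle
    cv_grid: CVGrid
    de_table: pd.DataFrame
    signature: list[str]
    alpha: float
    lambda_: float
    filter_report: dict


def standardized_signature_matrix(
    counts: CountMatrix, signature: list[str]
) -> tuple[np.ndarray, preprocess.StandardizationStats]:
    """Subset-library log2-CPM of the signature genes, z-scaled; returns (X, stats).

    X is samples x genes, ready for the penalized regression.  The
    library size is the per-sample sum over the signature genes only and
    no TMM factor is applied — identical to the prediction-time contract
    so stored statistics transfer exactly.
    """
    subset, _ = preprocess.subset_with_zero_fill(counts, signature)
    norm = preprocess.log2_cpm(subset, prior_count=0.5)
    stats = preprocess.fit_standardizer(norm)
    z = preprocess.apply_standardizer(norm, stats)
    return z.to_numpy(float).T, stats


def train_pipeline(
    counts: CountMatrix,
    hr_status: np.ndarray,
    annotation: pd.DataFrame,
    config: TrainingConfig | None = None,
    *,
    cpm_threshold: float = 10.0,
    min_prop: float = 0.7,
    alpha_fdr: float = 0.05,
) -> TrainingResult:
    """Run the full training recipe and return the fitted bundle with diagnostics."""
    config = config or TrainingConfig()
    hr_status = np.asarray(hr_status).astype(int)

    coding, report = preprocess.remove_excluded_genes(counts, annotation)
    logger.info("coding/chromosome filter: %s", report)

    n_hrd = int(hr_status.sum())
    group_sizes = (n_hrd, len(hr_status) - n_hrd)
    kept = preprocess.filter_low_expression(
        coding, group_sizes, cpm_threshold=cpm_threshold, min_prop=min_prop
    )
    filtered = coding.subset_genes(kept)
    logger.info("expression filter retained %d of %d genes", len(kept), coding.n_genes)

    norm_factors = preprocess.tmm_norm_factors(filtered)
    de_table = diffexp.run_differential_expression(filtered, hr_status, norm_factors)
    selected = diffexp.select_de_genes(de_table, alpha_fdr=alpha_fdr)
    signature = selected["gene_id"].tolist()
    logger.info(
        "signature: %d genes (%d up, %d down in HRD)",
        len(signature),
        int((selected["direction"] == "up").sum()),
        int((selected["direction"] == "down").sum()),
    )

    X, stats = standardized_signature_matrix(counts, signature)
    y_hrp = 1 - hr_status  # internal coding: raw probability is P(HRP)
    grid = cross_validate_alpha_grid(X, y_hrp, config)
    alpha, lam = select_alpha_one_se(grid, reference=config.one_se_reference)
    logger.info("one-SE selection: alpha=%.2f lambda=%.5g", alpha, lam)

    bundle = train_final_model(X, hr_status, alpha, lam, stats, signature, config)
    report.update(
        {"low_expression_removed": coding.n_genes - len(kept), "signature_size": len(signature)}
    )
    return TrainingResult(
        bundle=bundle,
        cv_grid=grid,
        de_table=de_table,
        signature=signature,
        alpha=alpha,
        lambda_=lam,
        filter_report=report,
    )
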