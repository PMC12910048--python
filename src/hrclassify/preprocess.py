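"""Count filtering, normalization and standardization.

The preprocessing contract has two distinct regimes:

* **Training**: protein-coding autosomal/X genes are kept, lowly expressed
  genes are filtered on CPM, TMM factors correct composition bias, and
  log2-CPM values are z-scaled per gene with statistics that are *stored*
  for later use.
* **Prediction**: counts are subset to the signature genes (absent genes
  zero-filled), the library size is the column sum over signature genes
  only, no TMM reference is used (norm factor 1), and z-scaling reuses the
  stored training statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import (
    DegenerateLibraryError,
    EmptyAfterFilterError,
    ExcessiveMissingnessError,
    MissingStatisticsError,
    UnmappedCellError,
    ZeroVarianceError,
)
from .io import CountMatrix

EXCLUDED_CHROMOSOMES = ("M", "MT", "Y")


@dataclass(frozen=True)
class TMMParams:
    """Trimmed-mean-of-M-values settings (canonical doubly trimmed weighted mean)."""

    logratio_trim: float = 0.30
    abs_expr_trim: float = 0.05

    def __post_init__(self) -> None:
        for t in (self.logratio_trim, self.abs_expr_trim):
            if not 0.0 <= t < 0.5:
                raise ValueError("TMM trims must lie in [0, 0.5)")


@dataclass
class NormalizedMatrix:
    """log2-CPM gene-by-sample matrix with the normalization it was built from."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    lib_sizes: np.ndarray
    norm_factors: np.ndarray
    prior_count: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class StandardizationStats:
    """Per-gene log2-CPM mean and sample SD (n-1 denominator) from training."""

    gene_ids: list[str]
    means: np.ndarray
    sds: np.ndarray


def remove_excluded_genes(
    counts: CountMatrix, annotation: pd.DataFrame
) -> tuple[CountMatrix, dict[str, int]]:
    """Drop non-coding genes and genes on mitochondrial or Y chromosomes.

    ``annotation`` is a GeneAnnotation table (gene_id, chromosome, biotype).
    Unannotated genes are removed and counted separately in the report.
    Returns the filtered matrix and a removal report by reason.
    """
    ann = annotation.set_index("gene_id")
    report = {"non_coding": 0, "chrM_or_chrY": 0, "unannotated": 0, "retained": 0}
    keep: list[int] = []
    for i, g in enumerate(counts.gene_ids):
        if g not in ann.index:
            report["unannotated"] += 1
            continue
        row = ann.loc[g]
        if str(row["chromosome"]).upper() in EXCLUDED_CHROMOSOMES:
            report["chrM_or_chrY"] += 1
        elif str(row["biotype"]) != "protein_coding":
            report["non_coding"] += 1
        else:
            keep.append(i)
    report["retained"] = len(keep)
    if not keep:
        raise EmptyAfterFilterError("no genes remain after coding/chromosome filter")
    out = CountMatrix(
        [counts.gene_ids[i] for i in keep], list(counts.sample_ids), counts.counts[keep]
    )
    return out, report


def filter_low_expression(
    counts: CountMatrix,
    group_sizes: Sequence[int],
    cpm_threshold: float = 10.0,
    min_prop: float = 0.7,
) -> list[str]:
    """Retain genes expressed above ``cpm_threshold`` CPM in enough samples.

    A gene is kept iff the number of samples with CPM >= threshold is at
    least ``ceil(min_prop * min(group_sizes))``.  CPM uses raw library
    sizes — no TMM factors, no prior count.
    """
    if len(group_sizes) < 2 or min(group_sizes) < 1:
        raise ValueError("need at least two groups with >= 1 sample each")
    lib = counts.library_sizes()
    if (lib == 0).any():
        raise DegenerateLibraryError("sample with zero total counts")
    cpm = counts.counts / lib * 1e6
    needed = math.ceil(min_prop * min(group_sizes))
    kept_mask = (cpm >= cpm_threshold).sum(axis=1) >= needed
    kept = [g for g, k in zip(counts.gene_ids, kept_mask) if k]
    if not kept:
        raise EmptyAfterFilterError("expression filter removed every gene")
    return kept


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float, params: TMMParams
) -> float:
    """Doubly trimmed weighted mean of M-values for one sample against the reference."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return 1.0
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    log_r = np.log2((o / n_obs) / (r / n_ref))
    abs_e = 0.5 * (np.log2(o / n_obs) + np.log2(r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * params.logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * params.abs_expr_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_r)
    rank_s = rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * log_r[keep]) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return 2.0 ** f


def tmm_norm_factors(counts: CountMatrix, params: TMMParams | None = None) -> np.ndarray:
    """TMM normalization factors, rescaled to have geometric mean 1.

    The reference library is the sample whose upper-quartile CPM is closest
    to the mean upper-quartile; each other library's factor is the doubly
    trimmed (M by ``logratio_trim``, A by ``abs_expr_trim``) precision-
    weighted mean of M-values against that reference.
    """
    params = params or TMMParams()
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.library_sizes()
    if (lib == 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l == 0]
        raise DegenerateLibraryError(f"all-zero libraries: {bad[:5]}")
    q75 = np.quantile(counts.counts / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts.counts[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair_factor(counts.counts[:, j], ref, lib[j], lib[ref_idx], params)
            for j in range(counts.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log2_cpm(
    counts: CountMatrix | np.ndarray,
    lib_sizes: np.ndarray | None = None,
    norm_factors: np.ndarray | None = None,
    prior_count: float = 0.5,
    *,
    gene_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> NormalizedMatrix:
    """log2 counts-per-million with a prior count.

    value = log2( (count + prior) / (lib * norm_factor + 2 * prior) * 1e6 )

    The doubled prior in the denominator keeps the transform finite at
    zero counts and depth-invariant when prior is 0 and counts positive.
    """
    if isinstance(counts, CountMatrix):
        mat = counts.counts.astype(float)
        gene_ids = list(counts.gene_ids)
        sample_ids = list(counts.sample_ids)
    else:
        mat = np.asarray(counts, dtype=float)
        gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(mat.shape[0])]
        sample_ids = (
            list(sample_ids) if sample_ids is not None else [f"s{j}" for j in range(mat.shape[1])]
        )
    if lib_sizes is None:
        lib_sizes = mat.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if norm_factors is None:
        norm_factors = np.ones_like(lib_sizes)
    norm_factors = np.asarray(norm_factors, dtype=float)
    eff = lib_sizes * norm_factors
    if (eff <= 0).any():
        bad = [s for s, e in zip(sample_ids, eff) if e <= 0]
        raise DegenerateLibraryError(f"zero effective library sizes: {bad[:5]}")
    values = np.log2((mat + prior_count) / (eff + 2.0 * prior_count) * 1e6)
    return NormalizedMatrix(gene_ids, sample_ids, values, lib_sizes, norm_factors, prior_count)


def fit_standardizer(norm: NormalizedMatrix) -> StandardizationStats:
    """Per-gene mean and sample SD of log2-CPM, persisted for later z-scaling."""
    if len(norm.sample_ids) < 2:
        raise ValueError("standardization needs >= 2 samples")
    means = norm.values.mean(axis=1)
    sds = norm.values.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = [g for g, s in zip(norm.gene_ids, sds) if s == 0]
        raise ZeroVarianceError(f"zero-variance genes: {bad[:5]}")
    return StandardizationStats(list(norm.gene_ids), means, sds)


def apply_standardizer(norm: NormalizedMatrix, stats: StandardizationStats) -> pd.DataFrame:
    """z = (log2-CPM - stored mean) / stored SD, per gene.

    Uses the *stored* training statistics; never recomputed on new data.
    """
    pos = pd.Index(stats.gene_ids).get_indexer(norm.gene_ids)
    if (pos < 0).any():
        missing = [g for g, p in zip(norm.gene_ids, pos) if p < 0]
        raise MissingStatisticsError(f"no stored statistics for genes: {missing[:5]}")
    z = (norm.values - stats.means[pos, None]) / stats.sds[pos, None]
    return pd.DataFrame(z, index=norm.gene_ids, columns=norm.sample_ids)


def subset_with_zero_fill(
    counts: CountMatrix,
    required_genes: Sequence[str],
    *,
    max_missing_fraction: float = 0.5,
) -> tuple[CountMatrix, list[str]]:
    """Subset to ``required_genes`` in order, zero-filling absent genes.

    Returns the subset matrix and the list of missing (zero-filled) genes.
    Refuses when more than ``max_missing_fraction`` of the required genes
    are absent.
    """
    required = list(required_genes)
    if not required or len(set(required)) != len(required):
        raise ValueError("required_genes must be non-empty and unique")
    idx = pd.Index(counts.gene_ids)
    pos = idx.get_indexer(required)
    missing = [g for g, p in zip(required, pos) if p < 0]
    frac = len(missing) / len(required)
    if frac > max_missing_fraction:
        raise ExcessiveMissingnessError(
            f"{len(missing)}/{len(required)} required genes missing "
            f"({frac:.0%} > {max_missing_fraction:.0%})"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(required)} required genes missing; zero-filled",
            stacklevel=2,
        )
    out = np.zeros((len(required), counts.n_samples), dtype=np.int64)
    present = pos >= 0
    out[present] = counts.counts[pos[present]]
    return CountMatrix(required, list(counts.sample_ids), out), missing


def write_missing_gene_report(missing: Sequence[str], path) -> None:
    """Two-column TSV (gene_id, reason) for zero-filled genes."""
    pd.DataFrame({"gene_id": list(missing), "reason": "absent_zero_filled"}).to_csv(
        path, sep="\t", index=False
    )


def pseudobulk_counts(cell_counts: CountMatrix, grouping: Mapping[str, str]) -> CountMatrix:
    """Sum single-cell counts into per-group (sample/patient) profiles.

    Every cell must be mapped to exactly one group; groups appear in order
    of first appearance among the cells.  Total counts are conserved.
    """
    unmapped = [c for c in cell_counts.sample_ids if c not in grouping]
    if unmapped:
        raise UnmappedCellError(f"cells without a group: {unmapped[:5]}")
    groups: list[str] = []
    for c in cell_counts.sample_ids:
        g = str(grouping[c])
        if g not in groups:
            groups.append(g)
    out = np.zeros((cell_counts.n_genes, len(groups)), dtype=np.int64)
    gidx = {g: j for j, g in enumerate(groups)}
    for i, c in enumerate(cell_counts.sample_ids):
        out[:, gidx[str(grouping[c])]] += cell_counts.counts[:, i]
    return CountMatrix(list(cell_counts.gene_ids), groups, out)
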