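"""Synthetic HGSC expression cohorts with known HR ground truth.

The generator emulates the statistical structure the classifier is
built to exploit: a two-class cohort of roughly 50% HR-deficient
samples, a continuous latent genomic-scar (HRD) score thresholded at 42,
copy-number-driven regional expression shifts (8q24.2 up in HRD, 5q13.2
and 19q12 down in HRD), tumour-purity dilution of those shifts, library
sizes on the order of tens of millions of reads, and negative-binomial
count noise with per-gene overdispersion.  A small number of non-coding
and chrM/chrY genes are included so upstream filters have work to do.

None of this reproduces real tumour biology — co-expression structure,
batch effects and subclonality are absent — but every pipeline stage can
be exercised and its parameter recovery measured against the planted
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import CountMatrix

HRD_CUTOFF = 42.0

#: chromosome arms used to scatter null genes across the genome
_BACKGROUND_ARMS = [
    "1p", "1q", "2p", "2q", "3p", "3q", "4p", "4q", "6p", "6q",
    "7p", "7q", "9p", "9q", "10p", "10q", "11p", "11q", "12p", "12q",
    "13q", "14q", "15q", "16p", "16q", "17p", "17q", "18p", "18q",
    "20p", "20q", "21q", "22q",
]


@dataclass(frozen=True)
class RegionEffect:
    """A copy-number-like regional expression shift.

    ``log2fc_range`` gives the per-gene |log2 fold-change| magnitudes
    (drawn uniformly); ``direction`` +1 means up in HRD.  ``coupling``
    in [0, 1] is the fraction of the effect that scales with the latent
    HRD score (via a logistic ramp centred at the clinical cutoff)
    rather than with the binary label.
    """

    band: str  # e.g. "8q24.2"
    n_genes: int
    direction: int  # +1 up in HRD, -1 down in HRD
    log2fc_range: tuple[float, float] = (0.5, 1.5)
    coupling: float = 0.5

    @property
    def arm(self) -> str:
        split = self.band.index("p") if "p" in self.band else self.band.index("q")
        return self.band[: split + 1]


DEFAULT_REGIONS = (
    RegionEffect("8q24.2", 50, +1),
    RegionEffect("5q13.2", 50, -1),
    RegionEffect("19q12", 50, -1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 240
    n_genes: int = 3000  # coding autosomal genes
    n_excluded_genes: int = 30  # extra non-coding / chrY / chrM genes
    prevalence: float = 0.5
    hrp_score_loc: float = 20.0
    hrp_score_scale: float = 10.0
    hrd_score_loc: float = 62.0
    hrd_score_scale: float = 12.0
    purity_range: tuple[float, float] = (0.30, 1.00)
    libsize_median: float = 6.0e7
    libsize_sigma: float = 0.3
    dispersion_log_mean: float = np.log(0.08)
    dispersion_log_sigma: float = 0.4
    baseline_log_sigma: float = 1.2
    regions: tuple[RegionEffect, ...] = DEFAULT_REGIONS
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_samples < 2 or self.n_genes < 10:
            raise ValueError("cohort too small to simulate")
        total_region = sum(r.n_genes for r in self.regions)
        if total_region > self.n_genes:
            raise ValueError("region genes exceed total genes")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("purity range must satisfy 0 < lo <= hi <= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort.

    ``samples``: sample_id, hrd_score, label (1 = HRD), purity, lib_size.
    ``genes``: gene_id, chromosome, arm, band, biotype, baseline,
    dispersion, region, true_log2fc (signed, up-in-HRD positive).
    """

    samples: pd.DataFrame
    genes: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.samples["label"].to_numpy(int)

    @property
    def hrd_scores(self) -> np.ndarray:
        return self.samples["hrd_score"].to_numpy(float)

    @property
    def effect_gene_ids(self) -> list[str]:
        return self.genes.loc[self.genes["true_log2fc"] != 0, "gene_id"].tolist()

    def annotation(self) -> pd.DataFrame:
        """GeneAnnotation view (gene_id, chromosome, arm, band, biotype)."""
        return self.genes[["gene_id", "chromosome", "arm", "band", "biotype"]].copy()


def label_from_hrd_score(score: float | np.ndarray, cutoff: float = HRD_CUTOFF):
    """HRD iff score >= cutoff (clinical genomic-scar convention)."""
    arr = np.asarray(score, float)
    out = (arr >= cutoff).astype(int)
    return int(out) if np.isscalar(score) or arr.ndim == 0 else out


def summarize_promoter_methylation(
    betas: np.ndarray, threshold: float = 0.15
) -> tuple[float, bool]:
    """Mean promoter beta value and a silencing flag (strictly above threshold)."""
    betas = np.asarray(betas, float)
    if betas.size == 0:
        raise ValueError("need at least one methylation probe")
    if ((betas < 0) | (betas > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    mean = float(betas.mean())
    return mean, mean > threshold


def _truncated_scores(
    rng: np.random.Generator, n: int, loc: float, scale: float, lo: float, hi: float
) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def _score_ramp(score: np.ndarray, width: float = 12.0) -> np.ndarray:
    """Logistic ramp in (0, 1) centred at the clinical cutoff."""
    return 1.0 / (1.0 + np.exp(-(score - HRD_CUTOFF) / width))


def simulate_cohort(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one cohort of negative-binomial counts with planted regional effects.

    Per sample: a binary HR label at the configured prevalence, a latent
    HRD score from the label's truncated normal (HRP on [0, 42), HRD on
    [42, inf) so labels and scores stay consistent), a purity and a
    library size.  Per gene: a log-normal baseline abundance and NB
    dispersion.  Region genes shift their expected proportion by
    2^(purity * m * log2FC) where m blends the binary label with the
    score ramp according to the region's coupling.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    labels = (rng.random(n) < config.prevalence).astype(int)
    scores = np.where(
        labels == 1,
        _truncated_scores(rng, n, config.hrd_score_loc, config.hrd_score_scale, HRD_CUTOFF, np.inf),
        _truncated_scores(rng, n, config.hrp_score_loc, config.hrp_score_scale, 0.0, HRD_CUTOFF),
    )
    purity = rng.uniform(*config.purity_range, size=n)
    lib = rng.lognormal(np.log(config.libsize_median), config.libsize_sigma, size=n)

    baseline = rng.lognormal(0.0, config.baseline_log_sigma, size=g)
    dispersion = rng.lognormal(config.dispersion_log_mean, config.dispersion_log_sigma, size=g)

    # gene annotation: region genes first, then background arms round-robin
    gene_ids = [f"SIMG{i:07d}" for i in range(g)]
    arms = np.empty(g, dtype=object)
    bands = np.empty(g, dtype=object)
    chroms = np.empty(g, dtype=object)
    true_lfc = np.zeros(g)
    region_of = np.full(g, "", dtype=object)
    cursor = 0
    for region in config.regions:
        sl = slice(cursor, cursor + region.n_genes)
        arms[sl] = region.arm
        bands[sl] = region.band
        chroms[sl] = "".join(ch for ch in region.arm if ch not in "pq")
        lo, hi = region.log2fc_range
        true_lfc[sl] = region.direction * rng.uniform(lo, hi, size=region.n_genes)
        region_of[sl] = region.band
        cursor += region.n_genes
    bg = np.arange(cursor, g)
    bg_arms = [_BACKGROUND_ARMS[i % len(_BACKGROUND_ARMS)] for i in range(len(bg))]
    arms[bg] = bg_arms
    bands[bg] = [f"{a}11" for a in bg_arms]
    chroms[bg] = ["".join(ch for ch in a if ch not in "pq") for a in bg_arms]

    # per-sample effect multiplier: purity dilutes; coupling tracks the score
    log2_shift = np.zeros((g, n))
    for region in config.regions:
        idx = np.flatnonzero(region_of == region.band)
        m = purity * (
            (1.0 - region.coupling) * labels + region.coupling * _score_ramp(scores)
        )
        log2_shift[idx] = np.outer(true_lfc[idx], m)

    props = baseline[:, None] * np.exp2(log2_shift)
    props /= props.sum(axis=0, keepdims=True)
    mu = props * lib[None, :]
    r = 1.0 / dispersion  # NB shape; variance = mu + dispersion * mu^2
    p_nb = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p_nb)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chroms,
            "arm": arms,
            "band": bands,
            "biotype": "protein_coding",
            "baseline": baseline,
            "dispersion": dispersion,
            "region": region_of,
            "true_log2fc": true_lfc,
        }
    )

    # excluded decoys: low-information genes the coding/chromosome filter drops
    if config.n_excluded_genes:
        ne = config.n_excluded_genes
        ex_ids = [f"SIMX{i:05d}" for i in range(ne)]
        kinds = np.array(["non_coding", "chrY", "chrM"])[np.arange(ne) % 3]
        ex_baseline = rng.lognormal(0.0, config.baseline_log_sigma, size=ne)
        ex_props = ex_baseline / baseline.sum()
        ex_mu = np.outer(ex_props, lib)
        ex_disp = rng.lognormal(config.dispersion_log_mean, config.dispersion_log_sigma, size=ne)
        ex_r = 1.0 / ex_disp
        ex_counts = rng.negative_binomial(ex_r[:, None], ex_r[:, None] / (ex_r[:, None] + ex_mu))
        ex_genes = pd.DataFrame(
            {
                "gene_id": ex_ids,
                "chromosome": np.where(kinds == "chrY", "Y", np.where(kinds == "chrM", "M", "2")),
                "arm": "",
                "band": "",
                "biotype": np.where(kinds == "non_coding", "lncRNA", "protein_coding"),
                "baseline": ex_baseline,
                "dispersion": ex_disp,
                "region": "",
                "true_log2fc": 0.0,
            }
        )
        gene_ids = gene_ids + ex_ids
        counts = np.vstack([counts, ex_counts])
        genes = pd.concat([genes, ex_genes], ignore_index=True)

    sample_ids = [f"S{config.seed}_{i:04d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "hrd_score": scores,
            "label": labels,
            "purity": purity,
            "lib_size": lib,
        }
    )
    return CountMatrix(gene_ids, sample_ids, counts), SyntheticTruth(samples, genes)


def simulate_single_cells(
    sample_profile: np.ndarray,
    n_cells: int,
    *,
    mean_libsize: float = 5000.0,
    libsize_sigma: float = 0.3,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> CountMatrix:
    """Draw single cells multinomially from a bulk profile's proportions."""
    profile = np.asarray(sample_profile, float)
    total = profile.sum()
    if total <= 0 or (profile < 0).any():
        raise ValueError("profile must be non-negative with positive total")
    rng = np.random.default_rng(seed)
    props = profile / total
    libs = np.maximum(rng.lognormal(np.log(mean_libsize), libsize_sigma, size=n_cells), 1).astype(
        int
    )
    counts = np.column_stack([rng.multinomial(l, props) for l in libs])
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(len(profile))]
    cells = [f"cell{j:05d}" for j in range(n_cells)]
    return CountMatrix(list(genes), cells, counts)


def split_cohort(
    counts: CountMatrix, truth: SyntheticTruth, n_train: int
) -> tuple[CountMatrix, SyntheticTruth, CountMatrix, SyntheticTruth]:
    """Split a simulated cohort into train/test by sample (genes shared).

    Samples are exchangeable draws, so a prefix split is an i.i.d. split.
    """
    if not 0 < n_train < counts.n_samples:
        raise ValueError("n_train must leave at least one test sample")
    tr = CountMatrix(list(counts.gene_ids), counts.sample_ids[:n_train], counts.counts[:, :n_train])
    te = CountMatrix(list(counts.gene_ids), counts.sample_ids[n_train:], counts.counts[:, n_train:])
    t_tr = SyntheticTruth(truth.samples.iloc[:n_train].reset_index(drop=True), truth.genes)
    t_te = SyntheticTruth(truth.samples.iloc[n_train:].reset_index(drop=True), truth.genes)
    return tr, t_tr, te, t_te


def default_train_test(
    seed: int = 1, *, n_train: int = 240, n_test: int = 60, n_genes: int = 3000
) -> tuple[CountMatrix, SyntheticTruth, CountMatrix, SyntheticTruth]:
    """The default study conditions: a training and a held-out test cohort.

    One cohort of ``n_train + n_test`` samples is simulated (so gene-level
    parameters — baselines, dispersions, planted effects — are shared)
    and split by sample into the two sets.
    """
    cfg = SimulationConfig(n_samples=n_train + n_test, n_genes=n_genes, seed=seed)
    counts, truth = simulate_cohort(cfg)
    return split_cohort(counts, truth, n_train)
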