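"""Readers, writers and core containers.

The universal input is a :class:`CountMatrix` — a dense non-negative
integer gene-by-sample matrix with unique, version-stripped gene
identifiers.  Dense TSV/CSV tables and 10x-style MatrixMarket triplets
(matrix.mtx + features.tsv + barcodes.tsv) are both supported.  Trained
classifiers persist as a schema-versioned JSON :class:`ModelBundle`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import (
    DuplicateIdentifierError,
    MalformedAnnotationError,
    MalformedInputError,
    MissingFieldError,
    SchemaVersionError,
)

BUNDLE_SCHEMA_VERSION = 1

_VERSION_SUFFIX = re.compile(r"\.(\d+)$")


def strip_gene_version(gene_id: str) -> str:
    """Remove a trailing numeric ``.N`` version suffix from a gene identifier.

    ``ENSG00000012048.21`` becomes ``ENSG00000012048``; identifiers without
    a numeric suffix are returned unchanged.  Idempotent.
    """
    if not gene_id:
        raise MalformedInputError("empty gene identifier")
    return _VERSION_SUFFIX.sub("", gene_id)


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample count matrix.

    Parameters
    ----------
    gene_ids : sequence of str
        Stable gene identifiers, unique after version stripping.
    sample_ids : sequence of str
        Unique sample identifiers.
    counts : ndarray of shape (n_genes, n_samples)
        Raw counts; validated to be non-negative integers.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise MalformedInputError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size:
            if np.issubdtype(counts.dtype, np.floating):
                if not np.isfinite(counts).all():
                    raise MalformedInputError("counts contain non-finite entries")
                if not np.equal(np.mod(counts, 1), 0).all():
                    g, s = np.argwhere(np.mod(counts, 1) != 0)[0]
                    raise MalformedInputError(
                        f"non-integral count at gene {self.gene_ids[g]!r}, "
                        f"sample {self.sample_ids[s]!r}"
                    )
            if (counts < 0).any():
                g, s = np.argwhere(counts < 0)[0]
                raise MalformedInputError(
                    f"negative count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
        self.counts = counts.astype(np.int64)
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
                raise DuplicateIdentifierError(f"duplicate {name} identifiers: {dupes[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts."""
        return self.counts.sum(axis=0).astype(np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Reorder/subset to ``gene_ids``, all of which must be present."""
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(list(gene_ids))
        if (pos < 0).any():
            missing = [g for g, p in zip(gene_ids, pos) if p < 0]
            raise MalformedInputError(f"genes absent from matrix: {missing[:5]}")
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[pos])


@dataclass
class SampleLabels:
    """Per-sample HR ground truth.

    ``hr_status`` is a binary vector (1 = HRD, 0 = HRP); ``hrd_score`` the
    continuous genomic scar score.  When a status is derived from a score
    the clinical cutoff is score >= 42 -> HRD.
    """

    sample_ids: list[str]
    hr_status: np.ndarray | None = None
    hrd_score: np.ndarray | None = None

    HRD_CUTOFF = 42.0

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdentifierError("duplicate sample identifiers in labels")
        if self.hr_status is not None:
            self.hr_status = np.asarray(self.hr_status).astype(int)
            if not np.isin(self.hr_status, [0, 1]).all():
                raise MalformedInputError("hr_status must be binary (1=HRD, 0=HRP)")
        if self.hrd_score is not None:
            self.hrd_score = np.asarray(self.hrd_score, dtype=float)
            if (self.hrd_score < 0).any():
                raise MalformedInputError("hrd_score must be non-negative")
        if self.hr_status is None and self.hrd_score is not None:
            self.hr_status = (self.hrd_score >= self.HRD_CUTOFF).astype(int)

    def status_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(sample_ids, pos) if p < 0]
            raise MalformedInputError(f"samples missing from labels: {missing[:5]}")
        if self.hr_status is None:
            raise MalformedInputError("labels carry no HR status")
        return self.hr_status[pos]


@dataclass
class ModelBundle:
    """A persisted HR-status classifier.

    Fields mirror what prediction needs and nothing more: the signature
    gene list (defining the subset-library normalization), the stored
    training log2-CPM mean/SD per gene, the sparse-capable coefficient
    vector with intercept, the elastic-net hyperparameters, and the
    decision threshold.  The raw linear-model probability is P(HRP); the
    reported probability of deficiency is its complement.
    """

    signature_gene_ids: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    alpha: float
    lambda_: float
    threshold: float = 0.5
    positive_class_convention: str = "raw_probability_is_P_HRP"

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        self.gene_sds = np.asarray(self.gene_sds, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n = len(self.signature_gene_ids)
        for name, vec in (
            ("gene_means", self.gene_means),
            ("gene_sds", self.gene_sds),
            ("coefficients", self.coefficients),
        ):
            if vec.shape != (n,):
                raise MalformedInputError(f"{name} length {vec.shape} != {n} signature genes")
        if (self.gene_sds <= 0).any():
            bad = np.asarray(self.signature_gene_ids)[self.gene_sds <= 0]
            raise MalformedInputError(f"non-positive gene SDs for {bad[:5].tolist()}")
        if not 0.0 <= self.threshold <= 1.0:
            raise MalformedInputError("threshold must lie in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise MalformedInputError("alpha must lie in [0, 1]")
        if self.lambda_ <= 0:
            raise MalformedInputError("lambda must be positive")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelBundle):
            return NotImplemented
        return (
            self.signature_gene_ids == other.signature_gene_ids
            and np.array_equal(self.gene_means, other.gene_means)
            and np.array_equal(self.gene_sds, other.gene_sds)
            and np.array_equal(self.coefficients, other.coefficients)
            and self.intercept == other.intercept
            and self.alpha == other.alpha
            and self.lambda_ == other.lambda_
            and self.threshold == other.threshold
            and self.positive_class_convention == other.positive_class_convention
        )


def read_counts(
    path: str | Path,
    format: str = "dense-table",
    *,
    transposed: bool = False,
    sep: str | None = None,
) -> CountMatrix:
    """Read a count matrix.

    Parameters
    ----------
    format : {"dense-table", "matrix-market"}
        Dense tables have gene rows (first column = gene ID, header row =
        sample IDs) unless ``transposed``.  Matrix-market expects
        ``matrix.mtx`` with ``features.tsv`` and ``barcodes.tsv`` sidecars
        in the same directory (``path`` may point at the .mtx file or the
        directory).
    """
    path = Path(path)
    if not path.exists():
        raise MalformedInputError(f"no such file: {path}")
    if format == "dense-table":
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transposed:
            df = df.T
        genes = [strip_gene_version(str(g)) for g in df.index]
        return CountMatrix(genes, [str(c) for c in df.columns], df.to_numpy())
    if format == "matrix-market":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        feat, barc = base / "features.tsv", base / "barcodes.tsv"
        for sidecar in (feat, barc):
            if not sidecar.exists():
                raise MalformedInputError(f"missing sidecar {sidecar.name} next to {mtx_path}")
        mat = scipy.sparse.csr_matrix(scipy.io.mmread(mtx_path))
        genes = [
            strip_gene_version(line.split("\t")[0])
            for line in feat.read_text().splitlines()
            if line.strip()
        ]
        samples = [line.strip() for line in barc.read_text().splitlines() if line.strip()]
        dense = np.asarray(mat.todense())
        return CountMatrix(genes, samples, dense)
    raise MalformedInputError(f"unknown count format {format!r}")


def write_counts(matrix: CountMatrix, path: str | Path, *, sep: str = "\t") -> None:
    """Write a dense gene-by-sample count table."""
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def write_counts_mtx(matrix: CountMatrix, directory: str | Path) -> None:
    """Write 10x-style MatrixMarket triplet: matrix.mtx, features.tsv, barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", scipy.sparse.coo_matrix(matrix.counts))
    (directory / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    (directory / "barcodes.tsv").write_text("".join(f"{s}\n" for s in matrix.sample_ids))


def read_labels(path: str | Path, *, sep: str | None = None) -> SampleLabels:
    """Read a sample label table with columns sample_id and hr_status and/or hrd_score.

    hr_status accepts 0/1 or the strings HRD/HRP (case-insensitive).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise MalformedInputError("label table needs a 'sample_id' column")
    status = None
    if "hr_status" in df.columns:
        raw = df["hr_status"]
        if raw.dtype == object:
            mapping = {"HRD": 1, "HRP": 0}
            status = raw.astype(str).str.upper().map(mapping)
            if status.isna().any():
                raise MalformedInputError("hr_status strings must be HRD or HRP")
            status = status.to_numpy()
        else:
            status = raw.to_numpy()
    score = df["hrd_score"].to_numpy() if "hrd_score" in df.columns else None
    return SampleLabels(df["sample_id"].tolist(), status, score)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    cols: dict[str, object] = {"sample_id": labels.sample_ids}
    if labels.hr_status is not None:
        cols["hr_status"] = np.where(labels.hr_status == 1, "HRD", "HRP")
    if labels.hrd_score is not None:
        cols["hrd_score"] = labels.hrd_score
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cytoband annotation


def _normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_cytobands(path: str | Path) -> pd.DataFrame:
    """Parse a UCSC cytoBand file (chrom, start, end, band, stain).

    Coordinates are 0-based half-open.  Returns a DataFrame with columns
    ``chromosome, start, end, band, arm, stain`` where ``band`` carries the
    full label (e.g. ``8q24.3``) and ``arm`` the chromosome arm (``8q``).
    Bands on a chromosome must not overlap.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 5:
            raise MalformedAnnotationError(f"cytoband line {ln}: expected 5 fields")
        chrom, start, end, name, stain = parts[:5]
        chrom = _normalize_chrom(chrom)
        if not name or name[0] not in "pq":
            raise MalformedAnnotationError(f"cytoband line {ln}: band {name!r} lacks p/q prefix")
        rows.append(
            {
                "chromosome": chrom,
                "start": int(start),
                "end": int(end),
                "band": f"{chrom}{name}",
                "arm": f"{chrom}{name[0]}",
                "stain": stain,
            }
        )
    bands = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "band", "arm", "stain"]
    )
    for chrom, sub in bands.groupby("chromosome"):
        sub = sub.sort_values("start")
        overlap = sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]
        if overlap.any():
            raise MalformedAnnotationError(f"overlapping cytobands on chromosome {chrom}")
    return bands


def annotate_genes(
    gene_positions: pd.DataFrame,
    cytobands: pd.DataFrame,
    *,
    biotype: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assign genes to cytobands by TSS, else interval midpoint (half-open).

    ``gene_positions`` needs columns ``gene_id, chromosome`` and either
    ``tss`` or ``start``/``end``.  Returns a GeneAnnotation table with
    columns ``gene_id, chromosome, arm, band, biotype``; genes whose
    position falls outside every band get band/arm NaN.
    """
    gp = gene_positions.copy()
    gp["chromosome"] = gp["chromosome"].astype(str).map(_normalize_chrom)
    if "tss" in gp.columns:
        pos = gp["tss"].to_numpy(dtype=np.int64)
    else:
        pos = ((gp["start"].to_numpy(np.int64) + gp["end"].to_numpy(np.int64)) // 2)
    out = []
    by_chrom = {c: s.sort_values("start") for c, s in cytobands.groupby("chromosome")}
    for gene, chrom, p in zip(gp["gene_id"], gp["chromosome"], pos):
        band = arm = None
        sub = by_chrom.get(chrom)
        if sub is not None:
            hit = sub[(sub["start"] <= p) & (p < sub["end"])]
            if len(hit):
                band = hit.iloc[0]["band"]
                arm = hit.iloc[0]["arm"]
        bt = biotype.get(gene, "protein_coding") if biotype is not None else "protein_coding"
        out.append(
            {"gene_id": strip_gene_version(str(gene)), "chromosome": chrom,
             "arm": arm, "band": band, "biotype": bt}
        )
    return pd.DataFrame(out, columns=["gene_id", "chromosome", "arm", "band", "biotype"])


# ---------------------------------------------------------------------------
# Model bundle serialization

_REQUIRED_BUNDLE_FIELDS = (
    "schema_version",
    "signature_gene_ids",
    "gene_means",
    "gene_sds",
    "coefficients",
    "intercept",
    "alpha",
    "lambda",
    "threshold",
    "positive_class_convention",
)


def write_model_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize a bundle to schema-versioned JSON with full float precision."""
    doc = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "signature_gene_ids": list(bundle.signature_gene_ids),
        "gene_means": bundle.gene_means.tolist(),
        "gene_sds": bundle.gene_sds.tolist(),
        "coefficients": bundle.coefficients.tolist(),
        "intercept": float(bundle.intercept),
        "alpha": float(bundle.alpha),
        "lambda": float(bundle.lambda_),
        "threshold": float(bundle.threshold),
        "positive_class_convention": bundle.positive_class_convention,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model_bundle(path: str | Path) -> ModelBundle:
    doc = json.loads(Path(path).read_text())
    for key in _REQUIRED_BUNDLE_FIELDS:
        if key not in doc:
            raise MissingFieldError(f"model bundle missing required field {key!r}")
    if doc["schema_version"] != BUNDLE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported bundle schema version {doc['schema_version']!r} "
            f"(supported: {BUNDLE_SCHEMA_VERSION})"
        )
    return ModelBundle(
        signature_gene_ids=list(doc["signature_gene_ids"]),
        gene_means=np.array(doc["gene_means"], dtype=float),
        gene_sds=np.array(doc["gene_sds"], dtype=float),
        coefficients=np.array(doc["coefficients"], dtype=float),
        intercept=float(doc["intercept"]),
        alpha=float(doc["alpha"]),
        lambda_=float(doc["lambda"]),
        threshold=float(doc["threshold"]),
        positive_class_convention=str(doc["positive_class_convention"]),
    )
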