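"""Expression-matrix containers, delimited-text I/O, and preprocessing filters.

Expression data move through the pipeline as :class:`ExpressionMatrix` objects:
a samples x genes value block with unique identifiers on both axes, a domain
tag (``source`` for cell-line-like cohorts, ``target`` for tumor-like cohorts),
optional per-sample tissue labels, and a metadata record of the transforms
already applied.  Transforms are idempotence-guarded: applying a log transform
or a normalization twice is an error, not a silent double-application.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SOURCE = "source"
TARGET = "target"

_CDR_SENSITIVE = {"complete response", "partial response"}
_CDR_RESISTANT = {"stable disease", "progressive disease",
                  "clinically progressive disease"}


class MatrixFormatError(ValueError):
    """Malformed expression file: duplicates, missing or non-numeric cells."""


@dataclass
class ExpressionMatrix:
    """Samples x genes expression block with identifiers and provenance.

    Parameters
    ----------
    sample_ids, gene_ids
        Ordered, unique identifiers for rows and columns of ``values``.
    values
        Real matrix of shape ``(n_samples, n_genes)``; no missing values.
    domain
        ``"source"`` (preclinical / cell-line-like) or ``"target"``
        (clinical / tumor-like).
    tissue
        Optional tissue or cancer-type label per sample.
    metadata
        Free-form provenance; the ``transforms`` list guards idempotence and
        ``units`` names the current expression scale.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    domain: str = SOURCE
    tissue: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise MatrixFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes")
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise MatrixFormatError(f"duplicate {name} ids: {sorted(dupes)}")
        if np.isnan(self.values).any():
            bad = np.argwhere(np.isnan(self.values))[0]
            raise MatrixFormatError(
                f"missing value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}")
        if self.domain not in (SOURCE, TARGET):
            raise ValueError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.tissue is not None:
            self.tissue = [str(t) for t in self.tissue]
            if len(self.tissue) != len(self.sample_ids):
                raise MatrixFormatError("tissue labels must align with sample_ids")
        self.metadata.setdefault("transforms", [])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def transforms(self) -> list[str]:
        return self.metadata["transforms"]

    def has_transform(self, name: str) -> bool:
        return name in self.transforms

    def record_transform(self, name: str) -> None:
        if self.has_transform(name):
            raise ValueError(f"transform {name!r} already applied (idempotence guard)")
        self.transforms.append(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            gene_ids=[str(g) for g in genes],
            values=self.values[:, cols].copy(),
            domain=self.domain,
            tissue=None if self.tissue is None else list(self.tissue),
            metadata=json.loads(json.dumps(self.metadata)),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not present: {missing[:10]}")
        rows = [idx[s] for s in samples]
        return ExpressionMatrix(
            sample_ids=[str(s) for s in samples],
            gene_ids=list(self.gene_ids),
            values=self.values[rows, :].copy(),
            domain=self.domain,
            tissue=None if self.tissue is None else [self.tissue[r] for r in rows],
            metadata=json.loads(json.dumps(self.metadata)),
        )


@dataclass
class ResponseTable:
    """Per-sample drug response: continuous ln IC50 (source) or binary labels
    (target, ``sensitive`` / ``resistant``) for one drug."""

    sample_ids: list[str]
    drug: str
    values: np.ndarray | None = None          # ln IC50, source domain
    labels: list[str] | None = None           # sensitive/resistant, target domain

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if (self.values is None) == (self.labels is None):
            raise ValueError("exactly one of values (continuous) or labels "
                             "(binary) must be provided")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if len(self.values) != len(self.sample_ids):
                raise ValueError("values must align with sample_ids")
            if not np.all(np.isfinite(self.values)):
                raise ValueError("non-finite response values")
        if self.labels is not None:
            if len(self.labels) != len(self.sample_ids):
                raise ValueError("labels must align with sample_ids")
            bad = sorted(set(self.labels) - {"sensitive", "resistant"})
            if bad:
                raise ValueError(f"labels must be sensitive/resistant, got {bad}")

    def aligned_to(self, matrix: ExpressionMatrix) -> "ResponseTable":
        """Reorder to a matrix's sample order; every id must resolve."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in matrix.sample_ids if s not in idx]
        if missing:
            raise KeyError(f"response missing for samples: {missing[:10]}")
        order = [idx[s] for s in matrix.sample_ids]
        return ResponseTable(
            sample_ids=list(matrix.sample_ids),
            drug=self.drug,
            values=None if self.values is None else self.values[order],
            labels=None if self.labels is None else [self.labels[i] for i in order],
        )


@dataclass
class PipelineConfig:
    """Run configuration for a single-drug pipeline execution."""

    drug: str = "drug"
    max_epochs: int = 1000
    patience: int = 30
    batch_sizes: tuple[int, ...] = (16, 64)
    learning_rates: tuple[float, ...] = (1e-4, 1e-3)
    hidden: tuple[int, ...] = (512, 256, 128)
    dropout: float = 0.2
    ensemble_size: int = 10
    n_explainers: int = 10
    explainer_hidden: int = 512
    explainer_layers: int = 2
    explainer_epochs: int = 150
    explainer_batch_size: int = 32
    explainer_learning_rate: float = 1e-3
    explainer_subsample: int | None = None  # cap on samples used for masking targets
    base_seed: int = 0
    normalization_mode: str = "tissue_informed"
    percentiles: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.normalization_mode not in ("tissue_informed", "train_norm", "test_norm"):
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")
        for name in ("max_epochs", "patience", "n_explainers", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(b <= 0 for b in self.batch_sizes) or any(lr <= 0 for lr in self.learning_rates):
            raise ValueError("grid entries must be positive")

    def grid(self) -> list[dict]:
        return [{"batch_size": b, "learning_rate": lr}
                for b in self.batch_sizes for lr in self.learning_rates]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("batch_sizes", "learning_rates", "hidden", "percentiles"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, orientation: str = "samples_in_rows",
                domain: str = SOURCE,
                tissue_column: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression matrix (header row + identifier column).

    ``orientation`` says what the file's rows are; the returned matrix is
    always samples x genes.  A JSON sidecar ``<path>.meta.json`` written by
    :func:`write_matrix`, if present, restores transforms/units/domain/tissue.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    sidecar = path.with_name(path.name + ".meta.json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        domain = meta.pop("domain", domain)

    tissue = None
    if tissue_column is not None:
        if tissue_column not in df.columns:
            raise MatrixFormatError(f"tissue column {tissue_column!r} not found")
        tissue = df[tissue_column].astype(str).tolist()
        df = df.drop(columns=[tissue_column])

    for axis_name, ids in (("row", df.index), ("column", df.columns)):
        dupes = _duplicates(ids)
        if dupes:
            raise MatrixFormatError(
                f"duplicate {axis_name} identifier(s): {sorted(dupes)}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise MatrixFormatError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise MatrixFormatError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}")

    if orientation == "genes_in_rows":
        numeric = numeric.T
        if tissue is not None:
            raise MatrixFormatError("tissue_column requires samples_in_rows")

    mm = meta.pop("tissue", None)
    if tissue is None and mm is not None:
        tissue = list(mm)
    return ExpressionMatrix(
        sample_ids=list(numeric.index), gene_ids=list(numeric.columns),
        values=numeric.values, domain=domain, tissue=tissue,
        metadata=meta if meta else {})


def write_matrix(matrix: ExpressionMatrix, path: str | Path,
                 float_format: str = "%.10g") -> None:
    """Write a samples-in-rows delimited matrix plus a JSON provenance sidecar."""
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), float_format=float_format,
                             index_label="sample_id")
    sidecar = path.with_name(path.name + ".meta.json")
    meta = dict(matrix.metadata)
    meta["domain"] = matrix.domain
    if matrix.tissue is not None:
        meta["tissue"] = list(matrix.tissue)
    sidecar.write_text(json.dumps(meta, indent=1))


def filter_target_genes(target: ExpressionMatrix, expr_threshold: float = 1.0,
                        fraction: float = 0.9) -> ExpressionMatrix:
    """Drop near-silent genes from a raw-FPKM-like target matrix, then log it.

    A gene is removed when its expression is below ``expr_threshold`` (strict
    ``<``) in at least ``fraction`` of the target samples; survivors are
    transformed elementwise to ``log2(value + 0.1)``.
    """
    if target.has_transform("log2"):
        raise ValueError("matrix is already log-transformed (idempotence guard)")
    low = (target.values < expr_threshold).mean(axis=0)
    keep = low < fraction           # removed when fraction of low samples >= cutoff
    out = target.subset_genes([g for g, k in zip(target.gene_ids, keep) if k])
    if out.n_genes == 0:
        raise ValueError("no genes survive the expression filter")
    out.values = np.log2(out.values + 0.1)
    out.record_transform("expression_filter")
    out.record_transform("log2")
    out.metadata["units"] = "log2(FPKM+0.1)"
    return out


def intersect_genes(source: ExpressionMatrix, target: ExpressionMatrix
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both cohorts to the shared gene set in lexicographic order."""
    shared = sorted(set(source.gene_ids) & set(target.gene_ids))
    if not shared:
        raise ValueError("source and target share no genes")
    return source.subset_genes(shared), target.subset_genes(shared)


def encode_cdr(sample_ids: Sequence[str], raw_labels: Sequence[str],
               drug: str) -> ResponseTable:
    """Collapse RECIST-style clinical drug response categories to a binary
    label: complete/partial response -> sensitive; stable/progressive
    disease -> resistant."""
    out = []
    for raw in raw_labels:
        key = " ".join(str(raw).strip().lower().replace("_", " ").split())
        if key in _CDR_SENSITIVE:
            out.append("sensitive")
        elif key in _CDR_RESISTANT:
            out.append("resistant")
        else:
            raise ValueError(f"unrecognized clinical response category: {raw!r}")
    return ResponseTable(sample_ids=list(sample_ids), drug=drug, labels=out)
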