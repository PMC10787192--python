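"""Gene-wise z-scoring and the tissue-informed normalizer.

The transfer problem: a regressor is trained on source-domain (cell-line-like)
expression and applied to target-domain (tumor-like) samples whose expression
sits on a different scale (platform and cohort effects).  Per-gene z-scoring
of each cohort against an appropriate reference removes any per-gene affine
shift between domains.  Three reference choices are supported:

``tissue_informed``
    Target samples are normalized against the per-gene moments of an
    *unlabeled pool* of target-domain samples restricted to the tissues in
    which the drug was actually administered, excluding the labeled test
    samples themselves.  This is the method's headline mechanism.
``train_norm``
    Source-fitted moments applied to both cohorts (a default workflow when
    domain discrepancy is ignored).
``test_norm``
    Each cohort z-scored against itself.

Population standard deviations (ddof=0) are used throughout so that the
source and target scalings are directly comparable.  Zero-variance genes are
flagged and treated as sigma = 1 (pure centering) rather than dropped, which
keeps train/test gene sets aligned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

logger = logging.getLogger(__name__)

MODES = ("tissue_informed", "train_norm", "test_norm")


@dataclass
class NormalizerStats:
    """Per-gene location/scale with provenance of the reference pool."""

    gene_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    mode: str = "test_norm"
    reference_pool: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.gene_ids)
        if self.mu.shape != (n,) or self.sigma.shape != (n,):
            raise ValueError("mu/sigma must align with gene_ids")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of zero-variance genes (sigma treated as 1)."""
        return self.sigma == 0.0

    def to_table(self, path: str | Path) -> None:
        df = pd.DataFrame({"gene": self.gene_ids, "mu": self.mu,
                           "sigma": self.sigma, "flagged": self.flagged})
        path = Path(path)
        df.to_csv(path, sep="\t", index=False)
        prov = {"mode": self.mode, "reference_pool": self.reference_pool}
        path.with_name(path.name + ".meta.json").write_text(json.dumps(prov, indent=1))

    @classmethod
    def from_table(cls, path: str | Path) -> "NormalizerStats":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta_path = path.with_name(path.name + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(gene_ids=df["gene"].astype(str).tolist(),
                   mu=df["mu"].values, sigma=df["sigma"].values,
                   mode=meta.get("mode", "test_norm"),
                   reference_pool=meta.get("reference_pool", {}))


@dataclass
class LabelNormalizer:
    """Drug-wise ln IC50 z-scoring (population sd) with inverse transform."""

    drug: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("label sigma must be positive (constant labels?)")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mu) / self.sigma

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sigma + self.mu


def _moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return values.mean(axis=0), values.std(axis=0, ddof=0)


def fit_zscore(matrix: ExpressionMatrix, mode: str = "test_norm") -> NormalizerStats:
    """Per-gene mean and population sd of the supplied matrix."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a normalizer")
    mu, sigma = _moments(matrix.values)
    n_flagged = int((sigma == 0).sum())
    if n_flagged:
        logger.warning("%d zero-variance gene(s) flagged; sigma treated as 1",
                       n_flagged)
    return NormalizerStats(
        gene_ids=list(matrix.gene_ids), mu=mu, sigma=sigma, mode=mode,
        reference_pool={"cohort": matrix.domain, "n_samples": matrix.n_samples})


def fit_tissue_informed(unlabeled_target: ExpressionMatrix,
                        target_tissues: Sequence[str],
                        exclude_samples: Sequence[str] = ()) -> NormalizerStats:
    """Fit target-domain moments on an unlabeled pool restricted to the
    drug's administered tissues, excluding held-out test samples by id."""
    if unlabeled_target.tissue is None:
        raise ValueError("unlabeled pool must carry tissue labels")
    tissues = {str(t) for t in target_tissues}
    excluded = {str(s) for s in exclude_samples}
    present = set(unlabeled_target.tissue)
    for t in sorted(tissues - present):
        logger.warning("tissue %r in the drug's tissue set is absent from the pool", t)
    keep = [s for s, t in zip(unlabeled_target.sample_ids, unlabeled_target.tissue)
            if t in tissues and s not in excluded]
    if not keep:
        raise ValueError("reference pool is empty after tissue/id filtering")
    pool = unlabeled_target.subset_samples(keep)
    mu, sigma = _moments(pool.values)
    if (sigma == 0).any():
        logger.warning("%d zero-variance gene(s) in tissue-informed pool",
                       int((sigma == 0).sum()))
    return NormalizerStats(
        gene_ids=list(pool.gene_ids), mu=mu, sigma=sigma, mode="tissue_informed",
        reference_pool={"cohort": unlabeled_target.domain,
                        "tissues": sorted(tissues),
                        "n_samples": len(keep),
                        "excluded_samples": sorted(excluded)})


def apply_normalizer(matrix: ExpressionMatrix, stats: NormalizerStats
                     ) -> ExpressionMatrix:
    """z-score each gene: x = (x_raw - mu) / sigma, sigma=1 for flagged genes."""
    if list(matrix.gene_ids) != list(stats.gene_ids):
        missing = sorted(set(stats.gene_ids) - set(matrix.gene_ids))
        extra = sorted(set(matrix.gene_ids) - set(stats.gene_ids))
        if missing or extra:
            raise ValueError(f"gene mismatch; missing={missing[:5]} extra={extra[:5]}")
        # same set, different order: align stats to the matrix order
        order = {g: i for i, g in enumerate(stats.gene_ids)}
        idx = [order[g] for g in matrix.gene_ids]
        stats = NormalizerStats(gene_ids=list(matrix.gene_ids),
                                mu=stats.mu[idx], sigma=stats.sigma[idx],
                                mode=stats.mode, reference_pool=stats.reference_pool)
    if matrix.has_transform("zscore"):
        raise ValueError("matrix already z-scored (idempotence guard)")
    denom = np.where(stats.sigma == 0.0, 1.0, stats.sigma)
    out = matrix.subset_genes(matrix.gene_ids)
    out.values = (out.values - stats.mu) / denom
    out.record_transform("zscore")
    out.metadata["units"] = "zscore"
    out.metadata["normalizer_mode"] = stats.mode
    return out


def normalize_labels(values: np.ndarray, drug: str
                     ) -> tuple[np.ndarray, LabelNormalizer]:
    """Drug-wise z-scoring of continuous ln IC50 labels."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("labels are constant; cannot z-score")
    norm = LabelNormalizer(drug=drug, mu=float(values.mean()),
                           sigma=float(values.std(ddof=0)))
    return norm.transform(values), norm
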