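"""Evaluation statistics for rank-based transfer assessment.

The target cohort carries only binary sensitive/resistant labels while the
model predicts a continuous (normalized) ln IC50, so evaluation is rank
based: a one-sided Mann-Whitney U test of whether resistant patients receive
higher predictions than sensitive ones, Fisher's method for combining per-drug
P values, AUROC, and precision at the k-th percentile of the prediction
distribution.  Residual domain discrepancy is quantified as the Ward merge
cost between the source and target sample groups in the model's latent space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .predictor import LatentEmbedding

SENSITIVE, RESISTANT = "sensitive", "resistant"


def _split(preds: np.ndarray, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if preds.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels must align")
    bad = sorted(set(labels) - {SENSITIVE, RESISTANT})
    if bad:
        raise ValueError(f"unknown labels: {bad}")
    return preds[labels == SENSITIVE], preds[labels == RESISTANT]


def mann_whitney_one_sided(resistant_preds: Sequence[float],
                           sensitive_preds: Sequence[float]
                           ) -> tuple[float, float]:
    """U statistic and one-sided P for resistant predictions being
    stochastically greater than sensitive ones.

    Exact enumeration when the pooled size is at most 12 and there are no
    ties; normal approximation with tie correction otherwise.
    """
    r = np.asarray(resistant_preds, dtype=float)
    s = np.asarray(sensitive_preds, dtype=float)
    if r.size == 0 or s.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([r, s])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(r, s, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_combined(pvalues: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: X = -2*sum(ln p) against chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one P value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P values must lie in (0, 1]")
    statistic, combined = stats.combine_pvalues(p, method="fisher")
    return float(statistic), float(combined)


def precision_at_percentile(preds: Sequence[float], labels: Sequence[str],
                            k: float) -> dict:
    """Precision among samples predicted most sensitive.

    t_k is the k-th percentile of the predictions (linear interpolation);
    samples with predictions strictly below t_k are called sensitive.
    Returns t_k, TP, FP and precision (NaN, flagged, when nothing falls
    below the threshold).
    """
    if not 0 < k <= 50:
        raise ValueError("k must lie in (0, 50]")
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    _split(preds, labels)                 # validates alignment and label values
    t_k = float(np.percentile(preds, k))
    below = preds < t_k
    tp = int(np.sum(below & (labels == SENSITIVE)))
    fp = int(np.sum(below & (labels == RESISTANT)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return {"k": float(k), "t_k": t_k, "TP": tp, "FP": fp,
            "precision": precision, "empty": (tp + fp) == 0}


def auroc(preds: Sequence[float], labels: Sequence[str]) -> float:
    """AUROC for recovering sensitivity from predicted ln IC50.

    Positive class = sensitive; ranking score = -prediction, so a model
    that assigns lower ln IC50 to sensitive samples scores above 0.5.
    Ties count half.  Equals the Mann-Whitney U of the resistant group
    divided by n_sensitive * n_resistant.
    """
    s, r = _split(np.asarray(preds, dtype=float), labels)
    if s.size == 0 or r.size == 0:
        raise ValueError("both classes must be present")
    u_res = stats.mannwhitneyu(r, s, alternative="greater",
                               method="asymptotic").statistic
    return float(u_res) / (s.size * r.size)


def domain_distance(source_emb: LatentEmbedding, target_emb: LatentEmbedding
                    ) -> float:
    """Ward merge cost between the source and target groups in latent space.

    The increase in within-cluster sum of squares when merging the two
    groups: (n1*n2 / (n1+n2)) * ||c1 - c2||^2 with c the group centroids.
    """
    a, b = source_emb.vectors, target_emb.vectors
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("embedding widths differ")
    n1, n2 = a.shape[0], b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)
    return float(n1 * n2 / (n1 + n2) * np.dot(diff, diff))


def domain_distance_per_member(model, source_matrix, target_matrix,
                               ci: float = 95.0) -> dict:
    """Ward distance per ensemble member with mean and percentile CI."""
    dists = [domain_distance(model.embed(source_matrix, member=k),
                             model.embed(target_matrix, member=k))
             for k in range(model.n_members)]
    lo, hi = np.percentile(dists, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return {"per_member": dists, "mean": float(np.mean(dists)),
            "ci": (float(lo), float(hi)), "ci_level": ci}


@dataclass
class EvalReport:
    """Per-drug evaluation summary."""

    drug: str
    u_statistic: float
    p_value: float
    auroc: float
    precision_table: list[dict] = field(default_factory=list)
    domain_distance: dict | None = None
    n_sensitive: int = 0
    n_resistant: int = 0
    conventions: dict = field(default_factory=lambda: {
        "percentile": "linear interpolation; strictly below t_k is positive",
        "auroc": "score = -prediction, positive class = sensitive",
    })

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.precision_table)


def evaluate_predictions(preds: Sequence[float], labels: Sequence[str],
                         drug: str = "drug",
                         percentiles: Sequence[float] = (10, 20, 30, 40, 50),
                         domain_dist: dict | None = None) -> EvalReport:
    """Assemble the full rank-based evaluation for one drug."""
    s, r = _split(np.asarray(preds, dtype=float), labels)
    u, p = mann_whitney_one_sided(r, s)
    return EvalReport(
        drug=drug, u_statistic=u, p_value=p, auroc=auroc(preds, labels),
        precision_table=[precision_at_percentile(preds, labels, k)
                         for k in percentiles],
        domain_distance=domain_dist,
        n_sensitive=int(s.size), n_resistant=int(r.size))
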