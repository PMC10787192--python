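"""Knee-point detection on sorted gene-score curves.

Given per-drug gene scores sorted in descending order, the panel cutoff is
the "knee" — the point of maximum curvature of the rank-vs-score curve.  The
kneedle construction is used: both axes are rescaled to [0, 1], a line l is
drawn from the first point (rank 1, highest score) to the last (rank n,
lowest score), and the difference curve d_i = l(i) - score_i is computed
(equivalent to rotating the curve so l becomes horizontal).  Local maxima of
d are knee candidates; the candidate farthest from l is the knee, with ties
broken toward the smallest rank so the selected panel is the more
conservative one.  The knee gene itself is included in the panel.

A curve with max d below a flatness tolerance (e.g. perfectly linear decay)
has no knee, as does a curve with fewer than 3 points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FLATNESS_TOL = 1e-9


@dataclass
class KneeResult:
    """Outcome of knee detection on a descending score curve."""

    scores: np.ndarray                   # descending
    gene_ids: list[str] | None
    knee_rank: int | None                # 1-based; None when no knee
    difference: np.ndarray               # normalized distance-from-line curve
    flag: str | None = None              # "too_short" | "flat" | None

    @property
    def has_knee(self) -> bool:
        return self.knee_rank is not None

    @property
    def selected_gene_ids(self) -> list[str]:
        if self.gene_ids is None or self.knee_rank is None:
            return []
        return list(self.gene_ids[: self.knee_rank])

    def to_table(self, path: str | Path) -> None:
        n = len(self.scores)
        df = pd.DataFrame({
            "rank": np.arange(1, n + 1),
            "gene": self.gene_ids if self.gene_ids is not None else [""] * n,
            "score": self.scores,
            "selected": [self.knee_rank is not None and r <= self.knee_rank
                         for r in range(1, n + 1)],
        })
        df.to_csv(Path(path), sep="\t", index=False)


def find_knee(scores: Sequence[float],
              gene_ids: Sequence[str] | None = None,
              flatness_tol: float = FLATNESS_TOL) -> KneeResult:
    """Locate the knee of a non-increasing score curve.

    Raises on unsorted input; returns a flagged no-knee result for fewer
    than 3 points or a flat/collinear curve.
    """
    y = np.asarray(scores, dtype=float)
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("scores must be sorted in non-increasing order")
    ids = None if gene_ids is None else [str(g) for g in gene_ids]
    if ids is not None and len(ids) != len(y):
        raise ValueError("gene_ids must align with scores")
    n = len(y)
    if n < 3:
        return KneeResult(scores=y, gene_ids=ids, knee_rank=None,
                          difference=np.zeros(n), flag="too_short")

    x_norm = np.linspace(0.0, 1.0, n)
    span = y[0] - y[-1]
    if span <= 0:
        return KneeResult(scores=y, gene_ids=ids, knee_rank=None,
                          difference=np.zeros(n), flag="flat")
    y_norm = (y - y[-1]) / span
    line = 1.0 - x_norm                   # from (0, 1) to (1, 0) in normalized axes
    d = line - y_norm

    interior = np.arange(1, n - 1)
    is_local_max = (d[interior] >= d[interior - 1]) & (d[interior] >= d[interior + 1])
    candidates = interior[is_local_max]
    if candidates.size == 0 or d[candidates].max() <= flatness_tol:
        return KneeResult(scores=y, gene_ids=ids, knee_rank=None,
                          difference=d, flag="flat")
    best = candidates[np.argmax(d[candidates])]   # argmax returns first = smallest rank
    return KneeResult(scores=y, gene_ids=ids, knee_rank=int(best) + 1,
                      difference=d, flag=None)


def select_panel(scores: "DrugGeneScores", flatness_tol: float = FLATNESS_TOL
                 ) -> KneeResult:
    """Rank aggregated drug-gene scores and cut the panel at the knee."""
    ranked = scores.ranked()
    return find_knee(ranked["score"].values, ranked["gene"].tolist(),
                     flatness_tol=flatness_tol)
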