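"""Masking-based contribution scores and their distillation into explainer
networks.

The attribution follows a Granger-style argument: a gene contributes to a
prediction to the extent that removing it (zeroing its normalized value)
degrades the trained predictor's accuracy.  For a sample X with true label
y and ensemble-mean prediction yhat, the squared error is

    eps_X = (y - yhat)^2

and for each gene i, eps_{X\\{i}} is the same error with feature i zeroed
out.  The per-gene contribution is the normalized error increase

    omega_i = delta_i / sum_j delta_j,   delta_i = eps_{X\\{i}} - eps_X

so each sample's contribution vector lies on the probability simplex.
Negative deltas (masking that *reduces* error) are clamped to zero before
normalization by default; if every delta is zero the uniform vector is
returned and flagged.

Because computing these targets needs p+1 forward passes per sample, they
are distilled into small "explainer" networks (two 512-unit ReLU layers and
a softmax head by default) trained to minimize KL(target || prediction) over
the training cohort.  An ensemble of independently seeded explainers is
trained and their per-gene medians (renormalized to the simplex) are the
final per-sample scores, which are then averaged across the labeled test
samples and scaled so the top gene of each drug scores exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .nn import DenseNet
from .predictor import TrainedPredictor

logger = logging.getLogger(__name__)


@dataclass
class ContributionSet:
    """Per-sample contribution vectors on the probability simplex."""

    sample_ids: list[str]
    gene_ids: list[str]
    omega: np.ndarray                    # samples x genes, rows sum to 1
    kind: str = "target"                 # "target" (masking) or "predicted"
    eps: np.ndarray | None = None        # per-sample base error (targets only)
    deltas: np.ndarray | None = None     # raw error increases (targets only)
    uniform_fallback: np.ndarray | None = None   # samples where all deltas were 0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        n, p = len(self.sample_ids), len(self.gene_ids)
        if self.omega.shape != (n, p):
            raise ValueError("omega shape must be (n_samples, n_genes)")
        if np.any(self.omega < -1e-12):
            raise ValueError("contributions must be nonnegative")
        sums = self.omega.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each contribution vector must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class DrugGeneScores:
    """Per-drug aggregated gene scores, scaled so the top gene scores 1."""

    gene_ids: list[str]
    scores: np.ndarray
    drug: str = "drug"
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids),):
            raise ValueError("scores must align with gene_ids")
        if np.any(self.scores < 0) or not np.isclose(self.scores.max(), 1.0):
            raise ValueError("scores must lie in [0, 1] with max exactly 1")

    def ranked(self) -> pd.DataFrame:
        """Genes sorted by descending score with 1-based ranks."""
        order = np.argsort(-self.scores, kind="stable")
        return pd.DataFrame({
            "rank": np.arange(1, len(order) + 1),
            "gene": [self.gene_ids[i] for i in order],
            "score": self.scores[order],
        })

    def to_table(self, path: str | Path) -> None:
        self.ranked().to_csv(Path(path), sep="\t", index=False)


@dataclass
class ExplainerEnsemble:
    """Independently seeded simplex-output networks distilled from masking
    contributions; scored by per-gene median."""

    members: list[DenseNet]
    gene_ids: list[str]
    base_seed: int = 0
    train_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("need at least one explainer")
        for m in self.members:
            if m.n_in != len(self.gene_ids) or m.n_out != len(self.gene_ids):
                raise ValueError("explainer input/output width must equal gene count")


def _masked_errors(model: TrainedPredictor, X: np.ndarray, y: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Base errors eps (n,) and masked errors (n, p): gene j zeroed column-wise."""
    yhat = model.predict(X)
    if not np.all(np.isfinite(yhat)):
        raise FloatingPointError("non-finite ensemble prediction")
    eps = (y - yhat) ** 2
    n, p = X.shape
    masked = np.empty((n, p))
    for j in range(p):
        Xm = X.copy()
        Xm[:, j] = 0.0
        masked[:, j] = (y - model.predict(Xm)) ** 2
    return eps, masked


def granger_contributions(model: TrainedPredictor,
                          X: np.ndarray | ExpressionMatrix,
                          y: np.ndarray,
                          sample_ids: Sequence[str] | None = None,
                          clamp_negative: bool = True) -> ContributionSet:
    """Masking-based contribution targets for one or more normalized samples.

    ``X`` is on the normalized scale (so masking to 0 sets a gene to its
    reference-pool mean) and ``y`` on the normalized label scale.
    """
    if isinstance(X, ExpressionMatrix):
        sample_ids = list(X.sample_ids)
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n, p = X.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    eps, masked = _masked_errors(model, X, y)
    deltas = masked - eps[:, None]
    work = np.clip(deltas, 0.0, None) if clamp_negative else deltas
    totals = work.sum(axis=1)
    fallback = totals <= 0.0
    if fallback.any():
        logger.warning("%d sample(s) had no positive masking delta; "
                       "uniform contributions returned", int(fallback.sum()))
    omega = np.where(fallback[:, None], 1.0 / p,
                     work / np.where(totals == 0.0, 1.0, totals)[:, None])
    return ContributionSet(sample_ids=list(sample_ids),
                           gene_ids=list(model.gene_ids), omega=omega,
                           kind="target", eps=eps, deltas=deltas,
                           uniform_fallback=fallback)


def train_explainer(model: TrainedPredictor, X: np.ndarray, y: np.ndarray,
                    n_explainers: int = 10, hidden: int = 512, layers: int = 2,
                    epochs: int = 150, batch_size: int = 32,
                    learning_rate: float = 1e-3, base_seed: int = 0,
                    targets: ContributionSet | None = None
                    ) -> ExplainerEnsemble:
    """Distill masking contributions into an ensemble of simplex networks.

    Computes the contribution targets for every training sample (unless a
    precomputed ``targets`` set is passed) and fits ``n_explainers``
    independently seeded networks minimizing KL(target || prediction).
    """
    X = np.asarray(X, dtype=float)
    if targets is None:
        targets = granger_contributions(model, X, y)
    omega = targets.omega
    if np.allclose(omega, omega[0]) and np.allclose(omega[0], 1.0 / omega.shape[1]):
        logger.warning("all contribution targets are uniform; explainer will "
                       "learn a constant map")
    members = []
    for k in range(n_explainers):
        net = DenseNet(n_in=X.shape[1], hidden=(hidden,) * layers,
                       n_out=X.shape[1], dropout=0.0, output="softmax",
                       seed=base_seed + k)
        net.fit(X, omega, epochs=epochs, batch_size=batch_size,
                learning_rate=learning_rate)
        members.append(net)
    return ExplainerEnsemble(members=members, gene_ids=list(model.gene_ids),
                             base_seed=base_seed,
                             train_info={"epochs": epochs, "batch_size": batch_size,
                                         "learning_rate": learning_rate,
                                         "hidden": hidden, "layers": layers})


def score_samples(explainers: ExplainerEnsemble,
                  test: ExpressionMatrix | np.ndarray,
                  sample_ids: Sequence[str] | None = None) -> ContributionSet:
    """Predicted contributions for test samples: per-gene median across
    explainers, renormalized to the simplex."""
    if isinstance(test, ExpressionMatrix):
        if list(test.gene_ids) != list(explainers.gene_ids):
            raise ValueError("test gene order does not match the explainer")
        sample_ids = list(test.sample_ids)
        X = test.values
    else:
        X = np.atleast_2d(np.asarray(test, dtype=float))
        if X.shape[1] != len(explainers.gene_ids):
            raise ValueError("input width does not match the explainer")
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(X.shape[0])]
    preds = np.stack([m.predict(X) for m in explainers.members])   # k x n x p
    med = np.median(preds, axis=0)
    med /= med.sum(axis=1, keepdims=True)
    return ContributionSet(sample_ids=list(sample_ids),
                           gene_ids=list(explainers.gene_ids),
                           omega=med, kind="predicted")


def aggregate_scores(scores: ContributionSet,
                     labeled_sample_ids: Sequence[str] | None = None,
                     drug: str = "drug") -> DrugGeneScores:
    """Per-drug gene scores: mean contribution over labeled test samples,
    scaled so the largest score equals 1."""
    if labeled_sample_ids is None:
        labeled_sample_ids = scores.sample_ids
    labeled_sample_ids = [str(s) for s in labeled_sample_ids]
    if not labeled_sample_ids:
        raise ValueError("empty labeled sample set")
    idx = {s: i for i, s in enumerate(scores.sample_ids)}
    missing = [s for s in labeled_sample_ids if s not in idx]
    if missing:
        raise KeyError(f"scores missing for samples: {missing[:10]}")
    rows = [idx[s] for s in labeled_sample_ids]
    mean = scores.omega[rows].mean(axis=0)
    return DrugGeneScores(gene_ids=list(scores.gene_ids),
                          scores=mean / mean.max(), drug=drug,
                          n_samples=len(rows))
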