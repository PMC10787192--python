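"""Dense-network ln IC50 regressor: tuning, ensemble training, prediction,
and latent-embedding extraction.

The regressor maps a z-scored expression vector (one node per gene) through
three ReLU hidden layers — 512, 256 and 128 units by default — with a single
dropout layer (p = 0.2) between the last hidden layer and the linear output
node, trained on MSE against drug-wise z-scored ln IC50 labels.

Hyperparameters (batch size, learning rate, and the number of epochs via
early stopping) are chosen by grid search with k-fold cross-validation on the
source cohort only, maximizing the mean Pearson correlation between
validation-fold predictions and labels.  Training during tuning is capped at
1000 epochs with early stopping once the validation loss has not improved for
30 epochs.  The final model is an ensemble of K independently trained members
(distinct seeds, identical architecture) whose predictions are averaged;
since final training uses all labeled samples and therefore has no validation
set, each member trains for the median early-stopped epoch count observed
across the tuning folds of the chosen grid point.

The 128-unit last hidden layer doubles as the model's latent space ("encoder"
representation) used for measuring residual domain discrepancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import ExpressionMatrix, PipelineConfig
from .nn import DenseNet, FitResult
from .normalization import LabelNormalizer


@dataclass
class LatentEmbedding:
    """Last-hidden-layer activations per sample."""

    sample_ids: list[str]
    vectors: np.ndarray                  # samples x d
    member: int | str = "averaged"       # member index or "averaged"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.sample_ids):
            raise ValueError("embedding rows must align with sample_ids")

    @property
    def width(self) -> int:
        return self.vectors.shape[1]


@dataclass
class TrainedPredictor:
    """Mean-aggregated ensemble of identically shaped dense regressors."""

    members: list[DenseNet]
    gene_ids: list[str]
    hyperparams: dict
    label_normalizer: LabelNormalizer | None = None
    base_seed: int = 0
    fit_results: list[FitResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        arch = {(m.n_in, m.hidden, m.n_out) for m in self.members}
        if len(arch) != 1:
            raise ValueError("ensemble members must share one architecture")
        if self.members[0].n_in != len(self.gene_ids):
            raise ValueError("input width must equal the number of genes")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def hidden(self) -> tuple[int, ...]:
        return self.members[0].hidden

    def _values(self, matrix: ExpressionMatrix | np.ndarray) -> np.ndarray:
        if isinstance(matrix, ExpressionMatrix):
            if list(matrix.gene_ids) != list(self.gene_ids):
                raise ValueError("gene order does not match the trained model")
            return matrix.values
        X = np.asarray(matrix, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.gene_ids):
            raise ValueError("input width does not match the trained model")
        return X

    def member_predictions(self, matrix) -> np.ndarray:
        """Per-member predictions, shape (n_members, n_samples)."""
        X = self._values(matrix)
        return np.stack([m.predict(X) for m in self.members])

    def predict(self, matrix) -> np.ndarray:
        """Ensemble prediction: arithmetic mean over members (normalized
        ln IC50 scale; dropout disabled)."""
        return self.member_predictions(matrix).mean(axis=0)

    def predict_ln_ic50(self, matrix) -> np.ndarray:
        """Predictions mapped back to the original ln IC50 scale."""
        if self.label_normalizer is None:
            raise ValueError("no label normalizer attached")
        return self.label_normalizer.inverse(self.predict(matrix))

    def embed(self, matrix, member: int | str = "averaged") -> LatentEmbedding:
        """Latent representation: post-ReLU last-hidden-layer activations.

        ``member`` selects one ensemble member by index, or ``"averaged"``
        for the member-mean embedding.
        """
        X = self._values(matrix)
        ids = (list(matrix.sample_ids) if isinstance(matrix, ExpressionMatrix)
               else [str(i) for i in range(X.shape[0])])
        if member == "averaged":
            vecs = np.mean([m.hidden_activations(X) for m in self.members], axis=0)
        else:
            member = int(member)
            if not 0 <= member < self.n_members:
                raise IndexError(f"member index {member} out of range "
                                 f"[0, {self.n_members})")
            vecs = self.members[member].hidden_activations(X)
        return LatentEmbedding(sample_ids=ids, vectors=vecs, member=member)

    # ---- persistence -------------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        m0 = self.members[0]
        manifest = {
            "gene_ids": self.gene_ids,
            "hidden": list(m0.hidden),
            "dropout": m0.dropout,
            "hyperparams": self.hyperparams,
            "base_seed": self.base_seed,
            "n_members": self.n_members,
            "member_seeds": [m.seed for m in self.members],
            "label_normalizer": (None if self.label_normalizer is None else
                                 {"drug": self.label_normalizer.drug,
                                  "mu": self.label_normalizer.mu,
                                  "sigma": self.label_normalizer.sigma}),
        }
        (model_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for i, m in enumerate(self.members):
            np.savez(model_dir / f"member_{i:02d}.npz", **m.get_weights())

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedPredictor":
        model_dir = Path(model_dir)
        manifest = json.loads((model_dir / "manifest.json").read_text())
        members = []
        for i in range(manifest["n_members"]):
            net = DenseNet(n_in=len(manifest["gene_ids"]),
                           hidden=tuple(manifest["hidden"]), n_out=1,
                           dropout=manifest["dropout"],
                           seed=manifest["member_seeds"][i])
            with np.load(model_dir / f"member_{i:02d}.npz") as z:
                net.set_weights(dict(z))
            members.append(net)
        ln = manifest["label_normalizer"]
        return cls(members=members, gene_ids=manifest["gene_ids"],
                   hyperparams=manifest["hyperparams"],
                   label_normalizer=None if ln is None else LabelNormalizer(**ln),
                   base_seed=manifest["base_seed"])


def _kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::folds] for i in range(folds)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def tune_hyperparameters(X: np.ndarray, y: np.ndarray,
                         config: PipelineConfig,
                         folds: int | None = None) -> dict:
    """Grid search with k-fold CV maximizing mean validation Pearson r.

    Returns the winning grid point augmented with ``epochs`` — the median
    early-stopped best epoch across its folds — and ``cv_pearson_r``.  Fold
    assignment is seeded by ``config.base_seed`` and reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = config.cv_folds if folds is None else folds
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    grid = config.grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    fold_idx = _kfold_indices(n, folds, config.base_seed)

    best: dict | None = None
    best_r = -np.inf
    for gi, point in enumerate(grid):
        rs, best_epochs = [], []
        for fi, val_idx in enumerate(fold_idx):
            train_mask = np.ones(n, dtype=bool)
            train_mask[val_idx] = False
            net = DenseNet(n_in=X.shape[1], hidden=config.hidden, n_out=1,
                           dropout=config.dropout,
                           seed=config.base_seed + 1000 * gi + fi)
            try:
                res = net.fit(X[train_mask], y[train_mask],
                              epochs=config.max_epochs,
                              batch_size=point["batch_size"],
                              learning_rate=point["learning_rate"],
                              patience=config.patience,
                              X_val=X[val_idx], Y_val=y[val_idx])
            except FloatingPointError:
                rs.append(np.nan)
                continue
            rs.append(_pearson(net.predict(X[val_idx]), y[val_idx]))
            best_epochs.append(res.best_epoch)
        mean_r = np.nanmean(rs) if np.any(np.isfinite(rs)) else np.nan
        if np.isfinite(mean_r) and mean_r > best_r:
            best_r = mean_r
            best = dict(point)
            best["epochs"] = int(np.median(best_epochs)) if best_epochs else 1
            best["cv_pearson_r"] = float(mean_r)
    if best is None:
        raise RuntimeError("every grid point produced undefined validation "
                           "correlation (constant or non-finite predictions)")
    return best


def train_ensemble(X: np.ndarray, y: np.ndarray, hyperparams: dict,
                   K: int = 10, base_seed: int = 0,
                   hidden: tuple[int, ...] = (512, 256, 128),
                   dropout: float = 0.2,
                   gene_ids: list[str] | None = None,
                   label_normalizer: LabelNormalizer | None = None
                   ) -> TrainedPredictor:
    """Train K members independently on all labeled samples (seed =
    base_seed + member index) and aggregate by mean."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(X.shape[1])]
    members, results = [], []
    for k in range(K):
        net = DenseNet(n_in=X.shape[1], hidden=tuple(hidden), n_out=1,
                       dropout=dropout, seed=base_seed + k)
        try:
            res = net.fit(X, y, epochs=int(hyperparams["epochs"]),
                          batch_size=int(hyperparams["batch_size"]),
                          learning_rate=float(hyperparams["learning_rate"]))
        except FloatingPointError as exc:
            raise FloatingPointError(f"member {k}: {exc}") from exc
        members.append(net)
        results.append(res)
    return TrainedPredictor(members=members, gene_ids=list(gene_ids),
                            hyperparams=dict(hyperparams),
                            label_normalizer=label_normalizer,
                            base_seed=base_seed, fit_results=results)
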