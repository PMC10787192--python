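"""Minimal fully-connected networks on numpy.

The pipeline's models are small dense nets (a few hundred inputs, up to three
hidden layers), trained with Adam on MSE (regressor) or KL divergence against
simplex targets (explainer).  At this scale a vectorized numpy implementation
trains in seconds on one CPU and gives exact control over seeding, dropout
placement, and hidden-layer extraction.

Conventions
-----------
* ReLU activations on all hidden layers; He-normal initialization.
* Inverted dropout on the last hidden layer only (i.e. immediately before the
  output layer), active only during training.
* ``output="linear"`` for regression (MSE loss), ``output="softmax"`` for
  simplex prediction (KL(target || prediction) loss with epsilon smoothing).
* All randomness (init, shuffling, dropout masks) flows from the seed given
  at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KL_EPS = 1e-8


@dataclass
class FitResult:
    """Training trace: per-epoch losses and the early-stopping bookkeeping."""

    epochs_run: int
    best_epoch: int                      # 1-based epoch with the lowest monitored loss
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] | None = None
    stopped_early: bool = False


class DenseNet:
    """Feed-forward net: input -> hidden ReLU stack -> (dropout) -> output."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int = 1,
                 dropout: float = 0.0, output: str = "linear", seed: int = 0):
        if output not in ("linear", "softmax"):
            raise ValueError(f"unknown output head {output!r}")
        self.n_in = int(n_in)
        self.hidden = tuple(int(h) for h in hidden)
        self.n_out = int(n_out)
        self.dropout = float(dropout)
        self.output = output
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        dims = [self.n_in, *self.hidden, self.n_out]
        self.W = [self.rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                                  size=(dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # ---- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool = False):
        """Return (output, hidden_activations, caches-for-backprop)."""
        acts = []
        h = X
        pre = []
        for i in range(len(self.hidden)):
            z = h @ self.W[i] + self.b[i]
            h = np.maximum(z, 0.0)
            pre.append(z)
            acts.append(h)
        drop_mask = None
        h_dropped = h
        if training and self.dropout > 0.0 and self.hidden:
            drop_mask = (self.rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h_dropped = h * drop_mask
        z_out = h_dropped @ self.W[-1] + self.b[-1]
        if self.output == "softmax":
            z_shift = z_out - z_out.max(axis=1, keepdims=True)
            e = np.exp(z_shift)
            out = e / e.sum(axis=1, keepdims=True)
        else:
            out = z_out
        cache = (X, pre, acts, drop_mask, h_dropped)
        return out, acts, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout disabled)."""
        out, _, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return out[:, 0] if (self.output == "linear" and self.n_out == 1) else out

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """Post-ReLU activations of the last hidden layer (pre-dropout)."""
        if not self.hidden:
            raise ValueError("network has no hidden layers")
        _, acts, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return acts[-1]

    # ---- loss & backward ---------------------------------------------------

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        out, _, _ = self._forward(X, training=False)
        return self._loss_value(out, Y)

    def _loss_value(self, out: np.ndarray, Y: np.ndarray) -> float:
        if self.output == "linear":
            diff = out - Y
            return float(np.mean(diff * diff))
        # mean over samples of KL(target || prediction), epsilon-smoothed
        t = Y + KL_EPS
        p = out + KL_EPS
        return float(np.mean(np.sum(Y * (np.log(t) - np.log(p)), axis=1)))

    def _backward(self, cache, out: np.ndarray, Y: np.ndarray):
        X, pre, acts, drop_mask, h_dropped = cache
        n = X.shape[0]
        if self.output == "linear":
            delta = 2.0 * (out - Y) / (n * Y.shape[1])
        else:
            # d/dlogits of mean KL(t||softmax(logits)) = (softmax - t)/n
            delta = (out - Y) / n
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gW[-1] = h_dropped.T @ delta
        gb[-1] = delta.sum(axis=0)
        grad_h = delta @ self.W[-1].T
        if drop_mask is not None:
            grad_h = grad_h * drop_mask
        for i in range(len(self.hidden) - 1, -1, -1):
            grad_z = grad_h * (pre[i] > 0.0)
            inp = X if i == 0 else acts[i - 1]
            gW[i] = inp.T @ grad_z
            gb[i] = grad_z.sum(axis=0)
            if i > 0:
                grad_h = grad_z @ self.W[i].T
        return gW, gb

    def _adam_step(self, gW, gb, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in (*self.W, *self.b)]
            self._adam_v = [np.zeros_like(p) for p in (*self.W, *self.b)]
        self._adam_t += 1
        t = self._adam_t
        params = [*self.W, *self.b]
        grads = [*gW, *gb]
        for k, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # ---- training loop -----------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray, *, epochs: int,
            batch_size: int, learning_rate: float,
            patience: int | None = None,
            X_val: np.ndarray | None = None,
            Y_val: np.ndarray | None = None) -> FitResult:
        """Minibatch Adam training with optional early stopping.

        Early stopping monitors the validation loss when a validation set is
        supplied, otherwise the full-data training loss; training stops when
        the monitored loss has not improved for ``patience`` epochs.  The
        parameters from the best monitored epoch are restored on exit.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            Y_val = np.asarray(Y_val, dtype=float)
            if Y_val.ndim == 1:
                Y_val = Y_val[:, None]
        n = X.shape[0]
        batch_size = min(int(batch_size), n)

        best_loss = np.inf
        best_epoch = 0
        best_params = None
        result = FitResult(epochs_run=0, best_epoch=0,
                           val_loss=[] if X_val is not None else None)
        for epoch in range(1, epochs + 1):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                out, _, cache = self._forward(X[idx], training=True)
                if not np.all(np.isfinite(out)):
                    raise FloatingPointError(
                        f"non-finite network output at epoch {epoch} "
                        f"(learning rate too high?)")
                gW, gb = self._backward(cache, out, Y[idx])
                self._adam_step(gW, gb, learning_rate)
            train_loss = self.loss(X, Y)
            result.train_loss.append(train_loss)
            monitored = train_loss
            if X_val is not None:
                val_loss = self.loss(X_val, Y_val)
                result.val_loss.append(val_loss)
                monitored = val_loss
            result.epochs_run = epoch
            if np.isfinite(monitored) and monitored < best_loss:
                best_loss = monitored
                best_epoch = epoch
                best_params = ([w.copy() for w in self.W],
                               [b.copy() for b in self.b])
            if patience is not None and epoch - best_epoch >= patience:
                result.stopped_early = True
                break
        if best_params is None:
            raise FloatingPointError("training never produced a finite loss")
        self.W, self.b = best_params
        result.best_epoch = best_epoch
        return result

    # ---- (de)serialization -------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        d = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            d[f"W{i}"] = w
            d[f"b{i}"] = b
        return d

    def set_weights(self, d: dict[str, np.ndarray]) -> None:
        for i in range(len(self.W)):
            w, b = np.asarray(d[f"W{i}"]), np.asarray(d[f"b{i}"])
            if w.shape != self.W[i].shape or b.shape != self.b[i].shape:
                raise ValueError(f"weight shape mismatch at layer {i}")
            self.W[i] = w.astype(float)
            self.b[i] = b.astype(float)
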