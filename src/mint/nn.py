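"""Minimal feed-forward network used by the category and score models.

Five weight layers by default (four hidden blocks + output), ReLU or
leaky-ReLU activations, inverted dropout, L2 weight decay, Adam, and
early stopping on a held-out validation split.  Dropout can be kept
active at inference for Monte-Carlo uncertainty estimates.  Everything is
seeded and single-threaded, so training is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionMismatchError

logger = logging.getLogger(__name__)


@dataclass
class MLPConfig:
    hidden_size: int = 256
    n_hidden: int = 4            # hidden blocks; +1 output layer = 5 weight layers
    activation: str = "relu"     # relu | leaky_relu
    leaky_alpha: float = 0.01
    dropout: float = 0.2
    l2: float = 1e-3
    learning_rate: float = 1e-3
    input_norm: bool = True
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 10
    val_fraction: float = 0.2

    def replace(self, **kw) -> "MLPConfig":
        d = {**self.__dict__, **kw}
        return MLPConfig(**d)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


@dataclass
class MLP:
    """Feed-forward net; ``task`` is one of mse | softmax_ce | bce."""

    input_dim: int
    output_dim: int
    task: str = "mse"
    config: MLPConfig = field(default_factory=MLPConfig)
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("mse", "softmax_ce", "bce"):
            raise ValueError(f"unknown task {self.task!r}")
        rng = np.random.default_rng(self.seed)
        sizes = (
            [self.input_dim]
            + [self.config.hidden_size] * self.config.n_hidden
            + [self.output_dim]
        )
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._norm_mean = np.zeros(self.input_dim)
        self._norm_std = np.ones(self.input_dim)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- forward ---------------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.config.activation == "relu":
            return np.maximum(z, 0.0)
        return np.where(z > 0, z, self.config.leaky_alpha * z)

    def _act_grad(self, z: np.ndarray) -> np.ndarray:
        if self.config.activation == "relu":
            return (z > 0).astype(float)
        return np.where(z > 0, 1.0, self.config.leaky_alpha)

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        if not self.config.input_norm:
            return X
        return (X - self._norm_mean) / self._norm_std

    def _forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None):
        """Returns (activations, pre-activations, dropout masks)."""
        p = self.config.dropout
        a = self._normalize(X)
        acts, zs, masks = [a], [], []
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            zs.append(z)
            if li < n_layers - 1:
                a = self._act(z)
                if dropout_rng is not None and p > 0:
                    mask = (dropout_rng.random(a.shape) >= p) / (1.0 - p)
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
            else:
                a = z
            acts.append(a)
        return acts, zs, masks

    def _output(self, z: np.ndarray) -> np.ndarray:
        if self.task == "softmax_ce":
            return _softmax(z)
        if self.task == "bce":
            return _sigmoid(z)
        return z

    def forward(
        self, X: np.ndarray, dropout_rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Deterministic prediction; pass ``dropout_rng`` for a stochastic
        (MC-dropout) forward pass."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise DimensionMismatchError(
                f"expected input dim {self.input_dim}, got {X.shape[1]}"
            )
        acts, zs, _ = self._forward(X, dropout_rng)
        return self._output(zs[-1])

    predict = forward

    # -- training --------------------------------------------------------

    def _loss(self, out: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        if self.task == "mse":
            return float(np.mean((out - y) ** 2))
        if self.task == "softmax_ce":
            return float(-np.mean(np.sum(y * np.log(out + eps), axis=1)))
        return float(
            -np.mean(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps))
        )

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int | None = None,
        weight_decay: float | None = None,
        refit_norm: bool = True,
        rng: np.random.Generator | None = None,
    ) -> "MLP":
        """Train with Adam and early stopping on a held-out split.

        ``weight_decay`` overrides the config L2 for this call (used by
        per-category fine-tuning).  ``epochs=0`` is a no-op.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        max_epochs = self.config.max_epochs if epochs is None else epochs
        if max_epochs == 0:
            return self
        l2 = self.config.l2 if weight_decay is None else weight_decay
        rng = rng or np.random.default_rng(self.seed + 1)

        if refit_norm and self.config.input_norm:
            self._norm_mean = X.mean(axis=0)
            std = X.std(axis=0)
            self._norm_std = np.where(std > 1e-12, std, 1.0)

        n = len(X)
        n_val = int(round(self.config.val_fraction * n)) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        if self.task == "mse" and float(np.std(ytr)) < 1e-12:
            logger.warning("degenerate targets: zero variance in training y")

        m = [np.zeros_like(W) for W in self.weights]
        v = [np.zeros_like(W) for W in self.weights]
        mb = [np.zeros_like(b) for b in self.biases]
        vb = [np.zeros_like(b) for b in self.biases]
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.config.learning_rate
        t = 0

        best_val = np.inf
        best_state = None
        if n_val:
            # the untrained (or pre-fine-tuning) state competes too, so a
            # fine-tune that never improves validation keeps the base weights
            best_val = self._loss(self.forward(Xval), yval)
            best_state = (
                [W.copy() for W in self.weights],
                [b.copy() for b in self.biases],
            )
        bad = 0
        bs = self.config.batch_size
        n_layers = len(self.weights)

        for epoch in range(max_epochs):
            order = rng.permutation(len(Xtr))
            ep_loss = 0.0
            for start in range(0, len(Xtr), bs):
                sel = order[start : start + bs]
                xb, yb = Xtr[sel], ytr[sel]
                acts, zs, masks = self._forward(xb, rng)
                out = self._output(zs[-1])
                ep_loss += self._loss(out, yb) * len(sel)
                B = len(sel)
                # output-layer delta: identical algebra for all three tasks
                if self.task == "mse":
                    delta = 2.0 * (out - yb) / B
                else:
                    delta = (out - yb) / B
                t += 1
                grads_W, grads_b = [None] * n_layers, [None] * n_layers
                for li in range(n_layers - 1, -1, -1):
                    grads_W[li] = acts[li].T @ delta + l2 * self.weights[li]
                    grads_b[li] = delta.sum(axis=0)
                    if li > 0:
                        delta = delta @ self.weights[li].T
                        if masks[li - 1] is not None:
                            delta = delta * masks[li - 1]
                        delta = delta * self._act_grad(zs[li - 1])
                for li in range(n_layers):
                    m[li] = b1 * m[li] + (1 - b1) * grads_W[li]
                    v[li] = b2 * v[li] + (1 - b2) * grads_W[li] ** 2
                    mb[li] = b1 * mb[li] + (1 - b1) * grads_b[li]
                    vb[li] = b2 * vb[li] + (1 - b2) * grads_b[li] ** 2
                    mhat = m[li] / (1 - b1**t)
                    vhat = v[li] / (1 - b2**t)
                    self.weights[li] -= lr * mhat / (np.sqrt(vhat) + eps)
                    mbh = mb[li] / (1 - b1**t)
                    vbh = vb[li] / (1 - b2**t)
                    self.biases[li] -= lr * mbh / (np.sqrt(vbh) + eps)

            self.history["train_loss"].append(ep_loss / max(1, len(Xtr)))
            if n_val:
                val_out = self.forward(Xval)
                val_loss = self._loss(val_out, yval)
                self.history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_state = (
                        [W.copy() for W in self.weights],
                        [b.copy() for b in self.biases],
                    )
                    bad = 0
                else:
                    bad += 1
                    if bad >= self.config.patience:
                        logger.debug("early stop at epoch %d", epoch + 1)
                        break

        if best_state is not None:
            self.weights, self.biases = best_state
        return self

    def copy(self) -> "MLP":
        clone = MLP(
            input_dim=self.input_dim,
            output_dim=self.output_dim,
            task=self.task,
            config=self.config,
            seed=self.seed,
        )
        clone.weights = [W.copy() for W in self.weights]
        clone.biases = [b.copy() for b in self.biases]
        clone._norm_mean = self._norm_mean.copy()
        clone._norm_std = self._norm_std.copy()
        return clone

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"norm_mean": self._norm_mean, "norm_std": self._norm_std}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        self._norm_mean = np.asarray(arrays["norm_mean"])
        self._norm_std = np.asarray(arrays["norm_std"])
        self.weights = [np.asarray(arrays[f"W{i}"]) for i in range(len(self.weights))]
        self.biases = [np.asarray(arrays[f"b{i}"]) for i in range(len(self.biases))]
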