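"""A compact 1-D convolutional network for the 4x12 feature grid.

The 48 features are viewed as 4 lead-channels of 12 ordered features; two
1-D convolutions (8 then 16 channels, kernel 3, valid padding, ReLU) mix
features locally across the per-lead blocks, followed by a dense hidden
layer and a logistic output. Training is full-batch Adam on binary
cross-entropy with early stopping on a held-out validation slice and
restoration of the best weights. Everything is plain numpy and fully
deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError

__all__ = ["ConvNetClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (n, C, L), w (F, C, K), b (F,) -> (n, F, L-K+1)."""
    k = w.shape[2]
    xw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (n,C,Lo,K)
    return np.einsum("nclk,fck->nfl", xw, w) + b[None, :, None]


def _conv1d_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) for :func:`_conv1d_forward`."""
    k = w.shape[2]
    lo = dout.shape[2]
    xw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    dw = np.einsum("nclk,nfl->fck", xw, dout)
    db = dout.sum(axis=(0, 2))
    dx = np.zeros_like(x)
    for j in range(k):
        dx[:, :, j:j + lo] += np.einsum("nfl,fc->ncl", dout, w[:, :, j])
    return dx, dw, db


class ConvNetClassifier:
    """Scikit-learn-style binary classifier over (n, 48) feature matrices."""

    def __init__(
        self,
        n_channels: int = 4,
        seq_len: int = 12,
        conv_channels: tuple = (8, 16),
        kernel_size: int = 3,
        hidden: int = 16,
        learning_rate: float = 0.01,
        max_epochs: int = 300,
        patience: int = 25,
        val_fraction: float = 0.15,
        l2: float = 1e-4,
        random_state: int = 0,
    ) -> None:
        self.n_channels = n_channels
        self.seq_len = seq_len
        self.conv_channels = tuple(conv_channels)
        self.kernel_size = kernel_size
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.l2 = l2
        self.random_state = random_state

    # -- parameter plumbing so the model works with clone()-style copying --
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_channels": self.n_channels, "seq_len": self.seq_len,
            "conv_channels": self.conv_channels, "kernel_size": self.kernel_size,
            "hidden": self.hidden, "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs, "patience": self.patience,
            "val_fraction": self.val_fraction, "l2": self.l2,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "ConvNetClassifier":
        for key, val in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    # ------------------------------------------------------------------
    def _reshape(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if X.shape[1] != self.n_channels * self.seq_len:
            raise ValueError(
                f"expected {self.n_channels * self.seq_len} features, got {X.shape[1]}"
            )
        return X.reshape(n, self.n_channels, self.seq_len)

    def _init_weights(self, rng: np.random.Generator) -> dict:
        c1, c2 = self.conv_channels
        k = self.kernel_size
        lo1 = self.seq_len - k + 1
        lo2 = lo1 - k + 1
        flat = c2 * lo2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        return {
            "w1": he((c1, self.n_channels, k), self.n_channels * k),
            "b1": np.zeros(c1),
            "w2": he((c2, c1, k), c1 * k),
            "b2": np.zeros(c2),
            "w3": he((flat, self.hidden), flat),
            "b3": np.zeros(self.hidden),
            "w4": he((self.hidden, 1), self.hidden),
            "b4": np.zeros(1),
        }

    def _forward(self, x: np.ndarray, p: dict) -> tuple[np.ndarray, dict]:
        z1 = _conv1d_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2 = _conv1d_forward(a1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(a2.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = (a3 @ p["w4"] + p["b4"]).ravel()
        cache = {"x": x, "z1": z1, "a1": a1, "z2": z2, "a2": a2,
                 "flat": flat, "z3": z3, "a3": a3}
        return logits, cache

    def _backward(self, y: np.ndarray, prob: np.ndarray, cache: dict,
                  p: dict) -> dict:
        n = y.size
        dlogits = (prob - y)[:, None] / n
        g = {}
        g["w4"] = cache["a3"].T @ dlogits + self.l2 * p["w4"]
        g["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["w4"].T
        dz3 = da3 * (cache["z3"] > 0)
        g["w3"] = cache["flat"].T @ dz3 + self.l2 * p["w3"]
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        da2 = dflat.reshape(cache["a2"].shape)
        dz2 = da2 * (cache["z2"] > 0)
        da1, g["w2"], g["b2"] = _conv1d_backward(cache["a1"], p["w2"], dz2)
        g["w2"] += self.l2 * p["w2"]
        dz1 = da1 * (cache["z1"] > 0)
        _, g["w1"], g["b1"] = _conv1d_backward(cache["x"], p["w1"], dz1)
        g["w1"] += self.l2 * p["w1"]
        return g

    @staticmethod
    def _bce(y: np.ndarray, logits: np.ndarray) -> float:
        # numerically stable log(1 + exp(-|z|)) formulation
        return float(np.mean(
            np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
        ))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConvNetClassifier":
        x_all = self._reshape(X)
        y_all = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y_all)
        if classes.size < 2:
            raise TrainingError("training data contains a single class")
        rng = np.random.default_rng(self.random_state)
        # stratified validation split for early stopping
        val_mask = np.zeros(y_all.size, dtype=bool)
        for cls in classes:
            idx = np.nonzero(y_all == cls)[0]
            rng.shuffle(idx)
            n_val = max(1, int(round(self.val_fraction * idx.size)))
            if n_val >= idx.size:
                n_val = idx.size - 1
            val_mask[idx[:n_val]] = True
        if val_mask.all() or (~val_mask).sum() < 2:
            raise TrainingError("too few samples to hold out a validation slice")
        x_tr, y_tr = x_all[~val_mask], y_all[~val_mask]
        x_va, y_va = x_all[val_mask], y_all[val_mask]

        p = self._init_weights(rng)
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(v) for k, v in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss, best_p, since_best = np.inf, None, 0
        for epoch in range(1, self.max_epochs + 1):
            logits, cache = self._forward(x_tr, p)
            prob = _sigmoid(logits)
            grads = self._backward(y_tr, prob, cache, p)
            for key in p:
                m[key] = beta1 * m[key] + (1 - beta1) * grads[key]
                v[key] = beta2 * v[key] + (1 - beta2) * grads[key] ** 2
                mhat = m[key] / (1 - beta1 ** epoch)
                vhat = v[key] / (1 - beta2 ** epoch)
                p[key] = p[key] - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_logits, _ = self._forward(x_va, p)
            val_loss = self._bce(y_va, val_logits)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_p = {k: w.copy() for k, w in p.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.params_ = best_p if best_p is not None else p
        self.n_epochs_ = epoch
        self.val_loss_ = best_loss
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise TrainingError("model is not fitted")
        logits, _ = self._forward(self._reshape(X), self.params_)
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(int)
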