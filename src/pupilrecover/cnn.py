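"""Minimal trainable 1-D convolutional network, NumPy only.

Architecture (fixed topology, configurable sizes): two conv(ReLU) blocks each
followed by max-pooling, flatten, one dense ReLU layer, dropout, and a
2-unit softmax head.  Trained with Adam on categorical cross-entropy with
early stopping on validation loss (best weights restored).

The network operates on short 1-D feature sequences (tens of samples, tens of
training examples), where explicit NumPy forward/backward passes are fast and
fully deterministic under a seeded Generator.  Gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNConfig", "CurveCNN", "softmax"]


@dataclass(frozen=True)
class CNNConfig:
    filters: tuple[int, int] = (16, 32)
    kernel_size: int = 5
    pool: int = 2
    dense_units: int = 32
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x (N,C,L), w (F,C,K) -> out (N,F,L-K+1); valid convolution."""
    xw = sliding_window_view(x, w.shape[2], axis=2)  # (N,C,Lo,K)
    out = np.einsum("nclk,fck->nfl", xw, w, optimize=True) + b[None, :, None]
    return out, xw


def _conv1d_backward(dout, xw, w, x_shape):
    dw = np.einsum("nclk,nfl->fck", xw, dout, optimize=True)
    db = dout.sum(axis=(0, 2))
    k = w.shape[2]
    pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
    dpw = sliding_window_view(pad, k, axis=2)  # (N,F,L,K)
    dx = np.einsum("nflk,fck->ncl", dpw, w[:, :, ::-1], optimize=True)
    assert dx.shape == x_shape
    return dx, dw, db


def _maxpool_forward(x: np.ndarray, pool: int):
    n, f, l = x.shape
    lo = l // pool
    xr = x[:, :, : lo * pool].reshape(n, f, lo, pool)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return out, (arg, x.shape, lo, pool)


def _maxpool_backward(dout, cache):
    arg, x_shape, lo, pool = cache
    n, f, _ = x_shape
    dxr = np.zeros((n, f, lo, pool))
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
    dx = np.zeros(x_shape)
    dx[:, :, : lo * pool] = dxr.reshape(n, f, lo * pool)
    return dx


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class CurveCNN:
    """1-D CNN over an amplitude-curve feature axis; binary softmax output."""

    input_len: int
    cfg: CNNConfig = field(default_factory=CNNConfig)
    params: dict = field(default_factory=dict)

    def init_params(self, rng: np.random.Generator) -> None:
        f1, f2 = self.cfg.filters
        k = self.cfg.kernel_size
        l1 = self.input_len - k + 1
        p1 = l1 // self.cfg.pool
        l2 = p1 - k + 1
        p2 = l2 // self.cfg.pool
        if l1 < 1 or l2 < 1 or p2 < 1:
            raise ValueError(
                f"input length {self.input_len} too short for the architecture"
            )
        self._flat = f2 * p2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        d = self.cfg.dense_units
        self.params = {
            "w1": he((f1, 1, k), k),
            "b1": np.zeros(f1),
            "w2": he((f2, f1, k), f1 * k),
            "b2": np.zeros(f2),
            "wd": he((self._flat, d), self._flat),
            "bd": np.zeros(d),
            "wo": he((d, 2), d),
            "bo": np.zeros(2),
        }

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """x (N, L) -> probabilities (N, 2), plus cache when training."""
        p = self.params
        a0 = x[:, None, :]
        z1, xw1 = _conv1d_forward(a0, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        m1, c1 = _maxpool_forward(a1, self.cfg.pool)
        z2, xw2 = _conv1d_forward(m1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        m2, c2 = _maxpool_forward(a2, self.cfg.pool)
        flat = m2.reshape(len(x), -1)
        zd = flat @ p["wd"] + p["bd"]
        ad = np.maximum(zd, 0.0)
        if train and self.cfg.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass requires an rng for dropout")
            mask = (rng.random(ad.shape) >= self.cfg.dropout) / (1 - self.cfg.dropout)
        else:
            mask = np.ones_like(ad)
        adrop = ad * mask
        logits = adrop @ p["wo"] + p["bo"]
        probs = softmax(logits)
        cache = (a0, xw1, z1, c1, m1, xw2, z2, c2, m2, flat, zd, mask, adrop)
        return probs, cache

    def loss_and_grads(self, x: np.ndarray, y_onehot: np.ndarray,
                       rng: np.random.Generator):
        p = self.params
        probs, cache = self.forward(x, train=True, rng=rng)
        a0, xw1, z1, c1, m1, xw2, z2, c2, m2, flat, zd, mask, adrop = cache
        n = len(x)
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        dlogits = (probs - y_onehot) / n
        grads = {}
        grads["wo"] = adrop.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dadrop = dlogits @ p["wo"].T
        dad = dadrop * mask
        dzd = dad * (zd > 0)
        grads["wd"] = flat.T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ p["wd"].T
        dm2 = dflat.reshape(m2.shape)
        da2 = _maxpool_backward(dm2, c2)
        dz2 = da2 * (z2 > 0)
        dm1, grads["w2"], grads["b2"] = _conv1d_backward(dz2, xw2, p["w2"], m1.shape)
        da1 = _maxpool_backward(dm1, c1)
        dz1 = da1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv1d_backward(dz1, xw1, p["w1"], a0.shape)
        return loss, grads

    def eval_loss(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        probs, _ = self.forward(x, train=False)
        return float(-np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1)))

    # -- training ------------------------------------------------------------

    def fit(self, x_train: np.ndarray, y_train: np.ndarray,
            x_val: np.ndarray, y_val: np.ndarray,
            rng: np.random.Generator) -> dict:
        """Adam + early stopping on validation loss; restores best weights.

        ``y_*`` are one-hot (N, 2).  Returns a small training history dict.
        """
        if not self.params:
            self.init_params(rng)
        opt = _Adam(self.params, self.cfg.learning_rate)
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        best_epoch = -1
        wait = 0
        history = {"train_loss": [], "val_loss": []}
        n = len(x_train)
        for epoch in range(self.cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                loss, grads = self.loss_and_grads(x_train[idx], y_train[idx], rng)
                opt.step(self.params, grads)
                epoch_loss += loss * len(idx)
            val_loss = self.eval_loss(x_val, y_val)
            history["train_loss"].append(epoch_loss / n)
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= self.cfg.patience:
                    break
        self.params = best_params
        history["best_epoch"] = best_epoch
        history["best_val_loss"] = float(best_loss) if np.isfinite(best_loss) else None
        return history

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if not self.params:
            raise RuntimeError("model has no parameters; call init_params or fit")
        probs, _ = self.forward(x, train=False)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)
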