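"""Minimal feed-forward training engine (numpy).

Implements exactly the building blocks the detection networks need —
dense layers (optionally with a binary connectivity mask), 1-D
convolution, max pooling, ReLU/sigmoid, dropout, mean-squared-error loss
and the Adam optimizer — with reverse-mode gradients written out by hand.
Initialization is Glorot-uniform from a caller-supplied generator, so a
fixed seed gives bit-reproducible training.
"""

from __future__ import annotations

import numpy as np

from ..errors import DataError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    train_only = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, *, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def apply_constraints(self) -> None:
        """Hook run after every optimizer step (e.g. re-apply masks)."""


class Dense(Layer):
    """Fully connected layer, optionally sparsified by a binary mask.

    ``mask`` has shape (n_in, n_out); masked-out weights are zero at
    initialization, their gradients are zeroed, and the mask is re-applied
    after every optimizer step, so they are *exactly* zero at all times.
    """

    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, mask: np.ndarray | None = None
    ) -> None:
        self.W = Param(_glorot(rng, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.mask = None
        if mask is not None:
            mask = np.asarray(mask, dtype=float)
            if mask.shape != (n_in, n_out):
                raise DataError(f"mask shape {mask.shape} != ({n_in}, {n_out})")
            self.mask = mask
            self.W.value *= mask

    def params(self):
        return [self.W, self.b]

    def forward(self, x, *, train, rng):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        if self.mask is not None:
            self.W.grad *= self.mask
        return grad @ self.W.value.T

    def apply_constraints(self):
        if self.mask is not None:
            self.W.value *= self.mask


class ReLU(Layer):
    def forward(self, x, *, train, rng):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class Sigmoid(Layer):
    def forward(self, x, *, train, rng):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float) -> None:
        if not 0 <= rate < 1:
            raise DataError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train, rng):
        if not train or self.rate == 0:
            self._m = None
            return x
        self._m = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._m

    def backward(self, grad):
        return grad if self._m is None else grad * self._m


class Conv1D(Layer):
    """Single-channel 1-D convolution: (batch, L) -> (batch, L-k+1, filters)."""

    def __init__(self, kernel_size: int, filters: int, rng: np.random.Generator) -> None:
        self.k = kernel_size
        self.W = Param(_glorot(rng, (kernel_size, filters)))
        self.b = Param(np.zeros(filters))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, *, train, rng):
        if x.shape[1] < self.k:
            raise DataError(f"input length {x.shape[1]} < kernel size {self.k}")
        self._win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        return self._win @ self.W.value + self.b.value

    def backward(self, grad):
        # grad: (b, Lo, f); win: (b, Lo, k)
        self.W.grad = np.tensordot(self._win, grad, axes=([0, 1], [0, 1]))
        self.b.grad = grad.sum(axis=(0, 1))
        b, Lo, _f = grad.shape
        gx = np.zeros((b, Lo + self.k - 1))
        for i in range(self.k):
            gx[:, i : i + Lo] += grad @ self.W.value[i]
        return gx


class MaxPool1D(Layer):
    """Max pooling along the length axis; the remainder is dropped."""

    def __init__(self, pool: int = 2) -> None:
        self.pool = pool

    def forward(self, x, *, train, rng):
        b, L, f = x.shape
        n = L // self.pool
        self._in_shape = x.shape
        xr = x[:, : n * self.pool].reshape(b, n, self.pool, f)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        b, L, f = self._in_shape
        n = L // self.pool
        gx = np.zeros((b, n, self.pool, f))
        bi, ni, fi = np.ogrid[:b, :n, :f]
        gx[bi, ni, self._arg, fi] = grad
        return np.concatenate(
            [gx.reshape(b, n * self.pool, f), np.zeros((b, L - n * self.pool, f))], axis=1
        )


class Flatten(Layer):
    def forward(self, x, *, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Network:
    """A plain sequential network."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, *, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def apply_constraints(self) -> None:
        for layer in self.layers:
            layer.apply_constraints()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise DataError("weight list does not match network parameters")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise DataError(f"weight shape {w.shape} != parameter shape {p.value.shape}")
            p.value = w.copy()


class Adam:
    """Adam with the benchmark defaults: lr 0.01, beta1 0.9, beta2 0.999,
    epsilon 1e-8, no decay (time-based learning-rate decay supported)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
        decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.decay = lr, beta1, beta2, epsilon, decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        lr = self.lr / (1.0 + self.decay * self.t) if self.decay else self.lr
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - lr * mhat / (np.sqrt(vhat) + self.eps)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


def fit(
    network: Network,
    X: np.ndarray,
    y: np.ndarray,
    *,
    optimizer: Adam,
    epochs: int = 50,
    batch_size: int = 32,
    val_fraction: float = 0.2,
    patience: int = 10,
    rng: np.random.Generator,
) -> dict:
    """Mini-batch training with MSE loss and optional early stopping.

    Returns a log dict with per-epoch train/validation losses.  The best
    validation-loss weights are restored at the end.  A NaN loss aborts
    with a diagnostic.
    """
    n = X.shape[0]
    if y.shape[0] != n:
        raise DataError("X and y disagree on sample count")
    idx = rng.permutation(n)
    n_val = int(round(n * val_fraction))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if train_idx.size == 0:
        raise DataError("no training samples left after validation split")
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    log: dict = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(train_idx.size)
        losses = []
        for s in range(0, order.size, batch_size):
            b = order[s : s + batch_size]
            pred = network.forward(Xtr[b], train=True, rng=rng)
            loss, grad = mse(pred, ytr[b])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {s // batch_size}; "
                    "reduce the learning rate or check the input scaling"
                )
            network.backward(grad)
            optimizer.step()
            network.apply_constraints()
            losses.append(loss)
        log["train_loss"].append(float(np.mean(losses)))
        if n_val:
            vloss, _ = mse(network.forward(Xval), yval)
            log["val_loss"].append(vloss)
            if vloss < best[0] - 1e-12:
                best = (vloss, network.get_weights())
                stale = 0
            else:
                stale += 1
                if stale > patience:
                    break
    if best[1] is not None:
        network.set_weights(best[1])
    log["epochs_run"] = len(log["train_loss"])
    return log
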