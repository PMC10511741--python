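"""A compact NumPy neural-network engine.

Implements exactly the layer set the package's two CNNs need — Conv2D
(stride 1, 'same'/'valid'), BatchNorm, 2x2 max pooling with floor semantics,
global average pooling, dense layers, ReLU — with reverse-mode gradients,
SGD/Adam optimizers, softmax-cross-entropy and sigmoid-BCE losses, and a
training loop with best-validation-accuracy checkpointing.

Layout is NHWC.  Convolutions are evaluated as im2col + BLAS matmul; the
conv backward pass accumulates the input gradient with one matmul per kernel
tap (at most nine), which keeps everything inside vectorised BLAS calls.
Weight initialisation is seeded He-uniform (uniform over +/- sqrt(6/fan_in)),
appropriate for the ReLU nonlinearities used throughout.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "ReLU",
    "Flatten",
    "Network",
    "SoftmaxCrossEntropy",
    "SigmoidBCE",
    "SGD",
    "Adam",
    "train_network",
]


def _he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of trainable
    arrays and their gradients; ``buffers`` holds non-trainable state."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    buffers: list[np.ndarray]

    def __init__(self):
        self.params, self.grads, self.buffers = [], [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, in_ch, out_ch, kernel, padding="valid", rng=None,
                 dtype=np.float32):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.kh, self.kw, self.in_ch, self.out_ch = kh, kw, in_ch, out_ch
        self.padding = padding
        fan_in = kh * kw * in_ch
        self.W = _he_uniform(rng, (kh * kw * in_ch, out_ch), fan_in, dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pad(self, x):
        if self.padding == "same":
            ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
            if ph or pw:
                return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        return x

    def forward(self, x, train):
        xp = self._pad(x)
        n, h, w, c = xp.shape
        oh, ow = h - self.kh + 1, w - self.kw + 1
        if self.kh == self.kw == 1:
            cols = xp.reshape(n * h * w, c)
        else:
            win = np.lib.stride_tricks.sliding_window_view(
                xp, (self.kh, self.kw), axis=(1, 2)
            )  # (n, oh, ow, c, kh, kw)
            cols = np.ascontiguousarray(
                np.moveaxis(win, 3, 5)
            ).reshape(n * oh * ow, self.kh * self.kw * c)
        self._cols, self._xshape, self._out_hw = cols, x.shape, (oh, ow)
        out = cols @ self.W + self.b
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, dout):
        n, oh, ow, _ = dout.shape
        dflat = dout.reshape(-1, self.out_ch)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        # input gradient: one matmul per kernel tap, accumulated on padded grid
        ph = (self.kh - 1) // 2 if self.padding == "same" else 0
        pw = (self.kw - 1) // 2 if self.padding == "same" else 0
        _, h, w, c = self._xshape
        dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c), dtype=dout.dtype)
        Wt = self.W.reshape(self.kh, self.kw, c, self.out_ch)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + oh, j : j + ow, :] += (dflat @ Wt[i, j].T).reshape(
                    n, oh, ow, c
                )
        if ph or pw:
            dxp = dxp[:, ph : ph + h, pw : pw + w, :]
        self._cols = None
        return dxp


class BatchNorm(Layer):
    """Channel-wise batch normalisation (momentum 0.99, eps 1e-3).

    Training uses batch statistics and updates the moving mean/variance
    (the two non-trainable arrays); inference uses the moving statistics.
    """

    def __init__(self, ch, momentum=0.99, eps=1e-3, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones(ch, dtype=dtype)
        self.beta = np.zeros(ch, dtype=dtype)
        self.moving_mean = np.zeros(ch, dtype=dtype)
        self.moving_var = np.ones(ch, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.buffers = [self.moving_mean, self.moving_var]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean *= self.momentum
            self.moving_mean += (1 - self.momentum) * mean
            self.moving_var *= self.momentum
            self.moving_var += (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, axes, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads[0][...] = (dout * xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv
        self._cache = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, floor semantics for odd sizes."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :]
        x6 = xc.reshape(n, h2, 2, w2, 2, c)
        flat = np.ascontiguousarray(x6.transpose(0, 1, 3, 2, 4, 5)).reshape(
            n, h2, w2, 4, c
        )
        self._idx = flat.argmax(axis=3)
        self._inshape = x.shape
        return np.take_along_axis(flat, self._idx[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, dout):
        n, h, w, c = self._inshape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, h2, w2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dflat.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(n, 2 * h2, 2 * w2, c)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._inshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._inshape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Flatten(Layer):
    def forward(self, x, train):
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._inshape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = _he_uniform(rng, (n_in, n_out), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Network:
    """An ordered stack of layers with a shared forward/backward pass."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @property
    def buffers(self):
        return [b for l in self.layers for b in l.buffers]

    def n_parameters(self) -> tuple[int, int]:
        """(trainable, non_trainable) parameter counts of the live arrays."""
        return (
            sum(p.size for p in self.params),
            sum(b.size for b in self.buffers),
        )

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def get_state(self):
        return [p.copy() for p in self.params + self.buffers]

    def set_state(self, state):
        for dst, src in zip(self.params + self.buffers, state):
            dst[...] = src


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SoftmaxCrossEntropy:
    """Categorical cross-entropy over integer class labels; the final dense
    layer emits logits and softmax is folded into the loss."""

    def loss_and_grad(self, logits, y):
        p = softmax(logits.astype(np.float64))
        n = len(y)
        loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
        grad = p
        grad[np.arange(n), y] -= 1.0
        return loss, (grad / n).astype(logits.dtype)

    def predict_proba(self, logits):
        return softmax(logits.astype(np.float64))

    def predict(self, logits):
        return logits.argmax(axis=-1)


class SigmoidBCE:
    """Binary cross-entropy on a single sigmoid output unit."""

    def loss_and_grad(self, logits, y):
        z = logits.astype(np.float64).ravel()
        y = np.asarray(y, dtype=np.float64)
        p = 1.0 / (1.0 + np.exp(-z))
        loss = -(y * np.log(np.maximum(p, 1e-12))
                 + (1 - y) * np.log(np.maximum(1 - p, 1e-12))).mean()
        grad = ((p - y) / len(y)).astype(logits.dtype)
        return loss, grad[:, None]

    def predict_proba(self, logits):
        p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64).ravel()))
        return np.stack([1 - p, p], axis=1)

    def predict(self, logits):
        return (logits.ravel() > 0).astype(int)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.0):
        self.params, self.lr, self.momentum = params, lr, momentum
        self.vel = [np.zeros_like(p) for p in params] if momentum else None

    def step(self, grads):
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if self.vel is not None:
                self.vel[i] = self.momentum * self.vel[i] - self.lr * g
                p += self.vel[i]
            else:
                p -= self.lr * g


class Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _batched_forward(net, X, batch, train=False):
    outs = [net.forward(X[i : i + batch], train) for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def train_network(
    net: Network,
    loss_fn,
    optimizer,
    X_train,
    y_train,
    X_val=None,
    y_val=None,
    epochs: int = 50,
    batch_size: int = 16,
    seed: int = 0,
    checkpoint: bool = True,
):
    """Mini-batch training with per-epoch history and (optionally) restoring
    the weights of the epoch with the best validation accuracy.

    Returns (history, best_epoch); history rows hold train/val loss and
    accuracy per epoch.
    """
    if len(X_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    history = []
    best_acc, best_epoch, best_state = -1.0, -1, None
    for epoch in range(epochs):
        order = rng.permutation(len(X_train))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            logits = net.forward(X_train[idx], train=True)
            loss, grad = loss_fn.loss_and_grad(logits, y_train[idx])
            net.backward(grad)
            optimizer.step(net.grads)
            losses.append(loss * len(idx))
        train_logits = _batched_forward(net, X_train, max(batch_size, 64))
        train_acc = float(np.mean(loss_fn.predict(train_logits) == y_train))
        row = {
            "epoch": epoch,
            "train_loss": float(np.sum(losses) / len(X_train)),
            "train_accuracy": train_acc,
        }
        if X_val is not None and len(X_val):
            val_logits = _batched_forward(net, X_val, max(batch_size, 64))
            val_loss, _ = loss_fn.loss_and_grad(val_logits, y_val)
            val_acc = float(np.mean(loss_fn.predict(val_logits) == y_val))
            row["val_loss"] = float(val_loss)
            row["val_accuracy"] = val_acc
            if checkpoint and val_acc > best_acc:
                best_acc, best_epoch, best_state = val_acc, epoch, net.get_state()
        history.append(row)
    if checkpoint and best_state is not None:
        net.set_state(best_state)
    else:
        best_epoch = epochs - 1
    return history, best_epoch
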