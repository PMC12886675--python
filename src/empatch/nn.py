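"""A small multi-task 1-D convolutional network, implemented on NumPy.

The architecture is hard parameter sharing: a shared encoder of five 1-D
convolutional layers (ReLU, stride 1, same padding) followed by global
average pooling over time, feeding two task heads — a 3-way linear
classifier trained with softmax cross-entropy and a scalar linear regressor
trained with mean-squared error. The joint objective is

    L = CE(class logits, class label) + λ · MSE(degree output, degree label)

optimised with Adam. Everything is dense NumPy (im2col convolutions), runs
single-threaded through BLAS, and is bit-reproducible for a fixed seed on a
given platform. float32 is the training dtype; float64 is available for
gradient checking.

This module holds only the network and optimiser; data handling,
standardisation and cross-validation live in :mod:`empatch.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d:
    """Same-padded 1-D convolution, kernel k, stride 1, via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.W = _he_init(rng, (c_in * k, c_out), c_in * k, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C, T) -> patches (B, T, C*k), zero padded at the edges
        B, C, T = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # win: (B, C, T, k) -> (B, T, C, k) -> (B, T, C*k)
        return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, T, C * self.k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = self._im2col(x)  # (B, T, C*k)
        y = cols @ self.W + self.b  # (B, T, c_out)
        self._cache = cols
        return np.ascontiguousarray(y.transpose(0, 2, 1))  # (B, c_out, T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols = self._cache
        B, T, _ = cols.shape
        dy_t = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (B, T, c_out)
        flat_cols = cols.reshape(B * T, -1)
        flat_dy = dy_t.reshape(B * T, -1)
        self.dW = flat_cols.T @ flat_dy
        self.db = flat_dy.sum(axis=0)
        dcols = (flat_dy @ self.W.T).reshape(B, T, self.c_in, self.k)
        # col2im: scatter-add each kernel tap back onto the padded time axis
        p = self.k // 2
        dx = np.zeros((B, self.c_in, T + 2 * p), dtype=dy.dtype)
        for j in range(self.k):
            dx[:, :, j:j + T] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx[:, :, p:p + T]


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = _he_init(rng, (n_in, n_out), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class MLPHead:
    """Optional-hidden-layer task head: Linear (→ ReLU → Linear)*."""

    def __init__(self, n_in: int, hidden: tuple, n_out: int,
                 rng: np.random.Generator, dtype=np.float32):
        widths = (n_in,) + tuple(hidden) + (n_out,)
        self.layers = [Linear(widths[i], widths[i + 1], rng, dtype)
                       for i in range(len(widths) - 1)]
        self._masks: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._masks = []
        for i, lin in enumerate(self.layers):
            x = lin.forward(x)
            if i < len(self.layers) - 1:
                mask = x > 0
                x = x * mask
                self._masks.append(mask)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                dy = dy * self._masks[i]
            dy = self.layers[i].backward(dy)
        return dy

    # expose stacked parameters with unique attribute-style access
    @property
    def sublayers(self):
        return self.layers


@dataclass
class MTLConfig:
    """Hyperparameters of the multi-task network and its training loop."""

    conv_channels: tuple = (16, 32, 32, 64, 64)
    kernel: int = 3
    n_input_channels: int = 6
    n_classes: int = 3
    cls_hidden: tuple = ()
    reg_hidden: tuple = (32,)
    loss_weight_lambda: float = 1.0
    lr: float = 1e-3
    lr_decay: float = 0.3  # multiplier applied at 60% and 85% of the schedule
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    dtype: str = "float32"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 5:
            raise ValueError("the shared encoder uses exactly five conv layers")
        if self.loss_weight_lambda < 0:
            raise ValueError("loss_weight_lambda must be >= 0")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MTLNet:
    """Shared 5-conv encoder with classification and regression heads."""

    def __init__(self, config: MTLConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        chans = (config.n_input_channels,) + tuple(config.conv_channels)
        self.convs = [
            Conv1d(chans[i], chans[i + 1], config.kernel, rng, dtype)
            for i in range(5)
        ]
        self.cls_head = MLPHead(chans[-1], tuple(config.cls_hidden),
                                config.n_classes, rng, dtype)
        self.reg_head = MLPHead(chans[-1], tuple(config.reg_hidden), 1, rng, dtype)
        self.dtype = dtype
        self.trained = False

    # -- forward -----------------------------------------------------------
    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate shared feature vector (global-average-pooled)."""
        h = np.asarray(x, dtype=self.dtype)
        self._relu_masks = []
        for conv in self.convs:
            h = conv.forward(h)
            mask = h > 0
            h = h * mask
            self._relu_masks.append(mask)
        self._T = h.shape[2]
        pooled = h.mean(axis=2)
        self._pooled = pooled
        return pooled

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (class logits (B, 3), degree output (B,))."""
        pooled = self.embed(x)
        logits = self.cls_head.forward(pooled)
        reg = self.reg_head.forward(pooled)[:, 0]
        return logits, reg

    # -- backward ----------------------------------------------------------
    def backward(self, dlogits: np.ndarray, dreg: np.ndarray) -> None:
        dpool = self.cls_head.backward(dlogits)
        dpool = dpool + self.reg_head.backward(dreg[:, None])
        dh = (dpool[:, :, None] / self._T).repeat(self._T, axis=2).astype(self.dtype)
        for conv, mask in zip(reversed(self.convs), reversed(self._relu_masks)):
            dh = conv.backward(dh * mask)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[tuple[object, str]]:
        mods = list(self.convs) + self.cls_head.sublayers + self.reg_head.sublayers
        return [(m, n) for m in mods for n in ("W", "b")]

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(m, n).copy() for m, n in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (m, n), w in zip(self.parameters(), weights):
            setattr(m, n, w.astype(self.dtype))


class Adam:
    def __init__(self, net: MTLNet, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(m, n)) for m, n in net.parameters()]
        self.v = [np.zeros_like(getattr(m, n)) for m, n in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, (mod, name) in enumerate(self.net.parameters()):
            g = getattr(mod, "d" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p = getattr(mod, name)
            setattr(
                mod, name,
                (p - lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)).astype(p.dtype),
            )


def joint_loss_and_grads(
    net: MTLNet, x: np.ndarray, y_class: np.ndarray, y_degree: np.ndarray,
    lam: float,
) -> tuple[float, float]:
    """One forward/backward pass; returns (cross-entropy, MSE) on the batch.

    Gradients are left on the network's layers for the optimiser to consume.
    """
    B = x.shape[0]
    logits, reg = net.forward(x)
    p = softmax(logits.astype(np.float64))
    ce = float(-np.mean(np.log(p[np.arange(B), y_class] + 1e-12)))
    err = reg.astype(np.float64) - y_degree
    mse = float(np.mean(err**2))
    if not np.isfinite(ce) or not np.isfinite(mse):
        raise FloatingPointError("non-finite loss")
    onehot = np.zeros_like(p)
    onehot[np.arange(B), y_class] = 1.0
    dlogits = ((p - onehot) / B).astype(net.dtype)
    dreg = (lam * 2.0 * err / B).astype(net.dtype)
    net.backward(dlogits, dreg)
    return ce, mse


def train_network(
    net: MTLNet,
    x: np.ndarray,
    y_class: np.ndarray,
    y_degree: np.ndarray,
    config: MTLConfig,
    x_val: np.ndarray | None = None,
    y_class_val: np.ndarray | None = None,
    y_degree_val: np.ndarray | None = None,
    callback=None,
) -> list[dict]:
    """Mini-batch Adam training; returns a per-epoch history of both losses.

    Raises ``RuntimeError`` with the offending epoch and learning rate if
    the joint loss goes non-finite.
    """
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(net, config.lr)
    n = x.shape[0]
    x = np.asarray(x, dtype=net.dtype)
    y_degree = np.asarray(y_degree, dtype=np.float64)
    history = []
    decay_at = {int(config.epochs * 0.6), int(config.epochs * 0.85)}
    for epoch in range(config.epochs):
        if epoch in decay_at:
            opt.lr *= config.lr_decay
        order = rng.permutation(n)
        ce_sum = mse_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            try:
                ce, mse = joint_loss_and_grads(
                    net, x[idx], y_class[idx], y_degree[idx],
                    config.loss_weight_lambda,
                )
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={config.lr}); "
                    "reduce the learning rate"
                ) from exc
            opt.step()
            ce_sum += ce * idx.size
            mse_sum += mse * idx.size
        rec = {"epoch": epoch, "ce_loss": ce_sum / n, "mse_loss": mse_sum / n}
        if x_val is not None:
            logits, reg = net.forward(np.asarray(x_val, dtype=net.dtype))
            pred = logits.argmax(axis=1)
            rec["val_acc"] = float(np.mean(pred == y_class_val))
            resid = reg.astype(np.float64) - y_degree_val
            tot = np.var(y_degree_val)
            rec["val_r2"] = float(1.0 - np.mean(resid**2) / tot) if tot > 0 else np.nan
        history.append(rec)
        if callback is not None:
            callback(rec)
    net.trained = True
    return history
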