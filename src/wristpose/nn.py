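"""Compact seeded numpy engine for the window-classifier network.

Implements exactly the pieces the posture classifier needs — valid
(no-padding) 2-D convolution via im2col, 2x2 max pooling, a dense layer
with inverted dropout, softmax cross-entropy and Adam — in float32 with
every source of randomness drawn from an explicit ``numpy`` Generator,
so two builds from one seed are bit-identical.

Shape chain for the 12x100x1 input under valid convolutions:
conv 3x3x32 -> 10x98x32, pool 2x2 -> 5x49x32, conv 3x3x64 -> 3x47x64,
pool 2x2 -> 1x23x64, flatten -> 1472, dense -> 4096, dropout 0.8,
dense -> n_classes, softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# layer primitives (NHWC)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B,H,W,C) -> (B,H',W',kh*kw*C) patch matrix for valid convolution."""
    sw = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # sw: (B, H', W', C, kh, kw) -> (B, H', W', kh, kw, C)
    sw = sw.transpose(0, 1, 2, 4, 5, 3)
    b, hp, wp = sw.shape[:3]
    return np.ascontiguousarray(sw).reshape(b, hp, wp, kh * kw * x.shape[3])


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 2-D convolution (really cross-correlation, the CNN convention).

    ``w`` has shape (kh, kw, c_in, c_out).
    """
    kh, kw, cin, cout = w.shape
    cols = _im2col(x, kh, kw)
    out = cols @ w.reshape(kh * kw * cin, cout) + b
    return out, (cols, x.shape)


def conv2d_backward(dout: np.ndarray, w: np.ndarray, cache, need_dx: bool = True):
    cols, x_shape = cache
    kh, kw, cin, cout = w.shape
    bsz, hp, wp, _ = dout.shape
    dout_flat = dout.reshape(-1, cout)
    cols_flat = cols.reshape(-1, kh * kw * cin)
    dw = (cols_flat.T @ dout_flat).reshape(w.shape)
    db = dout_flat.sum(axis=0)
    dx = None
    if need_dx:
        # accumulate shifted contributions instead of im2col on a padded grid
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for di in range(kh):
            for dj in range(kw):
                dx[:, di : di + hp, dj : dj + wp, :] += (
                    dout_flat @ w[di, dj].T
                ).reshape(bsz, hp, wp, cin)
    return dx, dw, db


def maxpool2x2_forward(x: np.ndarray):
    """2x2 max pooling, stride 2, floor semantics (odd edges cropped)."""
    b, h, w, c = x.shape
    hp, wp = h // 2, w // 2
    xc = x[:, : 2 * hp, : 2 * wp].reshape(b, hp, 2, wp, 2, c)
    out = xc.max(axis=(2, 4))
    return out, (x.shape, xc, out)


def maxpool2x2_backward(dout: np.ndarray, cache):
    x_shape, xc, out = cache
    b, hp, _, wp, _, c = xc.shape
    mask = (xc == out[:, :, None, :, None, :]).astype(dout.dtype)
    # split gradient across ties so it stays exact for constant regions
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dx_c = mask * (dout[:, :, None, :, None, :] / counts)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : 2 * hp, : 2 * wp] = dx_c.reshape(b, 2 * hp, 2 * wp, c)
    return dx


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout * mask


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when rng is None (inference)."""
    if rng is None or rate <= 0:
        return x, None
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / F32(keep)
    return x * mask, mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = np.finfo(probs.dtype).tiny
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


# ---------------------------------------------------------------------------
# the posture network


@dataclass
class CnnParams:
    """Weight tensors keyed by layer name."""

    tensors: dict[str, np.ndarray]

    def copy(self) -> "CnnParams":
        return CnnParams({k: v.copy() for k, v in self.tensors.items()})


class PostureCnn:
    """Two conv/pool stages, one wide dense layer, softmax output.

    Input windows arrive as (B, 12, 100) and are treated as single-channel
    images. Initialization is He-normal from the given seed.
    """

    INPUT_SHAPE = (12, 100)

    def __init__(
        self,
        n_classes: int,
        seed: int = 0,
        conv_filters: tuple[int, int] = (32, 64),
        dense_units: int = 4096,
        dropout_rate: float = 0.80,
    ) -> None:
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_classes = n_classes
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.conv_filters = tuple(conv_filters)
        self.flat_dim = self._shape_chain()[-1]
        rng = np.random.default_rng(seed)
        f1, f2 = self.conv_filters

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)

        self.params = CnnParams(
            {
                "w1": he((3, 3, 1, f1), 9),
                "b1": np.zeros(f1, dtype=F32),
                "w2": he((3, 3, f1, f2), 9 * f1),
                "b2": np.zeros(f2, dtype=F32),
                "wd": he((self.flat_dim, dense_units), self.flat_dim),
                "bd": np.zeros(dense_units, dtype=F32),
                "wo": he((dense_units, n_classes), dense_units),
                "bo": np.zeros(n_classes, dtype=F32),
            }
        )

    def _shape_chain(self) -> list[int]:
        """Flattened size after conv->pool->conv->pool under valid padding."""
        h, w = self.INPUT_SHAPE
        h, w = h - 2, w - 2          # conv1 3x3 valid
        h, w = h // 2, w // 2        # pool1
        h, w = h - 2, w - 2          # conv2
        h, w = h // 2, w // 2        # pool2
        return [h, w, h * w * self.conv_filters[1]]

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Logits plus the cache needed for backprop.

        ``rng`` enables dropout (training mode); None means inference.
        """
        p = self.params.tensors
        if x.ndim != 3 or x.shape[1:] != self.INPUT_SHAPE:
            raise ValueError(
                f"expected input (B, {self.INPUT_SHAPE[0]}, {self.INPUT_SHAPE[1]}), "
                f"got {x.shape}"
            )
        h = x.astype(F32, copy=False)[..., None]
        c1, cc1 = conv2d_forward(h, p["w1"], p["b1"])
        r1, rm1 = relu_forward(c1)
        p1, pc1 = maxpool2x2_forward(r1)
        c2, cc2 = conv2d_forward(p1, p["w2"], p["b2"])
        r2, rm2 = relu_forward(c2)
        p2, pc2 = maxpool2x2_forward(r2)
        flat = p2.reshape(len(x), -1)
        d1 = flat @ p["wd"] + p["bd"]
        rd, rmd = relu_forward(d1)
        dd, dmask = dropout_forward(rd, self.dropout_rate, rng)
        logits = dd @ p["wo"] + p["bo"]
        cache = (cc1, rm1, pc1, cc2, rm2, pc2, flat, rmd, dd, dmask, p2.shape)
        return logits, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        p = self.params.tensors
        logits, cache = self.forward(x, rng=rng)
        cc1, rm1, pc1, cc2, rm2, pc2, flat, rmd, dd, dmask, p2_shape = cache
        probs = softmax(logits)
        loss = cross_entropy(probs, y)

        b = len(y)
        dlogits = probs
        dlogits[np.arange(b), y] -= 1.0
        dlogits = (dlogits / b).astype(F32)

        grads: dict[str, np.ndarray] = {}
        grads["wo"] = dd.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        ddd = dlogits @ p["wo"].T
        if dmask is not None:
            ddd = ddd * dmask
        dd1 = relu_backward(ddd, rmd)
        grads["wd"] = flat.T @ dd1
        grads["bd"] = dd1.sum(axis=0)
        dflat = dd1 @ p["wd"].T
        dp2 = dflat.reshape(p2_shape)
        dr2 = maxpool2x2_backward(dp2, pc2)
        dc2 = relu_backward(dr2, rm2)
        dp1, grads["w2"], grads["b2"] = conv2d_backward(dc2, p["w2"], cc2)
        dr1 = maxpool2x2_backward(dp1, pc1)
        dc1 = relu_backward(dr1, rm1)
        # first layer: input gradient is never needed
        _, grads["w1"], grads["b1"] = conv2d_backward(dc1, p["w1"], cc1, need_dx=False)
        return loss, grads

    # -- inference ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = np.empty((len(x), self.n_classes), dtype=F32)
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            out[i : i + batch_size] = softmax(logits)
        return out

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 1024) -> float:
        total = 0.0
        for i in range(0, len(x), batch_size):
            probs = self.predict_proba(x[i : i + batch_size], batch_size)
            total += cross_entropy(probs, y[i : i + batch_size]) * len(probs)
        return total / len(x)


class Adam:
    """Adaptive-moment gradient descent with the customary defaults."""

    def __init__(
        self,
        params: CnnParams,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.tensors.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.tensors.items()}

    def step(self, params: CnnParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        # bias correction folded into the step size (standard reformulation)
        lr_t = self.lr * np.sqrt(b2t) / b1t
        for k, g in grads.items():
            m, v = self.m[k], self.v[k]
            np.multiply(m, self.beta1, out=m)
            m += (1 - self.beta1) * g
            np.multiply(v, self.beta2, out=v)
            gsq = g * g
            gsq *= 1 - self.beta2
            v += gsq
            denom = np.sqrt(v)
            denom += self.eps * np.sqrt(b2t)
            update = m / denom
            update *= lr_t
            params.tensors[k] -= update


class EarlyStopper:
    """Patience-based stopping on a monitored loss, tracking the best epoch.

    ``update`` is called once per epoch with the validation loss and
    returns True when training should stop (no improvement for
    ``patience`` consecutive epochs). With a plateau starting at epoch k
    (1-based), stopping fires at epoch k + patience.
    """

    def __init__(self, patience: int, min_delta: float = 0.0) -> None:
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0

    def update(self, epoch: int, loss: float) -> bool:
        if loss < self.best_loss - self.min_delta:
            self.best_loss = loss
            self.best_epoch = epoch
            self.epochs_since_best = 0
            return False
        self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience
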