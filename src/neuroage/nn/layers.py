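"""Layers with explicit forward/backward passes.

Conventions: volumes are (N, C, D, H, W); dense inputs are (N, F).
``forward(x, training=False, rng=None)`` caches what backward needs;
``backward(grad)`` returns the gradient w.r.t. the layer input and
stores parameter gradients in ``self.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, 'same' zero padding (im2col matmul)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, *, rng=None, dtype=np.float32):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.params = {"w": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}

    def forward(self, x, training=False, rng=None):
        n, c, d, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # (N, C, D, H, W, k, k, k) -> (N*D*H*W, C*k^3)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * d * h * w, c * k**3
        )
        out = cols @ self.params["w"] + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(n, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, grad):
        cols, (n, c, d, h, w) = self._cache
        k, p = self.kernel, self.kernel // 2
        gm = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1)).reshape(-1, self.c_out)
        self.grads = {"w": cols.T @ gm, "b": gm.sum(axis=0)}
        dcols = (gm @ self.params["w"].T).reshape(n, d, h, w, c, k, k, k)
        dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)  # (N, C, D, H, W, k,k,k)
        dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    dxp[:, :, kd : kd + d, kh : kh + h, kw : kw + w] += dcols[
                        ..., kd, kh, kw
                    ]
        return dxp[:, :, p : p + d, p : p + h, p : p + w]


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for volumes)."""

    def __init__(self, n_features: int, *, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.n_features = n_features
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
        }
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)

    def _axes_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, self.n_features)
        if x.ndim == 5:
            return (0, 2, 3, 4), (1, self.n_features, 1, 1, 1)
        raise ValueError(f"BatchNorm expects 2D or 5D input, got {x.ndim}D")

    def forward(self, x, training=False, rng=None):
        axes, shape = self._axes_shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        self._cache = (xhat, invstd, axes, shape) if training else None
        self._eval_cache = None if training else (invstd, shape)
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, grad):
        if self._cache is None:
            # eval mode: mean/var are constants, so BN is a pure affine map
            invstd, shape = self._eval_cache
            return grad * (self.params["gamma"] * invstd).reshape(shape)
        xhat, invstd, axes, shape = self._cache
        m = np.prod([grad.shape[a] for a in axes])
        dbeta = grad.sum(axis=axes)
        dgamma = (grad * xhat).sum(axis=axes)
        self.grads = {"gamma": dgamma, "beta": dbeta}
        g = self.params["gamma"].reshape(shape) * invstd.reshape(shape)
        return (
            g / m * (m * grad - dbeta.reshape(shape) - xhat * dgamma.reshape(shape))
        )


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        out = np.maximum(x, 0)
        self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class MaxPool3D(Layer):
    """2x2x2 max pooling with stride 2; odd trailing planes are dropped."""

    def forward(self, x, training=False, rng=None):
        n, c, d, h, w = x.shape
        dc, hc, wc = (d // 2) * 2, (h // 2) * 2, (w // 2) * 2
        if min(dc, hc, wc) == 0:
            raise ValueError(f"spatial shape {(d, h, w)} too small to pool")
        xc = x[:, :, :dc, :hc, :wc].reshape(n, c, dc // 2, 2, hc // 2, 2, wc // 2, 2)
        out = xc.max(axis=(3, 5, 7))
        self._cache = (xc, out, x.shape)
        return out

    def backward(self, grad):
        xc, out, (n, c, d, h, w) = self._cache
        mask = xc == out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None, :, None] / counts)
        dc, hc, wc = (d // 2) * 2, (h // 2) * 2, (w // 2) * 2
        dx = np.zeros((n, c, d, h, w), dtype=grad.dtype)
        dx[:, :, :dc, :hc, :wc] = g.reshape(n, c, dc, hc, wc)
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.params = {"w": w.astype(dtype), "b": np.zeros(n_out, dtype=dtype)}
        self.n_in, self.n_out = n_in, n_out

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} features, got {x.shape[1]}")
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad):
        self.grads = {"w": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training or when rng is absent."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0 or rng is None:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def parameters(layers) -> list[tuple[Layer, str]]:
    """Flat list of (layer, param-name) pairs over a layer stack."""
    out = []
    for layer in layers:
        for name in layer.params:
            out.append((layer, name))
    return out
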