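"""A compact 1-D convolutional network in NumPy, tuned for 8 x 120 windows.

Architecture (the configuration that recognises gait/fatigue states best):
two same-padded convolutions with 128 filters, max-pool of stride 2, two
convolutions with 256 filters, a second stride-2 pool, then a flatten and a
softmax layer — all kernels of size 7, ReLU activations, trained with Adam
under a cosine learning-rate decay on categorical cross-entropy.

Implementation notes: activations are kept channel-major ``(channels, batch,
length)`` in float32 so every convolution (forward, weight gradient, input
gradient) is a single BLAS matmul over an im2col buffer; the im2col/col2im
reshuffles are K slice copies.  This keeps a full training run at the default
problem size within minutes on one CPU core.  With a fixed seed and batch
order the run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_DTYPE = np.float32


@dataclass(frozen=True)
class CNNSpec:
    """Hyperparameters of the window classifier."""

    filters: tuple[int, ...] = (128, 128, 256, 256)
    kernel_size: int = 7
    pool_stride: int = 2
    n_classes: int = 6
    epochs: int = 200
    batch_size: int = 48
    learning_rate: float = 1.0e-3
    lr_schedule: str = "cosine"  # or "constant"

    def __post_init__(self) -> None:
        if len(self.filters) != 4:
            raise ValueError("expected four convolutional layers")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (same padding)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.pool_stride < 1 or self.batch_size < 1:
            raise ValueError("pool_stride and batch_size must be >= 1")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(c, n, l) -> contiguous (c*k, n*l) patch matrix with same zero padding."""
    c, n, l = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    xc = np.empty((c, k, n, l), dtype=_DTYPE)
    for j in range(k):
        xc[:, j] = xp[:, :, j : j + l]
    return xc.reshape(c * k, n * l)

def _col2im(dxc: np.ndarray, c: int, n: int, l: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (c, n, l)."""
    p = k // 2
    d = dxc.reshape(c, k, n, l)
    dxp = np.zeros((c, n, l + k - 1), dtype=_DTYPE)
    for j in range(k):
        dxp[:, :, j : j + l] += d[:, j]
    return dxp[:, :, p : p + l]


class Conv1DNet:
    """Weights + forward/backward of the four-conv softmax network."""

    def __init__(self, spec: CNNSpec, input_shape: tuple[int, int], seed: int = 2023):
        self.spec = spec
        self.input_shape = tuple(input_shape)  # (channels, length)
        c_in, length = self.input_shape
        k = spec.kernel_size
        if length < k:
            raise ValueError("input length shorter than the kernel")
        if length % (spec.pool_stride**2) != 0:
            raise ValueError("input length must survive two pooling stages")
        rng = np.random.default_rng(int(seed) % (2**31))

        def he(fan_in: int, shape) -> np.ndarray:
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)

        chans = [c_in, *spec.filters]
        self.W = [he(chans[i] * k, (chans[i + 1], chans[i] * k)) for i in range(4)]
        self.b = [np.zeros(chans[i + 1], dtype=_DTYPE) for i in range(4)]
        self.out_length = length // (spec.pool_stride**2)
        flat = spec.filters[-1] * self.out_length
        self.Wd = he(flat, (spec.n_classes, flat))
        self.bd = np.zeros(spec.n_classes, dtype=_DTYPE)

    # --- introspection -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b, self.Wd, self.bd]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    def describe(self) -> list[dict]:
        """Layer-by-layer summary with per-layer parameter counts."""
        k = self.spec.kernel_size
        c_in, length = self.input_shape
        layers = []
        chans = [c_in, *self.spec.filters]
        l = length
        for i in range(4):
            layers.append(
                {
                    "layer": f"conv{i + 1}",
                    "filters": chans[i + 1],
                    "kernel": k,
                    "out": (chans[i + 1], l),
                    "params": chans[i + 1] * (chans[i] * k + 1),
                }
            )
            if i in (1, 3):
                l //= self.spec.pool_stride
                layers.append(
                    {"layer": f"pool{i // 2 + 1}", "stride": self.spec.pool_stride,
                     "out": (chans[i + 1], l), "params": 0}
                )
        layers.append(
            {
                "layer": "dense",
                "out": (self.spec.n_classes,),
                "params": self.spec.n_classes * (self.spec.filters[-1] * l + 1),
            }
        )
        return layers

    # --- forward / backward -------------------------------------------
    def _conv_forward(self, x: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
        c, n, l = x.shape
        xc = _im2col(x, self.spec.kernel_size)
        a = (self.W[i] @ xc).reshape(-1, n, l)
        a += self.b[i][:, None, None]
        np.maximum(a, 0.0, out=a)
        return a, xc

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (n, c, l) float array -> logits (n, n_classes).

        With ``want_cache`` the intermediate buffers needed by
        :meth:`backward` are returned as well.
        """
        n = x.shape[0]
        s = self.spec.pool_stride
        xcm = np.ascontiguousarray(x.transpose(1, 0, 2), dtype=_DTYPE)
        a1, xc1 = self._conv_forward(xcm, 0)
        a2, xc2 = self._conv_forward(a1, 1)
        f2, _, l2 = a2.shape
        a2r = a2.reshape(f2, n, l2 // s, s)
        p1 = a2r.max(axis=3)
        a3, xc3 = self._conv_forward(p1, 2)
        a4, xc4 = self._conv_forward(a3, 3)
        f4, _, l4 = a4.shape
        a4r = a4.reshape(f4, n, l4 // s, s)
        p2 = a4r.max(axis=3)
        flat = np.ascontiguousarray(p2.transpose(1, 0, 2)).reshape(n, -1)
        logits = flat @ self.Wd.T + self.bd
        if not want_cache:
            return logits
        cache = (xcm, a1, xc1, a2r, xc2, p1, a3, xc3, a4r, xc4, p2, flat)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients for all parameters, in :attr:`parameters` order."""
        (xcm, a1, xc1, a2r, xc2, p1, a3, xc3, a4r, xc4, p2, flat) = cache
        spec = self.spec
        k = spec.kernel_size
        s = spec.pool_stride
        n = dlogits.shape[0]

        dWd = dlogits.T @ flat
        dbd = dlogits.sum(axis=0)
        dflat = dlogits @ self.Wd  # (n, f4 * l_out)
        f4 = spec.filters[3]
        dp2 = np.ascontiguousarray(
            dflat.reshape(n, f4, -1).transpose(1, 0, 2)
        )  # (f4, n, l_out)

        # unpool 2 (route gradient to the max position)
        dmax4 = (a4r == p2[..., None]).astype(_DTYPE)
        dmax4 /= dmax4.sum(axis=3, keepdims=True)
        d4 = (dmax4 * dp2[..., None]).reshape(f4, n, -1)

        dW = [None] * 4
        db = [None] * 4

        def conv_back(dout, xc, i, c_in, need_dx):
            f = dout.shape[0]
            dr = dout.reshape(f, -1)
            dW[i] = dr @ xc.T
            db[i] = dr.sum(axis=1)
            if not need_dx:
                return None
            dxc = np.ascontiguousarray(self.W[i].T) @ dr
            nl = dout.shape[1] * dout.shape[2]
            return _col2im(dxc, c_in, dout.shape[1], dout.shape[2], k)

        d4 *= a4r.reshape(f4, n, -1) > 0  # ReLU mask of a4 (== cached post-ReLU)
        d3 = conv_back(d4, xc4, 3, spec.filters[2], True)
        d3 *= a3 > 0
        dp1 = conv_back(d3, xc3, 2, spec.filters[1], True)

        f2 = spec.filters[1]
        dmax2 = (a2r == p1[..., None]).astype(_DTYPE)
        dmax2 /= dmax2.sum(axis=3, keepdims=True)
        d2 = (dmax2 * dp1[..., None]).reshape(f2, n, -1)
        d2 *= a2r.reshape(f2, n, -1) > 0
        d1 = conv_back(d2, xc2, 1, spec.filters[0], True)
        d1 *= a1 > 0
        conv_back(d1, xc1, 0, self.input_shape[0], False)
        return [*dW, *db, dWd, dbd]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters, weights):
            p[...] = w


def softmax_cross_entropy(
    logits: np.ndarray, y_onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean CE loss and gradient w.r.t. logits (already divided by batch)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -float(np.sum(y_onehot * np.log(probs + 1e-12)) / n)
    return loss, (probs - y_onehot).astype(_DTYPE) / n


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= (lr * corr) * m / (np.sqrt(v) + self.eps)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from ``base_lr`` to ~0 over the training run."""
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(total_epochs, 1)))


def build_model(
    spec: CNNSpec, input_shape: tuple[int, int] = (8, 120), seed: int = 2023
) -> Conv1DNet:
    """Instantiate the network for a given input shape (channels, length)."""
    return Conv1DNet(spec, input_shape, seed)
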