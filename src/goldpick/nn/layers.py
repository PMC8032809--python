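"""Minimal CPU neural-network primitives with explicit backpropagation.

Only what an image-to-image GAN needs: 4x4 convolutions and transposed
convolutions via im2col/col2im, instance normalization, pointwise
nonlinearities, dropout, and Adam.  Every module caches its last forward
pass and exposes ``backward(grad_out) -> grad_in`` accumulating parameter
gradients in ``.grads``; correctness is pinned by numerical gradient checks
in the test suite.

Tensors are ``(N, C, H, W)`` arrays; parameters default to float32 (plenty
for GAN training and about twice as fast on CPU BLAS), with float64
available via the ``dtype`` constructor argument for gradient checking.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Dropout",
    "Adam",
    "bce_with_logits",
]


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Extract k x k windows from a padded (N,C,H,W) tensor.

    Returns ``(N, OH, OW, C, k, k)`` (a view followed by one copy on reshape
    downstream).
    """
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H',W',k,k)
    win = win[:, :, ::stride, ::stride]
    return win.transpose(0, 2, 3, 1, 4, 5)


def _col2im(
    dcols: np.ndarray, padded_shape: tuple[int, int, int, int], k: int, stride: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add windows back into the raster."""
    n, c, hp, wp = padded_shape
    oh, ow = dcols.shape[1], dcols.shape[2]
    out = np.zeros(padded_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return out


class Module:
    """Base class: parameter/grad dicts plus cached-forward backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = np.array(v, dtype=self.params[k].dtype)
            self.grads[k] = np.zeros_like(self.params[k])


class Conv2d(Module):
    """k x k convolution, weights ~ N(0, 0.02) as in the pix2pix lineage."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.params["w"] = rng.normal(0.0, 0.02, size=(c_out, c_in * k * k)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._xp_shape: tuple[int, int, int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, self.k, self.stride)
        n, oh, ow = cols.shape[:3]
        cols2 = cols.reshape(n, oh, ow, -1)
        if train:
            self._cols = cols2
            self._xp_shape = xp.shape
        y = cols2 @ self.params["w"].T + self.params["b"]
        return y.transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._cols is not None
        g = gy.transpose(0, 2, 3, 1)  # (N,OH,OW,Cout)
        flat_g = g.reshape(-1, self.c_out)
        self.grads["w"] += flat_g.T @ self._cols.reshape(-1, self._cols.shape[-1])
        self.grads["b"] += flat_g.sum(axis=0)
        dcols = (g @ self.params["w"]).reshape(
            g.shape[0], g.shape[1], g.shape[2], self.c_in, self.k, self.k
        )
        dxp = _col2im(dcols, self._xp_shape, self.k, self.stride)
        p = self.pad
        return dxp[:, :, p : dxp.shape[2] - p, p : dxp.shape[3] - p] if p else dxp


class ConvTranspose2d(Module):
    """Transposed k x k convolution (the adjoint of :class:`Conv2d`)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.params["w"] = rng.normal(0.0, 0.02, size=(c_in, c_out * k * k)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._x: np.ndarray | None = None

    def _out_padded_shape(self, x: np.ndarray) -> tuple[int, int, int, int]:
        n, _, h, w = x.shape
        return (n, self.c_out, (h - 1) * self.stride + self.k, (w - 1) * self.stride + self.k)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        n, _, h, w = x.shape
        xt = x.transpose(0, 2, 3, 1)  # (N,H,W,Cin)
        dcols = (xt @ self.params["w"]).reshape(n, h, w, self.c_out, self.k, self.k)
        yp = _col2im(dcols, self._out_padded_shape(x), self.k, self.stride)
        p = self.pad
        y = yp[:, :, p : yp.shape[2] - p, p : yp.shape[3] - p] if p else yp
        return y + self.params["b"][None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        p = self.pad
        gp = np.pad(gy, ((0, 0), (0, 0), (p, p), (p, p))) if p else gy
        cols = _im2col(gp, self.k, self.stride)  # (N,H,W,Cout,k,k)
        n, h, w = cols.shape[:3]
        cols2 = cols.reshape(n, h, w, -1)
        xt = self._x.transpose(0, 2, 3, 1).reshape(-1, self.c_in)
        self.grads["w"] += xt.T @ cols2.reshape(-1, cols2.shape[-1])
        self.grads["b"] += gy.sum(axis=(0, 2, 3))
        gx = cols2 @ self.params["w"].T  # (N,H,W,Cin)
        return gx.transpose(0, 3, 1, 2)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivstd
        if train:
            self._cache = (xhat, ivstd)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, ivstd = self._cache
        m = xhat.shape[2] * xhat.shape[3]
        self.grads["gamma"] += (gy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += gy.sum(axis=(0, 2, 3))
        dxhat = gy * self.params["gamma"][None, :, None, None]
        # classic normalized-input gradient, per (sample, channel)
        s1 = dxhat.sum(axis=(2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        return ivstd * (dxhat - s1 / m - xhat * s2 / m)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.slope * gy)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class Tanh(Module):
    def __init__(self) -> None:
        super().__init__()
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * (1.0 - self._y**2)


class Dropout(Module):
    """Inverted dropout; identity in eval mode (inference stays deterministic)."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        self._mask = keep / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class Adam:
    """Adam with beta1=0.5, the de-facto GAN setting.

    On construction, all module parameters and gradients are repacked as
    views into two contiguous buffers so the update runs as a handful of
    whole-buffer vector operations rather than per-tensor loops.
    """

    def __init__(
        self,
        modules: list[Module],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.modules = modules
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        total = sum(p.size for mod in modules for p in mod.params.values())
        dtype = next(iter(modules[0].params.values())).dtype if modules else np.float32
        self._p = np.empty(total, dtype=dtype)
        self._g = np.zeros(total, dtype=dtype)
        off = 0
        for mod in modules:
            for k, p in mod.params.items():
                n = p.size
                self._p[off : off + n] = p.ravel()
                mod.params[k] = self._p[off : off + n].reshape(p.shape)
                mod.grads[k] = self._g[off : off + n].reshape(p.shape)
                off += n
        self._m = np.zeros(total, dtype=dtype)
        self._v = np.zeros(total, dtype=dtype)
        self._scratch = np.empty(total, dtype=dtype)

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        g, m, v, upd = self._g, self._m, self._v, self._scratch
        m *= b1
        m += (1 - b1) * g
        np.multiply(g, g, out=upd)
        v *= b2
        v += (1 - b2) * upd
        np.divide(v, bias2, out=upd)
        np.sqrt(upd, out=upd)
        upd += self.eps
        np.divide(m, upd, out=upd)
        self._p -= (self.lr * lr_scale / bias1) * upd

    def zero_grad(self) -> None:
        self._g[...] = 0.0


def bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits against a constant label.

    Returns ``(loss, dloss/dz)`` using the numerically stable softplus form.
    """
    loss = float(np.mean(np.logaddexp(0.0, z) - target * z))
    grad = (1.0 / (1.0 + np.exp(-z)) - target) / z.size
    return loss, grad
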