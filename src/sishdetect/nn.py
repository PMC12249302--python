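"""Minimal pure-numpy convolutional encoder-decoder with backprop.

A small U-Net-style network: a contracting path (3x3 conv + ReLU blocks,
2x2 max-pooling) for context, an expansive path (nearest-neighbour
upsampling, skip concatenation, conv blocks) for localization, and two
1x1 heads — object-probability logits and non-negative radial distances
(softplus).  Convolutions run as im2col + matmul so both passes are a
handful of BLAS calls; everything is float32 and deterministic given the
init seed.

This is deliberately tiny: the package trains desk-scale networks on CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .errors import ConfigError

F32 = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patches with same-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = xshape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j]
    return dxp[:, :, p : p + h, p : p + w]


class Conv:
    """k x k convolution (same padding), optional fused ReLU."""

    def __init__(self, c_in: int, c_out: int, k: int, relu: bool, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.k = k
        self.relu = relu
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        n, c, h, w = x.shape
        cols = _im2col(x, self.k) if self.k > 1 else x.transpose(0, 2, 3, 1).reshape(-1, c)
        self._cols = cols
        y = cols @ self.w.T + self.b
        y = y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        if self.relu:
            y = np.maximum(y, 0)
            self._mask = y > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        n, co, h, w = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, co)
        self.dw += dyf.T @ self._cols
        self.db += dyf.sum(axis=0)
        dcols = dyf @ self.w
        if self.k > 1:
            return _col2im(dcols, self._xshape, self.k)
        c = self._xshape[1]
        return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def _maxpool(x: np.ndarray):
    n, c, h, w = x.shape
    v = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = v.max(axis=(3, 5))
    argmask = v == y[:, :, :, None, :, None]
    # break ties deterministically: keep only the first max per window
    flat = argmask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    argmask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return y, argmask


def _maxpool_back(dy: np.ndarray, argmask: np.ndarray) -> np.ndarray:
    n, c, h2, _, w2, _ = argmask.shape
    d = argmask * dy[:, :, :, None, :, None]
    return d.reshape(n, c, h2 * 2, w2 * 2)


def _upsample(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_back(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class StarConvexNet:
    """Encoder-decoder predicting (prob logits, softplus radial distances)."""

    def __init__(self, n_rays: int, depth: int = 3, base_filters: int = 32,
                 in_channels: int = 3, seed: int = 0, dist_scale: float = 5.0):
        if depth < 1:
            raise ConfigError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.n_rays = n_rays
        self.dist_scale = float(dist_scale)
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.enc: list[list[Conv]] = []
        c_prev = in_channels
        for level in range(depth):
            f = base_filters * 2**level
            self.enc.append([Conv(c_prev, f, 3, True, rng), Conv(f, f, 3, True, rng)])
            c_prev = f
        fb = base_filters * 2**depth
        self.mid = [Conv(c_prev, fb, 3, True, rng), Conv(fb, fb, 3, True, rng)]
        c_prev = fb
        self.dec: list[list[Conv]] = []
        for level in reversed(range(depth)):
            f = base_filters * 2**level
            self.dec.append(
                [Conv(c_prev + f, f, 3, True, rng), Conv(f, f, 3, True, rng)]
            )
            c_prev = f
        self.head_prob = Conv(c_prev, 1, 1, False, rng)
        self.head_dist = Conv(c_prev, n_rays, 1, False, rng)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray):
        """x: (N, C, H, W) float32, H and W multiples of 2**depth."""
        if x.shape[2] % 2**self.depth or x.shape[3] % 2**self.depth:
            raise ConfigError(
                f"input spatial size {x.shape[2:]} must be a multiple of 2^depth={2**self.depth}"
            )
        skips, pools = [], []
        h = x
        for block in self.enc:
            for conv in block:
                h = conv.forward(h)
            skips.append(h)
            h, am = _maxpool(h)
            pools.append(am)
        for conv in self.mid:
            h = conv.forward(h)
        self._concat_widths = []
        for i, block in enumerate(self.dec):
            h = _upsample(h)
            skip = skips[-(i + 1)]
            self._concat_widths.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            for conv in block:
                h = conv.forward(h)
        logits = self.head_prob.forward(h)[:, 0]
        zd = self.head_dist.forward(h)
        self._zd = zd
        # softplus times a fixed output scale: radii train in O(1) units
        dist = self.dist_scale * np.logaddexp(0, zd)
        self._pools = pools
        return logits, dist

    def backward(self, dlogits: np.ndarray, ddist: np.ndarray) -> None:
        dzd = self.dist_scale * ddist * expit(self._zd)
        dh = self.head_dist.backward(dzd.astype(F32))
        dh += self.head_prob.backward(dlogits[:, None].astype(F32))
        skip_grads = []
        for i, block in enumerate(reversed(self.dec)):
            for conv in reversed(block):
                dh = conv.backward(dh)
            wskip = self._concat_widths[-(i + 1)]
            skip_grads.append(dh[:, :wskip])
            dh = _upsample_back(dh[:, wskip:])
        for conv in reversed(self.mid):
            dh = conv.backward(dh)
        # skip_grads[j] pairs with skips[j] (shallow first)
        for i, block in enumerate(reversed(self.enc)):
            dh = _maxpool_back(dh, self._pools[-(i + 1)])
            dh += skip_grads[len(skip_grads) - 1 - i]
            for conv in reversed(block):
                dh = conv.backward(dh)

    # -- parameter plumbing ------------------------------------------------
    def _convs(self) -> list[Conv]:
        convs = []
        for block in self.enc:
            convs.extend(block)
        convs.extend(self.mid)
        for block in self.dec:
            convs.extend(block)
        convs.extend([self.head_prob, self.head_dist])
        return convs

    def params(self):
        out = []
        for conv in self._convs():
            out.extend(conv.params())
        return out

    def zero_grad(self) -> None:
        for conv in self._convs():
            conv.dw[:] = 0
            conv.db[:] = 0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights, strict=True):
            p[:] = w

    def flat_weights(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p, _ in self.params()])

    def set_flat_weights(self, flat: np.ndarray) -> None:
        i = 0
        for p, _ in self.params():
            p[:] = flat[i : i + p.size].reshape(p.shape)
            i += p.size
        if i != flat.size:
            raise ConfigError("flat weight vector does not match architecture")


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, net: StarConvexNet, lr: float, momentum: float):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p) for p, _ in net.params()]

    def step(self) -> None:
        for v, (p, g) in zip(self.vel, self.net.params()):
            v *= self.momentum
            v -= self.lr * g
            p += v
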