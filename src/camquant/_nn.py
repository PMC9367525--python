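"""Minimal CPU neural-network engine used by :mod:`camquant.segmentation`.

Implements exactly the pieces a small encoder–decoder segmenter needs —
3x3/1x1 convolutions via im2col, ReLU, 2x2 max-pooling, nearest-neighbour
upsampling and Adam — with hand-written backward passes.  Everything is
float32 and deterministic for a fixed seed; there is no GPU path and no
autograd graph, just layers that cache what their backward pass needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "UNet",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0):
    """Binary cross-entropy on logits.

    Returns ``(loss, dlogits)`` where the gradient is already divided by the
    number of elements.  ``pos_weight`` multiplies the loss of positive
    (vessel) pixels, trading precision for recall on imbalanced masks.
    """
    z = logits.astype(np.float32)
    y = targets.astype(np.float32)
    # log(1 + e^-|z|) + max(z, 0) - z*y  is the standard stable form.
    softplus = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)
    per_px = softplus - z * y
    # positive pixels get an extra (pos_weight - 1) * (-log sigmoid(z))
    if pos_weight != 1.0:
        neg_log_sig = softplus - z
        per_px = per_px + (pos_weight - 1.0) * y * neg_log_sig
    loss = float(per_px.mean())
    s = sigmoid(z)
    dz = (s * (1.0 + (pos_weight - 1.0) * y) - pos_weight * y) / z.size
    return loss, dz.astype(np.float32)


class Conv2d:
    """3x3 (same padding) or 1x1 convolution with bias, He-initialised."""

    def __init__(self, cin: int, cout: int, ksize: int = 3, *, rng: np.random.Generator):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.ksize = cin, cout, ksize
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        self.w = rng.normal(0.0, std, size=(cout, cin, ksize, ksize)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    # -- im2col helpers ----------------------------------------------------
    @staticmethod
    def _im2col3(x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((B, 9 * C, H * W), dtype=np.float32)
        k = 0
        for di in range(3):
            for dj in range(3):
                cols[:, k * C:(k + 1) * C, :] = (
                    xp[:, :, di:di + H, dj:dj + W].reshape(B, C, H * W)
                )
                k += 1
        return cols

    @staticmethod
    def _col2im3(dcols: np.ndarray, shape) -> np.ndarray:
        B, C, H, W = shape
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=np.float32)
        k = 0
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + H, dj:dj + W] += (
                    dcols[:, k * C:(k + 1) * C, :].reshape(B, C, H, W)
                )
                k += 1
        return dxp[:, :, 1:-1, 1:-1]

    def _wmat(self) -> np.ndarray:
        # layout must match _im2col3 stacking: (di, dj) outer, channel inner
        return self.w.transpose(0, 2, 3, 1).reshape(self.cout, -1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        if self.ksize == 1:
            wmat = self.w.reshape(self.cout, self.cin)
            y = np.einsum("oc,bchw->bohw", wmat, x, optimize=True)
            y += self.b[None, :, None, None]
            if train:
                self._cache = ("1x1", x)
            return y
        cols = self._im2col3(x)
        y = (self._wmat()[None] @ cols).reshape(B, self.cout, H, W)
        y += self.b[None, :, None, None]
        if train:
            self._cache = ("3x3", cols, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward(train=True)")
        self.db += dy.sum(axis=(0, 2, 3))
        if self._cache[0] == "1x1":
            _, x = self._cache
            wmat = self.w.reshape(self.cout, self.cin)
            self.dw += np.einsum("bohw,bchw->oc", dy, x, optimize=True).reshape(
                self.w.shape
            )
            dx = np.einsum("oc,bohw->bchw", wmat, dy, optimize=True)
        else:
            _, cols, xshape = self._cache
            B, C, H, W = xshape
            dyf = dy.reshape(B, self.cout, H * W)
            dwmat = np.einsum("bop,bcp->oc", dyf, cols, optimize=True)
            self.dw += (
                dwmat.reshape(self.cout, 3, 3, self.cin).transpose(0, 3, 1, 2)
            )
            dcols = self._wmat().T[None] @ dyf
            dx = self._col2im3(dcols, xshape)
        self._cache = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling; ties split their gradient evenly."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("pooling requires even spatial dimensions")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            mask = (xr == y[:, :, :, None, :, None]).astype(np.float32)
            mask /= mask.sum(axis=(3, 5), keepdims=True)
            self._cache = (mask, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, (B, C, H, W) = self._cache
        dxr = mask * dy[:, :, :, None, :, None]
        self._cache = None
        return dxr.reshape(B, C, H, W)


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class UNet:
    """Compact encoder–decoder with skip connections.

    ``depth`` counts resolution levels including the bottleneck; channel
    width doubles per level starting from ``base``.  Input height/width must
    be divisible by ``2**(depth-1)``.
    """

    def __init__(self, in_ch: int = 3, depth: int = 4, base: int = 8, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.in_ch, self.depth, self.base = in_ch, depth, base
        rng = np.random.default_rng(seed)
        ch = [base * 2 ** i for i in range(depth)]
        self.enc = []
        cin = in_ch
        for c in ch[:-1]:
            self.enc.append(
                (Conv2d(cin, c, rng=rng), ReLU(), Conv2d(c, c, rng=rng), ReLU())
            )
            cin = c
        self.pools = [MaxPool2() for _ in ch[:-1]]
        cb = ch[-1]
        self.bott = (Conv2d(cin, cb, rng=rng), ReLU(), Conv2d(cb, cb, rng=rng), ReLU())
        self.ups = [Upsample2() for _ in ch[:-1]]
        self.dec = []
        clow = cb
        for c in reversed(ch[:-1]):
            self.dec.append(
                (Conv2d(clow + c, c, rng=rng), ReLU(), Conv2d(c, c, rng=rng), ReLU())
            )
            clow = c
        self.head = Conv2d(ch[0], 1, ksize=1, rng=rng)
        self._skip_ch = list(reversed(ch[:-1]))

    @property
    def stride(self) -> int:
        return 2 ** (self.depth - 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bott:
            h = layer.forward(h, train)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([h, skip], axis=1)
            for layer in block:
                h = layer.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, block, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)
        ):
            for layer in reversed(block):
                d = layer.backward(d)
            dskips.append(d[:, -c_skip:])
            d = up.backward(d[:, :-c_skip])
        for layer in reversed(self.bott):
            d = layer.backward(d)
        # dskips is in top-down encoder order; walk the encoder bottom-up
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d) + dskip
            for layer in reversed(block):
                d = layer.backward(d)

    # -- parameter access --------------------------------------------------
    def _convs(self):
        for block in self.enc:
            yield block[0]
            yield block[2]
        yield self.bott[0]
        yield self.bott[2]
        for block in self.dec:
            yield block[0]
            yield block[2]
        yield self.head

    def params(self):
        out = []
        for conv in self._convs():
            out.extend(conv.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match architecture")
        for (p, _), w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
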