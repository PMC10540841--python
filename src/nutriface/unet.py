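"""A NumPy U-net for binary segmentation, trained with RMSProp.

Encoder-decoder with skip connections: each resolution level applies two
3x3 same-padding convolutions with ReLU; levels are joined by 2x2 max
pooling on the way down and 2x2 stride-2 transposed convolutions plus
channel concatenation on the way up; a final 1x1 convolution and sigmoid
produce a per-pixel foreground probability.  Channels double at each level
from ``base_channels``.

Convolutions run as im2col + BLAS matmul in float32; gradients are derived
by hand layer by layer.  The optimizer matches the common RMSProp-with-
momentum formulation: a running mean of squared gradients normalizes each
step, and a momentum buffer accumulates the normalized steps.  Everything
is seeded and single-threaded-deterministic: same data, config and seed
give the same trained weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "RMSProp", "bce_loss"]

_F = np.float32


# --- layer primitives -------------------------------------------------------

def _conv3_forward(x, w, b):
    """x: (Cin,H,W); w: (Cout, Cin*9); b: (Cout,). Same padding."""
    cin, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    cols = np.empty((cin, 3, 3, h, wd), dtype=_F)
    for di in range(3):
        for dj in range(3):
            cols[:, di, dj] = xp[:, di : di + h, dj : dj + wd]
    cols = cols.reshape(cin * 9, h * wd)
    y = (w @ cols + b[:, None]).reshape(-1, h, wd)
    return y, cols


def _conv3_backward(dy, cols, w, x_shape):
    cin, h, wd = x_shape
    dy2 = dy.reshape(dy.shape[0], -1)
    dw = dy2 @ cols.T
    db = dy2.sum(axis=1)
    dcols = (w.T @ dy2).reshape(cin, 3, 3, h, wd)
    dxp = np.zeros((cin, h + 2, wd + 2), dtype=_F)
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + wd] += dcols[:, di, dj]
    return dxp[:, 1:-1, 1:-1], dw, db


def _conv1_forward(x, w, b):
    cin, h, wd = x.shape
    y = (w @ x.reshape(cin, -1) + b[:, None]).reshape(-1, h, wd)
    return y


def _conv1_backward(dy, x, w):
    dy2 = dy.reshape(dy.shape[0], -1)
    x2 = x.reshape(x.shape[0], -1)
    return (w.T @ dy2).reshape(x.shape), dy2 @ x2.T, dy2.sum(axis=1)


def _maxpool(x):
    c, h, w = x.shape
    v = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(
        c, h // 2, w // 2, 4
    )
    arg = v.argmax(axis=-1)
    return v.max(axis=-1), (arg, x.shape)


def _maxpool_backward(dy, cache):
    arg, shape = cache
    c, h, w = shape
    dv = np.zeros((c, h // 2, w // 2, 4), dtype=_F)
    np.put_along_axis(dv, arg[..., None], dy[..., None], axis=-1)
    return (
        dv.reshape(c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 3, 2, 4)
        .reshape(c, h, w)
    )


def _upconv_forward(x, w, b):
    """2x2 stride-2 transposed conv. w: (2, 2, Cout, Cin); b: (Cout,)."""
    cin, h, wd = x.shape
    cout = w.shape[2]
    x2 = x.reshape(cin, -1)
    y = np.empty((cout, 2 * h, 2 * wd), dtype=_F)
    for a in range(2):
        for c in range(2):
            y[:, a::2, c::2] = (w[a, c] @ x2 + b[:, None]).reshape(cout, h, wd)
    return y


def _upconv_backward(dy, x, w):
    cin, h, wd = x.shape
    x2 = x.reshape(cin, -1)
    dx = np.zeros((cin, h * wd), dtype=_F)
    dw = np.zeros_like(w)
    db = np.zeros(w.shape[2], dtype=_F)
    for a in range(2):
        for c in range(2):
            dya = dy[:, a::2, c::2].reshape(w.shape[2], -1)
            dw[a, c] = dya @ x2.T
            db += dya.sum(axis=1)
            dx += w[a, c].T @ dya
    return dx.reshape(x.shape), dw, db


def bce_loss(prob, target):
    """Mean binary cross-entropy; target in {0,1}, prob in (0,1)."""
    p = np.clip(prob, 1e-7, 1.0 - 1e-7)
    return float(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean())


# --- the network ------------------------------------------------------------

class UNet:
    """Binary-segmentation U-net over single-channel images.

    ``levels`` counts resolution scales (so ``levels - 1`` poolings); the
    input side length must be divisible by ``2**(levels-1)``.
    """

    def __init__(self, base_channels: int = 64, levels: int = 4,
                 in_channels: int = 1, seed: int = 0, out_bias: float = 0.0):
        if levels < 2:
            raise ValueError("need at least 2 levels")
        self.base_channels = base_channels
        self.levels = levels
        self.in_channels = in_channels
        self.seed = seed
        self.out_bias = out_bias
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCAFE]))

        def conv_init(name, cin, cout, k=3):
            fan_in = cin * k * k
            std = np.sqrt(2.0 / fan_in)
            self.params[f"{name}_w"] = rng.normal(
                0.0, std, (cout, cin * k * k)
            ).astype(_F)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=_F)

        chans = [base_channels * 2**l for l in range(levels)]
        cin = in_channels
        for l in range(levels):
            conv_init(f"enc{l}_c1", cin, chans[l])
            conv_init(f"enc{l}_c2", chans[l], chans[l])
            cin = chans[l]
        for l in reversed(range(levels - 1)):
            cout = chans[l]
            cin_up = chans[l + 1]
            std = np.sqrt(2.0 / (cin_up * 4))
            self.params[f"up{l}_w"] = rng.normal(
                0.0, std, (2, 2, cout, cin_up)
            ).astype(_F)
            self.params[f"up{l}_b"] = np.zeros(cout, dtype=_F)
            conv_init(f"dec{l}_c1", 2 * cout, cout)
            conv_init(f"dec{l}_c2", cout, cout)
        conv_init("out", chans[0], 1, k=1)
        # initializing the output bias at the prior log-odds of the (sparse)
        # foreground lets early updates focus on the region of interest
        self.params["out_b"][:] = out_bias

    # -- forward/backward

    def _double_conv(self, name, x, cache):
        p = self.params
        y1, cols1 = _conv3_forward(x, p[f"{name}_c1_w"], p[f"{name}_c1_b"])
        a1 = np.maximum(y1, 0.0)
        y2, cols2 = _conv3_forward(a1, p[f"{name}_c2_w"], p[f"{name}_c2_b"])
        a2 = np.maximum(y2, 0.0)
        cache[name] = (x.shape, cols1, y1 > 0, a1.shape, cols2, y2 > 0)
        return a2

    def _double_conv_backward(self, name, da2, cache, grads):
        p = self.params
        x_shape, cols1, m1, a1_shape, cols2, m2 = cache[name]
        dy2 = da2 * m2
        da1, dw2, db2 = _conv3_backward(dy2, cols2, p[f"{name}_c2_w"], a1_shape)
        grads[f"{name}_c2_w"] = dw2
        grads[f"{name}_c2_b"] = db2
        dy1 = da1 * m1
        dx, dw1, db1 = _conv3_backward(dy1, cols1, p[f"{name}_c1_w"], x_shape)
        grads[f"{name}_c1_w"] = dw1
        grads[f"{name}_c1_b"] = db1
        return dx

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (H, W) or (C, H, W) float in [0,1] -> probability map (H, W)."""
        if x.ndim == 2:
            x = x[None]
        x = np.ascontiguousarray(x, dtype=_F)
        h, w = x.shape[1:]
        f = 2 ** (self.levels - 1)
        if h % f or w % f:
            raise ValueError(f"input side must be divisible by {f}")

        cache: dict = {"input_shape": x.shape}
        skips = {}
        hcur = x
        for l in range(self.levels - 1):
            hcur = self._double_conv(f"enc{l}", hcur, cache)
            skips[l] = hcur
            hcur, pc = _maxpool(hcur)
            cache[f"pool{l}"] = pc
        hcur = self._double_conv(f"enc{self.levels - 1}", hcur, cache)

        for l in reversed(range(self.levels - 1)):
            up_in = hcur
            hcur = _upconv_forward(
                up_in, self.params[f"up{l}_w"], self.params[f"up{l}_b"]
            )
            cache[f"up{l}_in"] = up_in
            cat = np.concatenate([skips[l], hcur], axis=0)
            cache[f"cat{l}_split"] = skips[l].shape[0]
            hcur = self._double_conv(f"dec{l}", cat, cache)

        logits = _conv1_forward(hcur, self.params["out_w"], self.params["out_b"])
        cache["out_in"] = hcur
        z = logits[0]
        prob = np.where(  # numerically stable sigmoid
            z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
            np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))),
        )
        if want_cache:
            return prob, cache
        return prob

    def backward(self, prob, target, cache):
        """Gradients of mean BCE w.r.t. all parameters.

        Uses the combined sigmoid+BCE gradient (prob - target)/N on the
        logits, which is exact and numerically stable.
        """
        grads: dict[str, np.ndarray] = {}
        n = prob.size
        dlogits = ((prob - target) / n).astype(_F)[None]
        dh, dw, db = _conv1_backward(
            dlogits, cache["out_in"], self.params["out_w"]
        )
        grads["out_w"] = dw
        grads["out_b"] = db

        for l in range(self.levels - 1):
            dcat = self._double_conv_backward(f"dec{l}", dh, cache, grads)
            split = cache[f"cat{l}_split"]
            dskip, dup = dcat[:split], dcat[split:]
            dupin, dw, db = _upconv_backward(
                dup, cache[f"up{l}_in"], self.params[f"up{l}_w"]
            )
            grads[f"up{l}_w"] = dw
            grads[f"up{l}_b"] = db
            cache[f"dskip{l}"] = dskip
            dh = dupin

        dh = self._double_conv_backward(f"enc{self.levels - 1}", dh, cache, grads)
        for l in reversed(range(self.levels - 1)):
            dh = _maxpool_backward(dh, cache[f"pool{l}"])
            dh = dh + cache[f"dskip{l}"]
            dh = self._double_conv_backward(f"enc{l}", dh, cache, grads)
        return grads

    # -- persistence

    def state(self) -> dict:
        arch = {
            "base_channels": self.base_channels,
            "levels": self.levels,
            "in_channels": self.in_channels,
            "seed": self.seed,
            "out_bias": self.out_bias,
        }
        return {"arch": arch, "params": dict(self.params)}

    @classmethod
    def from_state(cls, arch: dict, params: dict) -> "UNet":
        net = cls(**arch)
        for k in net.params:
            net.params[k] = np.asarray(params[k], dtype=_F)
        return net


class RMSProp:
    """RMSProp with momentum and L2 weight decay.

    Update per parameter: ``g += wd * w``; ``s = alpha*s + (1-alpha)*g^2``;
    ``buf = momentum*buf + g/(sqrt(s/(1-alpha^t)) + eps)``; ``w -= lr*buf``.

    The running square average is divided by ``1 - alpha**t`` before the
    square root (the same correction Adam applies), so early steps are
    scaled by the gradient magnitude actually observed rather than by the
    arbitrary zero initialization of the accumulator; after the burn-in of
    a long schedule the correction factor is 1 and the update coincides
    with the textbook rule.
    """

    def __init__(self, params: dict, lr: float = 1e-5, alpha: float = 0.99,
                 eps: float = 1e-8, weight_decay: float = 1e-8,
                 momentum: float = 0.9):
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.t = 0
        self.sq = {k: np.zeros_like(v) for k, v in params.items()}
        self.buf = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        corr = 1.0 - self.alpha**self.t
        for k, w in params.items():
            g = grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * w
            s = self.sq[k]
            s *= self.alpha
            s += (1.0 - self.alpha) * g * g
            b = self.buf[k]
            b *= self.momentum
            b += g / (np.sqrt(s / corr) + self.eps)
            w -= self.lr * b
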