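"""Minimal reverse-mode autodiff and neural-network layers on numpy.

Only what the detector needs: 2-D convolution (im2col + BLAS matmul),
batch normalization, ReLU, max pooling, nearest-neighbor upsampling,
channel concatenation, fully connected layers, RoI Align, and the three
loss primitives (softmax cross-entropy, sigmoid binary cross-entropy,
smooth L1).  Tensors are float32; gradients are accumulated through a
topologically sorted tape.

Parameters carry a dotted ``name`` so training phases can select trainable
subsets by prefix, and a ``trainable`` flag the optimizer honours.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "BatchNorm2d", "Linear",
    "relu", "add", "concat", "maxpool2d", "upsample_nearest2", "subsample2",
    "flatten", "roi_align", "softmax_cross_entropy", "bce_with_logits",
    "smooth_l1", "SGD", "he_init",
]


# ---------------------------------------------------------------------------
# autodiff core

class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    __slots__ = ("name", "trainable")

    def __init__(self, data, name: str = "", trainable: bool = True):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.trainable = trainable


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad),
                  backward=backward if req else None)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


# ---------------------------------------------------------------------------
# elementwise / structural ops

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x._accum(g * mask)

    return _make(out_data, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    return _make(a.data + b.data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o, s in zip(tensors, offsets[:-1], sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o, o + s)
                t._accum(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def flatten(x: Tensor) -> Tensor:
    shape = x.data.shape

    def backward(g):
        x._accum(g.reshape(shape))

    return _make(x.data.reshape(shape[0], -1), (x,), backward)


def scale(x: Tensor, c: float) -> Tensor:
    def backward(g):
        x._accum(g * c)

    return _make(x.data * c, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape

    def backward(g):
        x._accum(g.reshape(old))

    return _make(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        x._accum(g.transpose(inv))

    return _make(np.ascontiguousarray(x.data.transpose(axes)), (x,), backward)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)
    unique = len(np.unique(idx)) == len(idx)

    def backward(g):
        dx = np.zeros_like(x.data)
        if unique:
            dx[idx] = g
        else:
            np.add.at(dx, idx, g)
        x._accum(dx)

    return _make(x.data[idx], (x,), backward)


def weighted_sum(terms: list[tuple[Tensor, float]]) -> Tensor:
    """Σ wᵢ·termᵢ over scalar loss tensors."""
    total_data = np.float32(sum(float(t.data) * w for t, w in terms))

    def backward(g):
        for t, w in terms:
            if t.requires_grad:
                t._accum(np.float32(g * w))

    return _make(total_data, tuple(t for t, _ in terms), backward)


# ---------------------------------------------------------------------------
# convolution via im2col

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # xp: padded (N, C, H, W) -> (N, Ho, Wo, C, kh, kw) view copied contiguously
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                 # (N, C, Ho, Wo, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    assert C == Cw, f"channel mismatch {C} vs {Cw}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    col = _im2col(xp, kh, kw, stride).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, -1)
    out = col @ wmat.T
    if b is not None:
        out += b.data
    out_data = out.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, F)
        if w.requires_grad:
            w._accum((gmat.T @ col).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcol = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dcol[:, :, :, :, i, j]
            x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resampling

def maxpool2d(x: Tensor, k: int, stride: int, pad: int = 0) -> Tensor:
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf) if pad else x.data
    N, C, H, W = xp.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win.reshape(N, C, Ho, Wo, k * k)
    arg = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros_like(xp)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            sel = (arg == idx) * g
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += sel
        x._accum(dxp[:, :, pad : pad + x.data.shape[2], pad : pad + x.data.shape[3]] if pad else dxp)

    return _make(out_data, (x,), backward)


def subsample2(x: Tensor) -> Tensor:
    """Stride-2 subsampling (used for the coarsest pyramid level)."""
    out_data = x.data[:, :, ::2, ::2]

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[:, :, ::2, ::2] = g
        x._accum(dx)

    return _make(out_data, (x,), backward)


def upsample_nearest2(x: Tensor, out_hw: tuple[int, int] | None = None) -> Tensor:
    N, C, H, W = x.data.shape
    up = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    oh, ow = out_hw if out_hw is not None else (2 * H, 2 * W)
    out_data = up[:, :, :oh, :ow]

    def backward(g):
        gp = np.zeros((N, C, 2 * H, 2 * W), dtype=np.float32)
        gp[:, :, :oh, :ow] = g
        x._accum(gp.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# RoI Align

def _bilinear_plan(boxes: np.ndarray, H: int, W: int, out: int):
    """Sample locations and corner weights for one sample per output bin."""
    R = boxes.shape[0]
    x0, y0, x1, y1 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    bh = (y1 - y0) / out
    bw = (x1 - x0) / out
    iy = np.arange(out)
    ys = y0[:, None] + (iy[None, :] + 0.5) * bh[:, None] - 0.5        # (R, out)
    xs = x0[:, None] + (iy[None, :] + 0.5) * bw[:, None] - 0.5
    ys = np.clip(ys, 0, H - 1)
    xs = np.clip(xs, 0, W - 1)
    yy = np.broadcast_to(ys[:, :, None], (R, out, out))
    xx = np.broadcast_to(xs[:, None, :], (R, out, out))
    y0i = np.floor(yy).astype(np.int64)
    x0i = np.floor(xx).astype(np.int64)
    y1i = np.minimum(y0i + 1, H - 1)
    x1i = np.minimum(x0i + 1, W - 1)
    wy = yy - y0i
    wx = xx - x0i
    corners = [(y0i, x0i, (1 - wy) * (1 - wx)), (y0i, x1i, (1 - wy) * wx),
               (y1i, x0i, wy * (1 - wx)), (y1i, x1i, wy * wx)]
    return corners


def roi_align(feature: Tensor, boxes: np.ndarray, output_size: int, stride: float = 1.0) -> Tensor:
    """Fixed-size crops from a (1, C, H, W) feature map by bilinear interpolation.

    ``boxes`` are half-open image-coordinate boxes; ``stride`` converts them
    to feature coordinates.  One bilinear sample per output bin, taken at
    the bin center, with no coordinate quantization.
    """
    assert feature.data.shape[0] == 1, "single-image batches only"
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4) / stride
    if boxes.size and ((boxes[:, 2] <= boxes[:, 0]) | (boxes[:, 3] <= boxes[:, 1])).any():
        raise ValueError("non-positive box supplied to roi_align")
    _, C, H, W = feature.data.shape
    R = boxes.shape[0]
    corners = _bilinear_plan(boxes, H, W, output_size)
    fmap = feature.data[0]                                            # (C, H, W)
    out_data = np.zeros((R, C, output_size, output_size), dtype=np.float32)
    for yi, xi, wgt in corners:
        out_data += fmap[:, yi, xi].transpose(1, 0, 2, 3) * wgt[:, None]

    def backward(g):
        acc = np.zeros(H * W * C)
        base = np.arange(C) * (H * W)
        for yi, xi, wgt in corners:
            contrib = (g * wgt[:, None]).transpose(1, 0, 2, 3).reshape(C, -1)
            idx = (base[:, None] + (yi * W + xi).ravel()[None, :]).ravel()
            acc += np.bincount(idx, weights=contrib.ravel(), minlength=H * W * C)
        feature._accum(acc.reshape(C, H, W)[None].astype(np.float32))

    return _make(out_data, (feature,), backward)


# ---------------------------------------------------------------------------
# losses

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows; labels are integer class ids."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()

    def backward(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accum(g * d / n)

    return _make(np.float32(loss), (logits,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean of per-element sigmoid binary cross-entropy."""
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    # stable: log(1+e^-|z|) + max(z,0) - z*t
    per = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    w = np.ones_like(per) if weights is None else np.asarray(weights, dtype=np.float32)
    denom = max(per.size, 1)
    loss = (per * w).sum() / denom

    def backward(g):
        s = expit(z)
        logits._accum(g * w * (s - t) / denom)

    return _make(np.float32(loss), (logits,), backward)


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) over all elements."""
    t = np.asarray(target, dtype=np.float32)
    d = (pred.data - t).astype(np.float64)
    ad = np.abs(d)
    per = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    denom = max(per.size, 1)
    loss = per.sum() / denom

    def backward(g):
        grad = np.where(ad < beta, d / beta, np.sign(d))
        pred._accum(g * grad / denom)

    return _make(np.float32(loss), (pred,), backward)


# ---------------------------------------------------------------------------
# layers

class Module:
    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []

        def walk(v):
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    walk(item)

        for v in vars(self).values():
            walk(v)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.parameters()}
        for m, prefix in self._bn_modules():
            state[prefix + ".running_mean"] = m.running_mean.copy()
            state[prefix + ".running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data = np.asarray(state[p.name], dtype=np.float32).copy()
        for m, prefix in self._bn_modules():
            if prefix + ".running_mean" in state:
                m.running_mean = np.asarray(state[prefix + ".running_mean"], dtype=np.float32).copy()
                m.running_var = np.asarray(state[prefix + ".running_var"], dtype=np.float32).copy()

    def _bn_modules(self) -> list[tuple["BatchNorm2d", str]]:
        out: list[tuple[BatchNorm2d, str]] = []

        def walk(v):
            if isinstance(v, BatchNorm2d):
                out.append((v, v.gamma.name.rsplit(".", 1)[0]))
            elif isinstance(v, Module):
                out.extend(v._bn_modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    walk(item)

        for v in vars(self).values():
            walk(v)
        return out


class Conv2d(Module):
    def __init__(self, rng, cin: int, cout: int, k: int, stride: int = 1, pad: int | None = None,
                 bias: bool = False, name: str = "conv"):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.w = Parameter(he_init(rng, (cout, cin, k, k), cin * k * k), name=name + ".w")
        self.b = Parameter(np.zeros(cout, dtype=np.float32), name=name + ".b") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    ``use_batch_stats`` selects between live batch statistics (training
    from scratch) and the stored running statistics (inference, or
    fine-tuning from a pretrained checkpoint with frozen statistics).
    """

    def __init__(self, c: int, name: str = "bn", momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c, dtype=np.float32), name=name + ".gamma")
        self.beta = Parameter(np.zeros(c, dtype=np.float32), name=name + ".beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.use_batch_stats = True

    def __call__(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        if self.use_batch_stats:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out_data = g.data[None, :, None, None] * xhat + b.data[None, :, None, None]
        batch = self.use_batch_stats

        def backward(grad):
            if g.requires_grad:
                g._accum((grad * xhat).sum(axis=(0, 2, 3)))
            if b.requires_grad:
                b._accum(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = g.data[None, :, None, None] * inv[None, :, None, None]
                if batch:
                    m = grad.shape[0] * grad.shape[2] * grad.shape[3]
                    mean_g = grad.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (grad * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    x._accum(gi * (grad - mean_g - xhat * mean_gx))
                else:
                    x._accum(gi * grad)

        return _make(out_data, (x, g, b), backward)


class Linear(Module):
    def __init__(self, rng, din: int, dout: int, name: str = "fc"):
        self.w = Parameter(he_init(rng, (din, dout), din), name=name + ".w")
        self.b = Parameter(np.zeros(dout, dtype=np.float32), name=name + ".b")

    def __call__(self, x: Tensor) -> Tensor:
        w, b = self.w, self.b
        out_data = x.data @ w.data + b.data

        def backward(g):
            if w.requires_grad:
                w._accum(x.data.T @ g)
            if b.requires_grad:
                b._accum(g.sum(axis=0))
            if x.requires_grad:
                x._accum(g @ w.data.T)

        return _make(out_data, (x, w, b), backward)


# ---------------------------------------------------------------------------
# optimizer

class SGD:
    """SGD with momentum and (coupled) weight decay; honours trainable flags.

    ``clip_norm`` rescales the global gradient norm over all trainable
    parameters before the update, guarding single-image detection training
    against rare loss spikes from hard proposal batches.
    """

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._velocity: dict[int, np.ndarray] = {}

    def step(self) -> None:
        clip_scale = 1.0
        if self.clip_norm is not None:
            sq = sum(
                float((p.grad.astype(np.float64) ** 2).sum())
                for p in self.params
                if p.trainable and p.grad is not None
            )
            norm = np.sqrt(sq)
            if not np.isfinite(norm):
                for p in self.params:
                    p.grad = None
                return
            if norm > self.clip_norm:
                clip_scale = self.clip_norm / norm
        for p in self.params:
            if not p.trainable or p.grad is None:
                continue
            g = p.grad * clip_scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self._velocity.get(id(p))
            if v is None:
                v = np.zeros_like(p.data)
            v = self.momentum * v - self.lr * g
            self._velocity[id(p)] = v
            p.data = p.data + v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
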