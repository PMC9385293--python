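"""Minimal reverse-mode array autodiff for the desk-scale segmenter.

Tensors wrap float64 NumPy arrays in NCHW layout; each op records a backward
closure and gradients are accumulated by a topological sweep.  Only the ops
the segmentation network needs are provided: 2-D convolution (stride,
dilation, zero padding), 2x2 max pooling, ReLU, channel concat/split/shuffle,
broadcast add/multiply, global average pooling, corner-aligned bilinear
upsampling, and a numerically stable binary cross-entropy on logits.

Everything is plain NumPy (im2col convolutions); sizes of interest here are
tens of pixels, where this is fast enough for CPU training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2x2",
    "relu",
    "tanh",
    "add",
    "mul",
    "concat_channels",
    "split_channels",
    "channel_shuffle",
    "global_avg_pool",
    "upsample_bilinear",
    "bce_with_logits",
    "sigmoid_array",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable requires_grad tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float)
        else:
            self.grad += grad


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Elementwise and structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def tanh(x: Tensor) -> Tensor:
    s = np.tanh(x.data)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * (1.0 - s * s))

    return Tensor(s, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def backward(grad):
        start = 0
        for t, c in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(grad[:, start : start + c])
            start += c

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def split_channels(x: Tensor) -> tuple[Tensor, Tensor]:
    c = x.data.shape[1]
    if c % 2 != 0:
        raise ValueError("channel count must be even to split")
    half = c // 2

    def make(lo, hi):
        def backward(grad):
            if x.requires_grad:
                full = np.zeros_like(x.data)
                full[:, lo:hi] = grad
                x._accumulate(full)

        return Tensor(x.data[:, lo:hi], parents=(x,), backward=backward)

    return make(0, half), make(half, c)


def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if c % groups != 0:
        raise ValueError("channels not divisible by groups")
    perm = np.arange(c).reshape(groups, c // groups).T.ravel()
    inv = np.argsort(perm)
    out_data = x.data[:, perm]

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad[:, inv])

    return Tensor(out_data, parents=(x,), backward=backward)


def shuffle_order(n_channels: int, groups: int = 2) -> np.ndarray:
    """The permutation applied by :func:`channel_shuffle` (for inspection)."""
    return np.arange(n_channels).reshape(groups, n_channels // groups).T.ravel()


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(grad / (h * w), x.data.shape).copy())

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# Convolution / pooling / resampling
# ---------------------------------------------------------------------------

def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: int | tuple[int, int] = 0,
) -> Tensor:
    """2-D convolution (cross-correlation), NCHW x (O,C,kh,kw) -> NCHW."""
    kh, kw = w.data.shape[2], w.data.shape[3]
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, hp, wp = xp.shape
    eff_h = (kh - 1) * dilation + 1
    eff_w = (kw - 1) * dilation + 1
    if hp < eff_h or wp < eff_w:
        raise ValueError("input smaller than effective kernel")
    ho = (hp - eff_h) // stride + 1
    wo = (wp - eff_w) // stride + 1
    i = (stride * np.arange(ho))[:, None] + dilation * np.arange(kh)[None, :]  # (ho, kh)
    j = (stride * np.arange(wo))[:, None] + dilation * np.arange(kw)[None, :]  # (wo, kw)
    ib = i[:, None, :, None]  # (ho, 1, kh, 1)
    jb = j[None, :, None, :]  # (1, wo, 1, kw)
    cols = xp[:, :, ib, jb]  # (n, c, ho, wo, kh, kw)
    out_data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(grad):
        if w.requires_grad:
            w._accumulate(np.einsum("nohw,nchwij->ocij", grad, cols, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("nohw,ocij->nchwij", grad, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            np.add.at(dxp, (slice(None), slice(None), ib, jb), dcols)
            if ph or pw:
                dxp = dxp[:, :, ph : hp - ph, pw : wp - pw]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h < 2 or w < 2:
        raise ValueError("spatial dims must be >= 2 for 2x2 pooling")
    h2, w2 = h // 2, w // 2
    xt = x.data[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(grad):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, arg[..., None], grad[..., None], axis=-1)
            dxt = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            dx = np.zeros_like(x.data)
            dx[:, :, : 2 * h2, : 2 * w2] = dxt.reshape(n, c, 2 * h2, 2 * w2)
            x._accumulate(dx)

    return Tensor(out_data, parents=(x,), backward=backward)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Corner-aligned 1-D linear interpolation matrix (n_out x n_in)."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.minimum(np.floor(pos).astype(int), n_in - 2)
    frac = pos - lo
    a[np.arange(n_out), lo] = 1.0 - frac
    a[np.arange(n_out), lo + 1] += frac
    return a


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    ah = _interp_matrix(h, ho)
    aw = _interp_matrix(w, wo)
    out_data = np.einsum("ih,nchw,jw->ncij", ah, x.data, aw, optimize=True)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(np.einsum("ih,ncij,jw->nchw", ah, grad, aw, optimize=True))

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def sigmoid_array(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all elements, numerically stable."""
    z = logits.data
    t = np.asarray(targets, dtype=float)
    if t.shape != z.shape:
        raise ValueError("targets must match logits shape")
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array(loss.mean())

    def backward(grad):
        if logits.requires_grad:
            logits._accumulate(grad * (sigmoid_array(z) - t) / z.size)

    return Tensor(out_data, parents=(logits,), backward=backward)
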