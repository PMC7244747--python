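"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the FD-UNet needs: 2D convolution (stride 1,
"same" padding), 2 x 2 stride-2 transposed convolution, 2 x 2 max pooling,
batch normalization, ReLU, channel concatenation, elementwise add, and mean
squared error.  Tensors form a tape; ``backward`` walks it in reverse
topological order.  Everything is float32 NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "relu",
    "batchnorm",
    "concat",
    "add",
    "mse_loss",
]


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the tape eagerly: large per-step graphs otherwise linger
        # until the cycle collector runs
        for node in topo:
            if node._backward is not None:   # interior node: drop activations
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    ph, pw = kh // 2, kw // 2
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, C, H+p, W+p) -> (B*H*W, C*kh*kw) for stride-1 windows."""
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))     # B,C,H,W,kh,kw
    b, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * kh * kw), (b, h, w)


def _corr2d(x: np.ndarray, weight: np.ndarray,
            cols_cache: list | None = None) -> np.ndarray:
    """Cross-correlation, stride 1, same padding.  weight: (O, C, kh, kw).

    When ``cols_cache`` is given, the im2col matrix is appended to it so the
    backward pass can reuse it for the weight gradient.
    """
    o, c, kh, kw = weight.shape
    if kh == 1 and kw == 1:
        b, _, h, w = x.shape
        out = np.tensordot(weight.reshape(o, c), x, axes=([1], [1]))  # O,B,H,W
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))
    xp = _pad_same(x, kh, kw)
    cols, (b, h, w) = _im2col(xp, kh, kw)
    if cols_cache is not None:
        cols_cache.append(cols)
    out = cols @ weight.reshape(o, -1).T                     # (BHW, O)
    return np.ascontiguousarray(out.reshape(b, h, w, o).transpose(0, 3, 1, 2))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2D convolution (cross-correlation convention)."""
    o, c, kh, kw = weight.data.shape
    cache: list = []
    out_data = _corr2d(x.data, weight.data, cols_cache=cache if kh > 1 else None)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, parents=parents)

    def backward(grad: np.ndarray) -> None:
        b, _, h, w = x.data.shape
        if weight.requires_grad:
            if kh == 1 and kw == 1:
                gw = np.tensordot(grad, x.data, axes=([0, 2, 3], [0, 2, 3]))
                weight._accum(gw.reshape(o, c, 1, 1))
            else:
                g2 = grad.transpose(0, 2, 3, 1).reshape(b * h * w, o)
                weight._accum((g2.T @ cache[0]).reshape(o, c, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation with the flipped, channel-transposed kernel
            w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            x._accum(_corr2d(grad, np.ascontiguousarray(w_flip)))
        cache.clear()

    out._backward = backward
    return out


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2 x 2, stride-2 transposed convolution (exact 2x upsampling).

    weight: (C_in, C_out, 2, 2); output spatial dims are doubled.  With
    kernel == stride the output blocks do not overlap, so the op is a
    reshape-friendly einsum in both directions.
    """
    b, c, h, w = x.shape
    tmp = np.tensordot(x.data, weight.data, axes=([1], [0]))   # B,H,W,O,2,2
    o = weight.data.shape[1]
    out_data = tmp.transpose(0, 3, 1, 4, 2, 5).reshape(b, o, 2 * h, 2 * w)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, parents=parents)

    def backward(grad: np.ndarray) -> None:
        gblk = grad.reshape(b, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # B,H,W,O,2,2
        if weight.requires_grad:
            gw = np.tensordot(x.data, gblk, axes=([0, 2, 3], [0, 1, 2]))   # C,O,2,2
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.tensordot(gblk, weight.data, axes=([3, 4, 5], [1, 2, 3]))  # B,H,W,C
            x._accum(gx.transpose(0, 3, 1, 2))

    out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    blocks = x.data.reshape(b, c, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], grad[..., None], axis=-1)
            gx = gflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gx.reshape(b, c, h, w))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(grad * mask)

    out._backward = backward
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
              training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (B, H, W).

    ``running`` holds the inference-time "mean" and "var" arrays, updated in
    place during training.
    """
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    out = Tensor(out_data, parents=(x, gamma, beta))

    def backward(grad: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accum((grad * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g = grad * gamma.data.reshape(1, -1, 1, 1)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gm = g.sum(axis=(0, 2, 3), keepdims=True)
                gx = (g - gm / m
                      - xhat * (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                      ) * inv.reshape(1, -1, 1, 1)
            else:
                gx = g * inv.reshape(1, -1, 1, 1)
            x._accum(gx)

    out._backward = backward
    return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), parents=tuple(tensors))
    sizes = [t.data.shape[1] for t in tensors]

    def backward(grad: np.ndarray) -> None:
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                t._accum(grad[:, start:start + s])
            start += s

    out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(grad: np.ndarray) -> None:
        if a.requires_grad:
            a._accum(grad)
        if b.requires_grad:
            b._accum(grad)

    out._backward = backward
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=np.float32)
    diff = pred.data - target
    out = Tensor(np.array(np.mean(diff * diff)), parents=(pred,))

    def backward(grad: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accum((2.0 / diff.size) * diff * grad)

    out._backward = backward
    return out
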