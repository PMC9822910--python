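"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for a convolutional encoder-decoder: tensors carry a
float32 array, a gradient slot and closures back to their parents.  Ops are
plain functions building the graph; ``Tensor.backward()`` runs a topological
sweep.  Everything is single-threaded NumPy, so results are deterministic on
one machine for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "add", "mul", "relu", "sigmoid", "conv2d",
           "global_avg_pool", "resize_nearest", "pad_hw", "slice_hw",
           "concat", "sse_loss"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        # parents: sequence of (Tensor, grad_fn) pairs
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p, _ in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(order):
            if node.grad is None:
                continue
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                g = grad_fn(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> np.ndarray:
        return self.data


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(
        a.data + b.data,
        parents=(
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ),
    )
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        parents=(
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ),
    )


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=((x, lambda g: g * mask),))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, parents=((x, lambda g: g * s * (1.0 - s)),))


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D convolution, NCHW layout, square kernel, symmetric padding."""
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    assert cin == cin_w, "channel mismatch"
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - (kh - 1) * dilation - 1) // stride + 1
    wo = (wp - (kw - 1) * dilation - 1) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"input {h}x{w} too small for this convolution")

    out = np.zeros((n, cout, ho, wo), dtype=np.float32)
    cols = {}
    for ky in range(kh):
        for kx in range(kw):
            xs = xp[
                :,
                :,
                ky * dilation : ky * dilation + stride * ho : stride,
                kx * dilation : kx * dilation + stride * wo : stride,
            ]
            cols[(ky, kx)] = xs
            # (cout,cin) . (n,cin,ho,wo) -> (n,cout,ho,wo)
            out += np.tensordot(weight.data[:, :, ky, kx], xs, axes=([1], [1])).transpose(
                1, 0, 2, 3
            )
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)

    def grad_x(g: np.ndarray) -> np.ndarray:
        gxp = np.zeros_like(xp)
        for (ky, kx), _ in cols.items():
            # (cin,cout) . (n,cout,ho,wo) -> (n,cin,ho,wo)
            contrib = np.tensordot(
                weight.data[:, :, ky, kx].T, g, axes=([1], [1])
            ).transpose(1, 0, 2, 3)
            gxp[
                :,
                :,
                ky * dilation : ky * dilation + stride * ho : stride,
                kx * dilation : kx * dilation + stride * wo : stride,
            ] += contrib
        if padding:
            return gxp[:, :, padding : padding + h, padding : padding + w]
        return gxp

    def grad_w(g: np.ndarray) -> np.ndarray:
        gw = np.zeros_like(weight.data)
        for (ky, kx), xs in cols.items():
            # sum over n,ho,wo: (n,cout,ho,wo) x (n,cin,ho,wo) -> (cout,cin)
            gw[:, :, ky, kx] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
        return gw

    parents = [(x, grad_x), (weight, grad_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=tuple(parents))


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def grad_fn(g: np.ndarray) -> np.ndarray:
        return np.broadcast_to(g / (h * w), x.data.shape).astype(np.float32)

    return Tensor(out, parents=((x, grad_fn),))


def resize_nearest(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Nearest-neighbour spatial resize to an arbitrary target size."""
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    rows = (np.arange(ho) * h) // ho
    cols = (np.arange(wo) * w) // wo
    out = x.data[:, :, rows[:, None], cols[None, :]]

    def grad_fn(g: np.ndarray) -> np.ndarray:
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), rows[:, None], cols[None, :]), g)
        return gx

    return Tensor(out, parents=((x, grad_fn),))


def pad_hw(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad bottom/right of the spatial dims."""
    if pad_h == 0 and pad_w == 0:
        return x
    out = np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
    h, w = x.data.shape[2], x.data.shape[3]
    return Tensor(out, parents=((x, lambda g: g[:, :, :h, :w]),))


def slice_hw(x: Tensor, r0: int, r1: int, c0: int, c1: int) -> Tensor:
    out = x.data[:, :, r0:r1, c0:c1]

    def grad_fn(g: np.ndarray) -> np.ndarray:
        gx = np.zeros_like(x.data)
        gx[:, :, r0:r1, c0:c1] = g
        return gx

    return Tensor(out, parents=((x, grad_fn),))


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_grad(i: int):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, parents=tuple((t, make_grad(i)) for i, t in enumerate(tensors)))


def sse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Pixel-wise squared error, summed over pixels, averaged over the batch."""
    t = np.asarray(target, dtype=np.float32)
    diff = pred.data - t
    n = pred.data.shape[0]
    out = np.asarray((diff**2).sum() / n, dtype=np.float32)
    return Tensor(out, parents=((pred, lambda g: (2.0 / n) * diff * g),))
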