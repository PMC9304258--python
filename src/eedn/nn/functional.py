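"""Differentiable array operations used by the denoising networks.

Convolutions are im2col/matmul based: the 3x3 and 1x1 convolutions carry
nearly all of the compute, and a single BLAS matmul per layer is the
fastest route on CPU.  Transposed convolution is implemented as the exact
adjoint of the strided convolution (col2im scatter), so the two share their
correctness logic.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, make_result

__all__ = [
    "add",
    "sub",
    "mul",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "prelu",
    "sigmoid",
    "replicate_pad1",
    "laplacian",
    "charbonnier",
]

LAPLACIAN_STENCIL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]], dtype=np.float32)


def add(x: Tensor, y: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x.accumulate(g)
        if y.requires_grad:
            y.accumulate(g)

    return make_result(x.data + y.data, (x, y), backward)


def sub(x: Tensor, y: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x.accumulate(g)
        if y.requires_grad:
            y.accumulate(-g)

    return make_result(x.data - y.data, (x, y), backward)


def mul(x: Tensor, y: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x.accumulate(g * y.data)
        if y.requires_grad:
            y.accumulate(g * x.data)

    return make_result(x.data * y.data, (x, y), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return make_result(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def _gather(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """im2col in GEMM-friendly layout: (N,C,Hp,Wp) -> (C,kh,kw,N,Ho,Wo).

    Filled by kh*kw strided block copies, which beats a transpose-reshape
    of a sliding-window view on CPU.
    """
    n, c = xp.shape[:2]
    col = np.empty((c, kh, kw, n, ho, wo), dtype=np.float32)
    xr = xp.transpose(1, 0, 2, 3)
    for i in range(kh):
        for j in range(kw):
            col[:, i, j] = xr[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return col


def _scatter(col: np.ndarray, xp_shape, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_gather`: scatter-add patches back onto the image."""
    out = np.zeros(xp_shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += col[
                :, i, j
            ].transpose(1, 0, 2, 3)
    return out


def _conv_raw(xd: np.ndarray, wd: np.ndarray, stride: int, padding: int):
    """Plain forward cross-correlation; returns (out, colm) for grad reuse."""
    cout, cin, kh, kw = wd.shape
    n = xd.shape[0]
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    colm = _gather(xp, kh, kw, stride, ho, wo).reshape(cin * kh * kw, -1)
    out = np.ascontiguousarray(
        (wd.reshape(cout, -1) @ colm).reshape(cout, n, ho, wo).transpose(1, 0, 2, 3)
    )
    return out, colm, xp.shape, (ho, wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation; x (N,C,H,W), w (Cout,Cin,kh,kw), zero padding."""
    cout, cin, kh, kw = w.data.shape
    n = x.data.shape[0]
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d expects {cin} input channels, got {x.data.shape[1]}")
    out, colm, xp_shape, (ho, wo) = _conv_raw(x.data, w.data, stride, padding)
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
            w.accumulate((gm @ colm.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride == 1:
                # grad wrt input = correlation with the flipped kernel; this
                # gathers over Cout (small for dense layers) instead of
                # scattering over the wide concatenated input
                wflip = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                dx, _, _, _ = _conv_raw(g, wflip, 1, kh - 1 - padding)
                x.accumulate(dx)
            else:
                gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
                dcol = (w.data.reshape(cout, -1).T @ gm).reshape(cin, kh, kw, n, ho, wo)
                dxp = _scatter(dcol, xp_shape, kh, kw, stride, ho, wo)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x.accumulate(dxp)

    return make_result(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution; x (N,Cin,H,W), w (Cin,Cout,kh,kw).

    Output size is ``(H-1)*stride - 2*padding + kh`` (the usual k=4, s=2,
    p=1 configuration exactly doubles the spatial size).  Implemented as
    the exact adjoint of the strided convolution.
    """
    cin, cout, kh, kw = w.data.shape
    n, _, h, wdt = x.data.shape
    hout = (h - 1) * stride - 2 * padding + kh
    wout = (wdt - 1) * stride - 2 * padding + kw
    xm = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3)).reshape(cin, -1)
    wm = w.data.reshape(cin, -1)
    colT = (wm.T @ xm).reshape(cout, kh, kw, n, h, wdt)
    padded_shape = (n, cout, hout + 2 * padding, wout + 2 * padding)
    out_p = _scatter(colT, padded_shape, kh, kw, stride, h, wdt)
    out = out_p[:, :, padding : padding + hout, padding : padding + wout] if padding else out_p
    out = np.ascontiguousarray(out)
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else g
        gcolm = _gather(gp, kh, kw, stride, h, wdt).reshape(cout * kh * kw, -1)
        if w.requires_grad:
            w.accumulate((xm @ gcolm.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = (wm @ gcolm).reshape(cin, n, h, wdt).transpose(1, 0, 2, 3)
            x.accumulate(np.ascontiguousarray(dx))

    return make_result(out, parents, backward)


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """PReLU with one learnable slope per channel; a has shape (C,)."""
    slope = a.data[None, :, None, None]
    pos = x.data > 0
    out = np.where(pos, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.where(pos, g, slope * g))
        if a.requires_grad:
            a.accumulate(np.sum(g * x.data * ~pos, axis=(0, 2, 3)))

    return make_result(out, (x, a), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * y * (1.0 - y))

    return make_result(y, (x,), backward)


def replicate_pad1(x: Tensor) -> Tensor:
    """Edge-replicate padding by one pixel on both spatial axes."""
    out = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.array(g[:, :, 1:-1, 1:-1], copy=True)
        dx[:, :, 0, :] += g[:, :, 0, 1:-1]
        dx[:, :, -1, :] += g[:, :, -1, 1:-1]
        dx[:, :, :, 0] += g[:, :, 1:-1, 0]
        dx[:, :, :, -1] += g[:, :, 1:-1, -1]
        dx[:, :, 0, 0] += g[:, :, 0, 0]
        dx[:, :, 0, -1] += g[:, :, 0, -1]
        dx[:, :, -1, 0] += g[:, :, -1, 0]
        dx[:, :, -1, -1] += g[:, :, -1, -1]
        x.accumulate(dx)

    return make_result(out, (x,), backward)


_LAPLACIAN_W = Tensor(LAPLACIAN_STENCIL.reshape(1, 1, 3, 3))


def laplacian(x: Tensor) -> Tensor:
    """Discrete 4-neighbour Laplacian with replicate borders (differentiable)."""
    return conv2d(replicate_pad1(x), _LAPLACIAN_W, stride=1, padding=0)


def charbonnier(pred: Tensor, target: Tensor, epsilon: float = 1e-3, reduction: str = "sum") -> Tensor:
    """Charbonnier penalty ``sum sqrt((target - pred)**2 + eps**2)``.

    ``reduction='sum'`` sums over every element; ``'batchmean'`` sums
    per-sample pixel means over the batch (so the loss scale is independent
    of patch size); ``'mean'`` averages over all elements.
    """
    if pred.data.shape != target.data.shape:
        raise ValueError("pred and target shapes must match")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    d = pred.data - target.data
    r = np.sqrt(d * d + np.float32(epsilon) ** 2)
    if reduction == "sum":
        coef = 1.0
    elif reduction == "mean":
        coef = 1.0 / d.size
    elif reduction == "batchmean":
        coef = d.shape[0] / d.size
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    out = np.float32(coef) * r.sum(dtype=np.float64)

    def backward(g):
        grad = (np.float32(coef * g) * d / r).astype(np.float32)
        if pred.requires_grad:
            pred.accumulate(grad)
        if target.requires_grad:
            target.accumulate(-grad)

    return make_result(np.float32(out), (pred, target), backward)
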