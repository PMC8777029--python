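"""Differentiable volumetric operations: convolution, block transposed
convolution, adaptive average pooling and trilinear resampling.

Arrays are laid out channels-first with a batch axis, ``(N, C, D, H, W)``.
Convolution is lowered to a single BLAS matmul through an im2col view;
its input gradient is assembled by looping over the (at most 27) kernel
offsets with strided in-place adds, which keeps everything vectorised.
Pooling and trilinear interpolation are expressed as separable per-axis
linear maps, so one routine serves both and the backward pass is just the
transposed matrices.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _make, astensor


# -- 3D convolution ------------------------------------------------------------

def _im2col(xp: np.ndarray, kshape: tuple[int, int, int], stride: int) -> np.ndarray:
    """(N,C,Dp,Hp,Wp) -> (N*P, C*kd*kh*kw) with P output positions."""
    win = sliding_window_view(xp, kshape, axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    n, c, do, ho, wo = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        n * do * ho * wo, c * kshape[0] * kshape[1] * kshape[2])
    return np.ascontiguousarray(cols), (do, ho, wo)


def _conv_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    """Plain strided cross-correlation; returns output and the im2col matrix."""
    co = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
    cols, (do, ho, wo) = _im2col(xp, w.shape[2:], stride)
    y = cols @ w.reshape(co, -1).T
    y = np.ascontiguousarray(
        y.reshape(x.shape[0], do, ho, wo, co).transpose(0, 4, 1, 2, 3))
    return y, cols


def conv3d(x, weight, bias=None, stride: int = 1, padding: int | None = None) -> Tensor:
    """3D cross-correlation with isotropic stride and zero padding.

    ``weight`` has shape (C_out, C_in, k, k, k); ``padding`` defaults to
    k // 2 ("same" for stride 1).  The input gradient is computed as a
    stride-1 correlation of the (zero-dilated) output gradient with the
    flipped, channel-transposed kernel, so both passes run through the
    same BLAS matmul.
    """
    x, weight = astensor(x), astensor(weight)
    co, ci, kd, kh, kw = weight.shape
    n, c, d, h, w = x.shape
    if c != ci:
        raise ValueError(f"conv3d: input has {c} channels, weight expects {ci}")
    p = kd // 2 if padding is None else padding
    y, cols = _conv_raw(x.data, weight.data, stride, p)
    do, ho, wo = y.shape[2:]

    def backward(g):
        if weight.requires_grad:
            gf = g.transpose(0, 2, 3, 4, 1).reshape(-1, co)
            weight._accumulate((gf.T @ cols).reshape(weight.shape))
        if x.requires_grad:
            w_t = np.ascontiguousarray(
                weight.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
            if stride > 1:
                gd = np.zeros((n, co, (do - 1) * stride + 1,
                               (ho - 1) * stride + 1, (wo - 1) * stride + 1),
                              dtype=g.dtype)
                gd[:, :, ::stride, ::stride, ::stride] = g
            else:
                gd = g
            full, _ = _conv_raw(gd, w_t, 1, kd - 1)
            # trailing rows the strided windows never reached get zero grad
            rem = [(dim + 2 * p - k_) - (o - 1) * stride
                   for dim, k_, o in zip((d, h, w), (kd, kh, kw), (do, ho, wo))]
            if any(rem):
                full = np.pad(full, [(0, 0), (0, 0)] + [(0, r) for r in rem])
            gx = full[:, :, p:p + d, p:p + h, p:p + w]
            x._accumulate(np.ascontiguousarray(gx))

    out = _make(y, (x, weight), backward)
    if bias is not None:
        bias = astensor(bias)
        out = out + bias.reshape(1, co, 1, 1, 1)
    return out


def upconv3d(x, weight, bias=None, factor: int = 2) -> Tensor:
    """Transposed convolution with kernel size equal to its stride.

    Each input voxel expands to a ``factor**3`` block, so output blocks
    never overlap and every spatial dimension is exactly multiplied by
    ``factor``.  ``weight`` has shape (C_in, C_out, f, f, f).
    """
    x, weight = astensor(x), astensor(weight)
    ci, co, f = weight.shape[0], weight.shape[1], factor
    n, c, d, h, w = x.shape
    if c != ci:
        raise ValueError(f"upconv3d: input has {c} channels, weight expects {ci}")
    y6 = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (N,D,H,W,Co,f,f,f)
    y = y6.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, co, d * f, h * f, w * f)
    y = np.ascontiguousarray(y)

    def backward(g):
        g6 = g.reshape(n, co, d, f, h, f, w, f).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        if x.requires_grad:
            gx = np.tensordot(g6, weight.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
            x._accumulate(np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3)))
        if weight.requires_grad:
            gw = np.tensordot(x.data, g6, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            weight._accumulate(gw)

    out = _make(y, (x, weight), backward)
    if bias is not None:
        bias = astensor(bias)
        out = out + bias.reshape(1, co, 1, 1, 1)
    return out


# -- separable per-axis linear maps --------------------------------------------

def _apply_axis(a: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(np.tensordot(m, a, axes=([1], [axis])), 0, axis)


def separable3(x, mats: tuple[np.ndarray, np.ndarray, np.ndarray]) -> Tensor:
    """Apply one linear map per spatial axis: y = (Md ⊗ Mh ⊗ Mw) x."""
    x = astensor(x)
    y = x.data
    for axis, m in zip((2, 3, 4), mats):
        y = _apply_axis(y, m, axis)
    y = np.ascontiguousarray(y)

    def backward(g):
        for axis, m in zip((2, 3, 4), mats):
            g = _apply_axis(g, m.T, axis)
        x._accumulate(np.ascontiguousarray(g))

    return _make(y, (x,), backward)


def avg_pool_matrix(n_in: int, n_out: int, dtype=np.float32) -> np.ndarray:
    """Adaptive average-pooling matrix (floor/ceil binning).

    Bin *i* averages input cells [floor(i·n_in/n_out), ceil((i+1)·n_in/n_out)).
    Well defined for any n_out, including n_out > n_in (bins then replicate
    cells); every row sums to 1, so constants are preserved.
    """
    m = np.zeros((n_out, n_in), dtype=dtype)
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def linear_interp_matrix(n_in: int, n_out: int, dtype=np.float32) -> np.ndarray:
    """1-D linear interpolation matrix with half-pixel-centre alignment."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = np.clip((i + 0.5) * scale - 0.5, 0.0, n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        frac = src - i0
        m[i, i0] += 1.0 - frac
        m[i, i1] += frac
    return m


def adaptive_avg_pool3d(x, out_size: tuple[int, int, int]) -> Tensor:
    x = astensor(x)
    mats = tuple(avg_pool_matrix(x.shape[2 + i], out_size[i], x.dtype)
                 for i in range(3))
    return separable3(x, mats)


def upsample_trilinear3d(x, out_size: tuple[int, int, int]) -> Tensor:
    x = astensor(x)
    mats = tuple(linear_interp_matrix(x.shape[2 + i], out_size[i], x.dtype)
                 for i in range(3))
    return separable3(x, mats)


def instance_norm3d(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel spatial normalisation with affine parameters.

    Fused into one op (forward statistics reused analytically in the
    backward pass) because it sits after every convolution.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * gamma.data + beta.data

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(_t_unbroadcast(g, beta.shape))
        if gamma.requires_grad:
            gamma._accumulate(_t_unbroadcast(g * xhat, gamma.shape))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=axes, keepdims=True)
            m2 = (gh * xhat).mean(axis=axes, keepdims=True)
            x._accumulate((gh - m1 - xhat * m2) * inv)

    return _make(y, (x, gamma, beta), backward)


def _t_unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    from .tensor import _unbroadcast
    return _unbroadcast(g, tuple(shape))


def global_avg_pool3d(x) -> Tensor:
    """(N,C,D,H,W) -> (N,C) spatial mean (the SE 'squeeze')."""
    return astensor(x).mean(axis=(2, 3, 4))


def softmax_channels(x) -> Tensor:
    """Softmax over the channel axis (axis 1), numerically stabilised."""
    x = astensor(x)
    shift = x - Tensor(x.data.max(axis=1, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=1, keepdims=True)
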