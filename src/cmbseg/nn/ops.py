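"""Low-level array operations: 2-D cross-correlation ("conv") and bilinear
upsampling, each with an explicit backward pass.

Conventions
-----------
* activations: ``(B, C, H, W)`` float32
* weights: ``(C_out, C_in, k, k)`` with odd ``k``; "same" padding ``k // 2``
  for stride 1, so spatial dims are preserved; stride-2 convolutions halve
  even spatial dims exactly.
* ``conv2d`` computes cross-correlation (the deep-learning convention).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft

# FFT path for every stride-1 kernel of size >= 3: its cost is independent
# of kernel size and it avoids the large im2col buffer copies.
_FFT_MIN_KERNEL = 3


def _fft_sizes(H: int, W: int, k: int) -> tuple[int, int]:
    return sfft.next_fast_len(H + k - 1), sfft.next_fast_len(W + k - 1)


def _mix(Af: np.ndarray, Bf: np.ndarray) -> np.ndarray:
    """Per-frequency channel mixing: (.., P, Q, nh, fw) pairs contracted as
    (F, B, P) @ (F, P, Q) batched matrix products."""
    nh, fw = Af.shape[2], Af.shape[3]
    Am = Af.transpose(2, 3, 0, 1).reshape(nh * fw, Af.shape[0], Af.shape[1])
    Bm = Bf.transpose(2, 3, 0, 1).reshape(nh * fw, Bf.shape[0], Bf.shape[1])
    return (Am @ Bm).reshape(nh, fw, Af.shape[0], Bf.shape[1]).transpose(2, 3, 0, 1)


def _conv_fft_forward(x: np.ndarray, w: np.ndarray):
    """Stride-1 'same' cross-correlation via frequency-domain channel mixing.

    Returns (y, cache); the cached input/kernel spectra are reused by
    :func:`_conv_fft_backward`, saving a third of the transforms.
    """
    B, C, H, W = x.shape
    Co, _, k, _ = w.shape
    p = k // 2
    nh, nw = _fft_sizes(H, W, k)
    Xf = sfft.rfft2(x, s=(nh, nw))                       # (B, C, nh, fw)
    Wf = sfft.rfft2(w[:, :, ::-1, ::-1], s=(nh, nw))     # flip -> correlation
    Yf = _mix(Xf, Wf.transpose(1, 0, 2, 3))
    y = sfft.irfft2(Yf, s=(nh, nw))
    out = np.ascontiguousarray(y[:, :, p : p + H, p : p + W]).astype(np.float32)
    return out, (Xf, Wf, (H, W, k, nh, nw))


def _conv_fft_backward(dy: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray]:
    """(dx, dw) for the FFT convolution, reusing the forward spectra.

    dx is the adjoint of crop∘(circular conv): embed dy at the crop offset
    (a phase twist on its spectrum) and convolve with the conjugate kernel
    spectrum.  dw is a circular correlation of the zero-padded input with
    dy; the lags (i − p) are wrap-free since the FFT length covers H+k−1.
    """
    Xf, Wf, (H, W, k, nh, nw) = cache
    p = k // 2
    Gf = sfft.rfft2(dy, s=(nh, nw))                      # (B, Co, nh, fw)
    fw = nw // 2 + 1
    # dx = irfft( (Gf·phase) @ conj(Wf) )[:H, :W]
    ph_h = np.exp(-2j * np.pi * p * np.arange(nh) / nh)
    ph_w = np.exp(-2j * np.pi * p * np.arange(fw) / nw)
    Df = Gf * (ph_h[:, None] * ph_w[None, :]).astype(Gf.dtype)
    Xb = _mix(Df, np.conj(Wf))
    dx = sfft.irfft2(Xb, s=(nh, nw))[:, :, :H, :W]
    # dw: contract over batch in the frequency domain
    Cf = _mix(Xf.transpose(1, 0, 2, 3), np.conj(Gf))
    corr = sfft.irfft2(Cf, s=(nh, nw))                   # (C, Co, nh, nw)
    iz = (np.arange(k) - p) % nh
    jz = (np.arange(k) - p) % nw
    dw = corr[:, :, iz][:, :, :, jz].transpose(1, 0, 2, 3)
    return (
        np.ascontiguousarray(dx).astype(np.float32),
        np.ascontiguousarray(dw).astype(np.float32),
    )


def _conv_im2col(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    B, C, H, W = x.shape
    Co, _, k, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    col = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    y = np.tensordot(col, w, axes=([1, 4, 5], [1, 2, 3]))  # (B, Ho, Wo, Co)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)).astype(np.float32)


def conv2d(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None = None,
    stride: int = 1,
    cache_out: dict | None = None,
) -> np.ndarray:
    """'Same'-padded cross-correlation; output is (B, Co, H//stride, W//stride).

    With ``cache_out`` supplied, forward FFT state is stored there and reused
    by :func:`conv2d_backward`.
    """
    k = w.shape[2]
    if stride == 1 and k >= _FFT_MIN_KERNEL:
        y, fft_cache = _conv_fft_forward(x, w)
        if cache_out is not None:
            cache_out["fft"] = fft_cache
    else:
        y = _conv_im2col(x, w, stride)
    if b is not None:
        y += b[None, :, None, None]
    return y


def conv2d_backward(
    x: np.ndarray,
    w: np.ndarray,
    dy: np.ndarray,
    stride: int = 1,
    cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of :func:`conv2d`."""
    B, C, H, W = x.shape
    Co, _, k, _ = w.shape
    p = k // 2
    dy = np.ascontiguousarray(dy, dtype=np.float32)
    db = dy.sum(axis=(0, 2, 3)).astype(np.float32)

    if stride == 1 and k >= _FFT_MIN_KERNEL:
        fft_cache = cache.get("fft") if cache else None
        if fft_cache is None:
            _, fft_cache = _conv_fft_forward(x, w)
        dx, dw = _conv_fft_backward(dy, fft_cache)
        return dx, dw, db

    # direct path (covers stride > 1 and small kernels)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    Ho, Wo = dy.shape[2], dy.shape[3]
    col = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # col: (B, C, Ho, Wo, k, k)
    dw = np.tensordot(dy, col, axes=([0, 2, 3], [0, 2, 3])).astype(np.float32)
    M = np.tensordot(dy, w, axes=([1], [0]))             # (B, Ho, Wo, C, k, k)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                M[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    dx = dxp[:, :, p : p + H, p : p + W] if p else dxp
    return np.ascontiguousarray(dx).astype(np.float32), dw, db


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n × n) bilinear factor-2 interpolation matrix (half-pixel centers,
    edges clamped) — the align_corners=False convention."""
    A = np.zeros((2 * n, n), dtype=np.float32)
    for o in range(2 * n):
        src = (o + 0.5) / 2.0 - 0.5
        f = int(np.floor(src))
        t = src - f
        f0 = min(max(f, 0), n - 1)
        f1 = min(max(f + 1, 0), n - 1)
        A[o, f0] += 1.0 - t
        A[o, f1] += t
    return A


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_mat(n: int) -> np.ndarray:
    if n not in _UP_CACHE:
        _UP_CACHE[n] = _upsample_matrix(n)
    return _UP_CACHE[n]


def upsample2(x: np.ndarray) -> np.ndarray:
    """Bilinear ×2 upsampling of (B, C, H, W) -> (B, C, 2H, 2W)."""
    H, W = x.shape[2], x.shape[3]
    Ah, Aw = _up_mat(H), _up_mat(W)
    return np.matmul(np.matmul(Ah, x), Aw.T).astype(np.float32)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    H2, W2 = dy.shape[2], dy.shape[3]
    Ah, Aw = _up_mat(H2 // 2), _up_mat(W2 // 2)
    return np.matmul(np.matmul(Ah.T, dy), Aw).astype(np.float32)


def maxpool2_target(t: np.ndarray, times: int) -> np.ndarray:
    """Downsample a binary target by repeated 2×2 max-pooling.

    Max (rather than average) pooling keeps even single-pixel lesions present
    at every auxiliary supervision scale.
    """
    out = np.asarray(t)
    for _ in range(times):
        H, W = out.shape[-2], out.shape[-1]
        out = out.reshape(*out.shape[:-2], H // 2, 2, W // 2, 2).max(axis=(-3, -1))
    return out
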