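"""Numba-accelerated inner loops for the NumPy network engine.

Depthwise 3x3 convolutions and batch-norm passes are memory-bandwidth
bound when expressed as whole-array NumPy expressions (every kernel tap
re-reads the full activation tensor).  The fused loops here make a
single pass over the data with SIMD over the contiguous channel axis.
A pure-NumPy fallback is kept in ``nn`` for environments without numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard runtime dep in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=True, fastmath=True)
def dw_conv_fwd(xp, w, stride, out):
    """out[b,ho,wo,c] = sum_ij xp[b, ho*s+i, wo*s+j, c] * w[i,j,c]."""
    B, Hp, Wp, C = xp.shape
    Ho, Wo = out.shape[1], out.shape[2]
    k = w.shape[0]
    for b in range(B):
        for ho in range(Ho):
            hi = ho * stride
            for wo in range(Wo):
                wi = wo * stride
                for c in range(C):
                    out[b, ho, wo, c] = 0.0
                for i in range(k):
                    for j in range(k):
                        for c in range(C):
                            out[b, ho, wo, c] += xp[b, hi + i, wi + j, c] * w[i, j, c]


@njit(cache=True, fastmath=True)
def dw_conv_bwd(xp, w, grad, stride, dxp, dw):
    """Accumulate input and weight gradients of the depthwise conv."""
    B, Hp, Wp, C = xp.shape
    Ho, Wo = grad.shape[1], grad.shape[2]
    k = w.shape[0]
    for b in range(B):
        for ho in range(Ho):
            hi = ho * stride
            for wo in range(Wo):
                wi = wo * stride
                for i in range(k):
                    for j in range(k):
                        for c in range(C):
                            g = grad[b, ho, wo, c]
                            dw[i, j, c] += xp[b, hi + i, wi + j, c] * g
                            dxp[b, hi + i, wi + j, c] += w[i, j, c] * g


@njit(cache=True, fastmath=True)
def conv3x3_fwd(xp, w, stride, out):
    """Standard 3x3 convolution; w has shape (3, 3, Cin, Cout)."""
    B, Hp, Wp, Cin = xp.shape
    Ho, Wo, Cout = out.shape[1], out.shape[2], out.shape[3]
    for b in range(B):
        for ho in range(Ho):
            hi = ho * stride
            for wo in range(Wo):
                wi = wo * stride
                for o in range(Cout):
                    out[b, ho, wo, o] = 0.0
                for i in range(3):
                    for j in range(3):
                        for c in range(Cin):
                            xv = xp[b, hi + i, wi + j, c]
                            for o in range(Cout):
                                out[b, ho, wo, o] += xv * w[i, j, c, o]


@njit(cache=True, fastmath=True)
def conv3x3_wgrad(xp, grad, stride, dw):
    """Weight gradient of the standard 3x3 convolution."""
    B, Hp, Wp, Cin = xp.shape
    Ho, Wo, Cout = grad.shape[1], grad.shape[2], grad.shape[3]
    for b in range(B):
        for ho in range(Ho):
            hi = ho * stride
            for wo in range(Wo):
                wi = wo * stride
                for i in range(3):
                    for j in range(3):
                        for c in range(Cin):
                            xv = xp[b, hi + i, wi + j, c]
                            for o in range(Cout):
                                dw[i, j, c, o] += xv * grad[b, ho, wo, o]


@njit(cache=True, fastmath=True)
def dw_weight_grad(xp, grad, stride, dw):
    """dw[i,j,c] += sum_bhw xp[b, h*s+i, w*s+j, c] * grad[b,h,w,c]."""
    B, Hp, Wp, C = xp.shape
    Ho, Wo = grad.shape[1], grad.shape[2]
    k = dw.shape[0]
    for b in range(B):
        for ho in range(Ho):
            hi = ho * stride
            for wo in range(Wo):
                wi = wo * stride
                for i in range(k):
                    for j in range(k):
                        for c in range(C):
                            dw[i, j, c] += xp[b, hi + i, wi + j, c] * grad[b, ho, wo, c]


@njit(cache=True, fastmath=True)
def bn_stats(x2):
    """Per-channel sum and sum of squares of a (N, C) view."""
    N, C = x2.shape
    s = np.zeros(C, dtype=np.float64)
    ss = np.zeros(C, dtype=np.float64)
    for n in range(N):
        for c in range(C):
            v = x2[n, c]
            s[c] += v
            ss[c] += v * v
    return s, ss


@njit(cache=True, fastmath=True)
def bn_relu_fwd(x2, mean, invstd, gamma, beta, out2):
    """out = relu(gamma * (x - mean) * invstd + beta), one pass."""
    N, C = x2.shape
    scale = gamma * invstd
    shift = beta - mean * scale
    for n in range(N):
        for c in range(C):
            a = x2[n, c] * scale[c] + shift[c]
            out2[n, c] = a if a > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def bn_relu_bwd(x2, grad2, mean, invstd, gamma, beta, dx2):
    """Gradient of relu(batchnorm(x)) using training-batch statistics.

    The ReLU mask and normalized activation are recomputed from the
    cached layer input, so no forward-pass tensors besides ``x2`` are
    needed.  ``dx2`` may alias ``grad2``.  Returns (dbeta, dgamma).
    """
    N, C = x2.shape
    scale = gamma * invstd
    shift = beta - mean * scale
    dbeta = np.zeros(C, dtype=np.float32)
    dgamma = np.zeros(C, dtype=np.float32)
    for n in range(N):
        for c in range(C):
            xc = x2[n, c]
            m = np.float32(xc * scale[c] + shift[c] > 0.0)
            g = grad2[n, c] * m
            dbeta[c] += g
            dgamma[c] += g * ((xc - mean[c]) * invstd[c])
    db_n = dbeta / N
    dg_n = dgamma / N
    for n in range(N):
        for c in range(C):
            xc = x2[n, c]
            m = np.float32(xc * scale[c] + shift[c] > 0.0)
            g = grad2[n, c] * m
            xh = (xc - mean[c]) * invstd[c]
            dx2[n, c] = scale[c] * (g - db_n[c] - xh * dg_n[c])
    return dbeta, dgamma
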