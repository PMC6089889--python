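"""Minimal NumPy neural-network engine used by the patch classifier.

Implements exactly the layers needed for a depthwise-separable
convolutional classifier (NHWC layout, float32 throughout): standard and
depthwise 2-D convolutions, batch normalization, ReLU, dropout, global
average pooling and a dense softmax head, together with reverse-mode
gradients and the two optimizers used for training (Adam for training
from scratch, Nesterov SGD for fine-tuning).

Convolutions are evaluated as a sum over the k*k kernel offsets of
strided-slice matmuls (standard conv) or broadcast multiplies (depthwise
conv), which keeps memory traffic low and lets BLAS do the heavy lifting
on a single CPU core.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "BatchNormReLU",
    "ReLU",
    "Dropout",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "NesterovSGD",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[Param]:
        return []


def _pad_amount(k: int, padding: str) -> int:
    if padding == "same":
        return k // 2
    if padding == "valid":
        return 0
    raise ValueError(f"unknown padding mode {padding!r}")


class Conv2d(Layer):
    """k x k convolution, NHWC, symmetric zero padding ('same') or 'valid'."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, stride: int = 1,
                 padding: str = "same", rng: np.random.Generator | None = None,
                 name: str = "conv", input_grad: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.padding = ksize, stride, padding
        self.input_grad = input_grad
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ksize, ksize, in_ch, out_ch))
        self.weight = Param(w, f"{name}.weight")
        self._cache = None

    @property
    def params(self):
        return [self.weight]

    def forward(self, x, train=False):
        k, s = self.k, self.stride
        if k == 1 and s == 1:
            B, H, W, C = x.shape
            x = np.ascontiguousarray(x)
            out = x.reshape(-1, C) @ self.weight.value[0, 0]
            self._cache = (x, x.shape, H, W)
            return out.reshape(B, H, W, self.out_ch)
        p = _pad_amount(k, self.padding)
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        else:
            xp = x
        B, Hp, Wp, C = xp.shape
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        W = self.weight.value
        if k == 3 and _kernels.HAVE_NUMBA:
            xp = np.ascontiguousarray(xp)
            out = np.empty((B, Ho, Wo, self.out_ch), dtype=np.float32)
            _kernels.conv3x3_fwd(xp, W, s, out)
            self._cache = (xp, x.shape, Ho, Wo)
            return out
        out = np.zeros((B * Ho * Wo, self.out_ch), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :]
                out += xs.reshape(-1, C) @ W[i, j]
        self._cache = (xp, x.shape, Ho, Wo)
        return out.reshape(B, Ho, Wo, self.out_ch)

    def backward(self, grad):
        xp, xshape, Ho, Wo = self._cache
        k, s = self.k, self.stride
        if k == 1 and s == 1:
            C = xp.shape[-1]
            g2 = np.ascontiguousarray(grad).reshape(-1, self.out_ch)
            self.weight.grad[0, 0] += xp.reshape(-1, C).T @ g2
            return (g2 @ self.weight.value[0, 0].T).reshape(xp.shape)
        p = _pad_amount(k, self.padding)
        B, Hp, Wp, C = xp.shape
        if k == 3 and _kernels.HAVE_NUMBA and not self.input_grad:
            _kernels.conv3x3_wgrad(xp, np.ascontiguousarray(grad), s,
                                   self.weight.grad)
            return None
        g2 = grad.reshape(-1, self.out_ch)
        W = self.weight.value
        dxp = np.zeros_like(xp) if self.input_grad else None
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :]
                self.weight.grad[i, j] += xs.reshape(-1, C).T @ g2
                if self.input_grad:
                    dxp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] += (
                        g2 @ W[i, j].T).reshape(B, Ho, Wo, C)
        if not self.input_grad:
            return None
        if p:
            return dxp[:, p:Hp - p, p:Wp - p, :]
        return dxp


class DepthwiseConv2d(Layer):
    """Per-channel k x k convolution (the 'depthwise' half of a block)."""

    def __init__(self, channels: int, ksize: int = 3, stride: int = 1,
                 padding: str = "same", rng: np.random.Generator | None = None,
                 name: str = "dwconv"):
        self.channels = channels
        self.k, self.stride, self.padding = ksize, stride, padding
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ksize, ksize, channels))
        self.weight = Param(w, f"{name}.weight")
        self._cache = None

    @property
    def params(self):
        return [self.weight]

    def forward(self, x, train=False):
        k, s = self.k, self.stride
        p = _pad_amount(k, self.padding)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else np.ascontiguousarray(x)
        B, Hp, Wp, C = xp.shape
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        W = self.weight.value
        out = np.empty((B, Ho, Wo, C), dtype=np.float32)
        if _kernels.HAVE_NUMBA:
            _kernels.dw_conv_fwd(xp, W, s, out)
        else:
            out[...] = 0.0
            for i in range(k):
                for j in range(k):
                    out += xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] * W[i, j]
        self._cache = (xp, Ho, Wo)
        return out

    def backward(self, grad):
        xp, Ho, Wo = self._cache
        k, s = self.k, self.stride
        p = _pad_amount(k, self.padding)
        B, Hp, Wp, C = xp.shape
        W = self.weight.value
        if _kernels.HAVE_NUMBA and s == 1 and p == 1:
            # stride-1 same-padding: dx is the correlation of the padded
            # upstream gradient with the flipped kernel (gather form,
            # no scatter write conflicts)
            grad = np.ascontiguousarray(grad)
            _kernels.dw_weight_grad(xp, grad, s, self.weight.grad)
            gp = np.pad(grad, ((0, 0), (1, 1), (1, 1), (0, 0)))
            wflip = np.ascontiguousarray(W[::-1, ::-1])
            dx = np.empty((B, Hp - 2 * p, Wp - 2 * p, C), dtype=np.float32)
            _kernels.dw_conv_fwd(gp, wflip, 1, dx)
            return dx
        dxp = np.zeros_like(xp)
        if _kernels.HAVE_NUMBA:
            _kernels.dw_conv_bwd(xp, W, np.ascontiguousarray(grad), s,
                                 dxp, self.weight.grad)
        else:
            for i in range(k):
                for j in range(k):
                    xs = xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :]
                    self.weight.grad[i, j] += np.einsum("bhwc,bhwc->c", xs, grad)
                    dxp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] += grad * W[i, j]
        if p:
            return dxp[:, p:Hp - p, p:Wp - p, :]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            axes = (0, 1, 2)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd) if train else None
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, grad):
        xhat, invstd = self._cache
        axes = (0, 1, 2)
        n = grad.shape[0] * grad.shape[1] * grad.shape[2]
        dgamma = np.einsum("bhwc,bhwc->c", grad, xhat)
        dbeta = grad.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value * invstd
        dx = g * (grad - dbeta / n - xhat * (dgamma / n))
        return dx.astype(np.float32)


class BatchNormReLU(Layer):
    """Fused batch normalization + ReLU (single-pass numba fast path).

    Numerically equivalent to ``BatchNorm2d`` followed by ``ReLU``; the
    fusion exists because both layers are memory-bound.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        C = x.shape[-1]
        x2 = x.reshape(-1, C)
        if train:
            if _kernels.HAVE_NUMBA:
                s, ss = _kernels.bn_stats(x2)
                n = x2.shape[0]
                mean = (s / n).astype(np.float32)
                var = np.maximum(ss / n - (s / n) ** 2, 0.0).astype(np.float32)
            else:
                mean = x2.mean(axis=0)
                var = x2.var(axis=0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        out = np.empty_like(x)
        if _kernels.HAVE_NUMBA:
            _kernels.bn_relu_fwd(x2, mean, invstd, self.gamma.value,
                                 self.beta.value, out.reshape(-1, C))
        else:
            a = self.gamma.value * invstd
            b = self.beta.value - mean * a
            np.maximum(x * a + b, 0.0, out=out)
        if train:
            self._cache = (x, mean, invstd)
        return out

    def backward(self, grad):
        x, mean, invstd = self._cache
        C = x.shape[-1]
        x2 = x.reshape(-1, C)
        n = x2.shape[0]
        if _kernels.HAVE_NUMBA:
            grad = np.ascontiguousarray(grad, dtype=np.float32)
            g2 = grad.reshape(-1, C)
            dbeta, dgamma = _kernels.bn_relu_bwd(
                x2, g2, mean, invstd, self.gamma.value, self.beta.value, g2)
            dx = grad
        else:
            xhat = (x2 - mean) * invstd
            pre = self.gamma.value * xhat + self.beta.value
            g = grad.reshape(-1, C) * (pre > 0)
            dbeta = g.sum(axis=0)
            dgamma = np.einsum("nc,nc->c", g, xhat)
            dx = (self.gamma.value * invstd
                  * (g - dbeta / n - xhat * (dgamma / n))
                  ).astype(np.float32).reshape(x.shape)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        self._mask = out > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        B, H, W, C = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (H * W),
                               self._shape).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_dim, dtype=np.float32), f"{name}.bias")
        self._cache = None

    @property
    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._cache = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        x = self._cache
        self.weight.grad += x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    labels are integer class indices of shape (B,).
    """
    probs = softmax(logits)
    B = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(B), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(B), labels] -= 1.0
    grad /= B
    return float(loss), grad.astype(np.float32), probs


class Sequential:
    """A plain layer stack with joint forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:  # first layer may skip its input gradient
                break
        return grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                state[f"{i}.{p.name}"] = p.value
            if isinstance(layer, (BatchNorm2d, BatchNormReLU)):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                p.value[...] = state[f"{i}.{p.name}"]
            if isinstance(layer, (BatchNorm2d, BatchNormReLU)):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class NesterovSGD:
    def __init__(self, params: list[Param], lr: float = 1e-4, momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        mu = self.momentum
        for p, v in zip(self.params, self.vel):
            v *= mu
            v -= self.lr * p.grad
            p.value += mu * v - self.lr * p.grad
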