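"""Neural layers for 1-D biosignal models, built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, softmax


class Module:
    """Base class with recursive parameter discovery (insertion-ordered)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def set_training(self, flag: bool):
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus buffers, in deterministic order."""
        arrays = [p.data for p in self.parameters()]
        arrays.extend(self._buffers())
        return arrays

    def _buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    bufs.extend(item._buffers())
        if isinstance(getattr(self, "running_mean", None), np.ndarray):
            bufs.append(self.running_mean)
            bufs.append(self.running_var)
        return bufs

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError(
                f"state mismatch: expected {len(targets)} arrays, got {len(arrays)}"
            )
        for tgt, src in zip(targets, arrays):
            if tgt.shape != src.shape:
                raise ValueError(f"shape mismatch {tgt.shape} vs {src.shape}")
            tgt[...] = src


def _param(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    scale = np.sqrt(1.0 / max(fan_in, 1))
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(dtype), requires_grad=True)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator, dtype=np.float32):
        self.stride = stride
        # default: SAME padding for stride 1, half-kernel for strided convs
        self.padding = kernel // 2 if padding is None else padding
        self.weight = _param(rng, (out_ch, in_ch, kernel), in_ch * kernel, dtype)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator, dtype=np.float32):
        self.weight = _param(rng, (in_f, out_f), in_f, dtype)
        self.bias = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class GroupNorm(Module):
    """Group normalization over [N, C, T] inputs."""

    def __init__(self, groups: int, channels: int, *, eps: float = 1e-5, dtype=np.float32):
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by {groups} groups")
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1), dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        N, C, T = x.shape
        g = self.groups
        xg = x.reshape(N, g, C // g, T)
        mu = xg.mean(axis=(2, 3), keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn.reshape(N, C, T) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalization over [N, C, T]; tracks running statistics."""

    def __init__(self, channels: int, *, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self.gamma = Tensor(np.ones((1, channels, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1), dtype=dtype)
        self.running_var = np.ones((1, channels, 1), dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data
            self.running_var[...] = (1 - m) * self.running_var + m * var.data
            xn = xc / (var + self.eps).sqrt()
        else:
            xn = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return xn * self.gamma + self.beta


class SelfAttention1d(Module):
    """Multi-head self-attention over the time axis of [N, C, T] features."""

    def __init__(self, channels: int, heads: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by {heads} heads")
        self.heads = heads
        self.qkv = Conv1d(channels, 3 * channels, 1, rng=rng, dtype=dtype)
        self.proj = Conv1d(channels, channels, 1, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        N, C, T = x.shape
        h = self.heads
        d = C // h
        qkv = self.qkv(x)  # [N, 3C, T]
        qkv = qkv.reshape(N, 3, h, d, T).transpose(1, 0, 2, 4, 3)  # [3, N, h, T, d]
        # split via constant-index views on data is not differentiable; use
        # reshape trick: build three tensors by slicing through matmul-free ops
        q = _take_first_axis(qkv, 0)
        k = _take_first_axis(qkv, 1)
        v = _take_first_axis(qkv, 2)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = softmax(scores, axis=-1)
        out = attn @ v  # [N, h, T, d]
        out = out.transpose(0, 1, 3, 2).reshape(N, C, T)
        return self.proj(out)


def _take_first_axis(t: Tensor, idx: int) -> Tensor:
    def bwd(g):
        full = np.zeros_like(t.data)
        full[idx] = g
        t._accum(full)

    return Tensor._make(t.data[idx], (t,), bwd)


class SqueezeExcite(Module):
    """Channel-gating block: global pooling, bottleneck MLP, sigmoid gates."""

    def __init__(self, channels: int, reduction: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=2)  # [N, C]
        gate = self.fc2(self.fc1(pooled).silu()).sigmoid()  # [N, C]
        N, C = gate.shape
        return x * gate.reshape(N, C, 1)
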