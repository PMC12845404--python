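"""Neural-network layers, optimizers and schedulers on the autodiff engine.

Conventions: sequence tensors are ``[batch, time, channels]``; image tensors
are ``[batch, channels, height, width]``.  Every layer draws its
initialization from an explicit ``numpy.random.Generator`` so whole models
are bit-reproducible from a single seed.
"""

from __future__ import annotations

import copy

import numpy as np

from .autodiff import Tensor, concat, embedding

EPS = 1e-5  # global epsilon floor wherever a division/std occurs


def seeded_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) % (2 ** 31))


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out, seen = [], set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return out

    def modules(self) -> list["Module"]:
        out = []

        def walk(obj):
            if isinstance(obj, Module):
                out.append(obj)
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]):
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Embedding(Module):
    """Learned code embedding.  Zero-initialized so that a code never seen in
    training (e.g. the held-out test year) contributes a neutral vector."""

    def __init__(self, n_codes: int, dim: int):
        super().__init__()
        self.weight = Tensor(np.zeros((n_codes, dim)), requires_grad=True)

    def forward(self, idx) -> Tensor:
        return embedding(self.weight, idx)


class Conv1d(Module):
    """1-D convolution over [B, T, C]; causal left-padding or same-padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng,
                 dilation: int = 1, causal: bool = False, bias: bool = True,
                 pad_mode: str = "constant"):
        super().__init__()
        self.kernel, self.dilation, self.causal = kernel, dilation, causal
        self.pad_mode = pad_mode
        self.weight = Tensor(_kaiming(rng, c_in * kernel, (kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        span = (self.kernel - 1) * self.dilation
        if self.causal:
            left, right = span, 0
        else:
            left = span // 2
            right = span - left
        xp = x.pad(((0, 0), (left, right), (0, 0)), mode=self.pad_mode)
        out = None
        for k in range(self.kernel):
            sl = xp[:, k * self.dilation:k * self.dilation + T, :] @ self.weight[k]
            out = sl if out is None else out + sl
        return out + self.bias if self.bias is not None else out


class Conv2d(Module):
    """Same-padded 2-D convolution over [B, C, H, W] (odd kernels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng,
                 stride: int = 1, bias: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernels only")
        self.kernel, self.stride = kernel, stride
        self.weight = Tensor(_kaiming(rng, c_in * kernel * kernel,
                                      (kernel, kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        p = (self.kernel - 1) // 2
        xp = x.pad(((0, 0), (0, 0), (p, p), (p, p)))
        xp = xp.transpose(0, 2, 3, 1)  # [B, H+2p, W+2p, C]
        s = self.stride
        ho = (h - 1) // s + 1
        wo = (w - 1) // s + 1
        out = None
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                sl = xp[:, ki:ki + h:s, kj:kj + w:s, :] @ self.weight[ki][kj]
                out = sl if out is None else out + sl
        if self.bias is not None:
            out = out + self.bias
        return out.transpose(0, 3, 1, 2)


class DepthwiseConv2d(Module):
    """Per-channel (depthwise) same-padded 2-D convolution."""

    def __init__(self, channels: int, kernel: int, rng, bias: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernels only")
        self.kernel = kernel
        self.weight = Tensor(_kaiming(rng, kernel * kernel,
                                      (kernel, kernel, channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        p = (self.kernel - 1) // 2
        xp = x.pad(((0, 0), (0, 0), (p, p), (p, p))).transpose(0, 2, 3, 1)
        out = None
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                sl = xp[:, ki:ki + h, kj:kj + w, :] * self.weight[ki][kj]
                out = sl if out is None else out + sl
        if self.bias is not None:
            out = out + self.bias
        return out.transpose(0, 3, 1, 2)


class BatchNorm2d(Module):
    """Batch norm over [B, C, H, W]: batch statistics while training,
    running statistics in eval (eval mode is exactly deterministic)."""

    def __init__(self, channels: int, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / (var + EPS ** 2).sqrt()
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Dropout(Module):
    def __init__(self, p: float, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adaptive-moment optimizer (the protocol's choice for the yield task)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5,
                 patience: int = 5, min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, loss: float):
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return ((pred - Tensor(target)) ** 2).mean()


def clone_state(state: list[np.ndarray]) -> list[np.ndarray]:
    return copy.deepcopy(state)
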