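"""Neural-network building blocks on top of the autodiff engine.

Follows the familiar Module/Parameter idiom: modules discover their
parameters and submodules by attribute, expose ``state_dict`` /
``load_state_dict`` for checkpointing, and switch between training and
evaluation behaviour (batch-norm statistics) with ``train()`` / ``eval()``.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, conv2d

__all__ = ["Parameter", "Module", "ModuleList", "Conv2d", "BatchNorm2d",
           "Linear", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{key}.")

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data for k, p in self.named_parameters()}
        state.update({k: v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self._named_buffer_owners())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32)
        for k, (owner, attr) in bufs.items():
            setattr(owner, attr, state[k].astype(np.float32))

    def _named_buffer_owners(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield key, (self, name)
            elif isinstance(value, Module):
                yield from value._named_buffer_owners(f"{key}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._items)), m)
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class Conv2d(Module):
    """2-D convolution; ``padding='same'`` keeps spatial size at stride 1."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding="same", dilation=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        if padding == "same":
            padding = dilation * (k // 2)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels * k * k
        std = math.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"Conv2d expected {self.in_channels} channels, "
                             f"got {x.shape[1]}")
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with batch statistics and updates the running
    mean/variance; evaluation mode uses the running statistics, making the
    forward pass a deterministic affine map.
    """

    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import batchnorm2d
        if self.training:
            C = x.shape[1]
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var * (n / max(n - 1, 1))
                                ).astype(np.float32)
            return batchnorm2d(x, self.gamma, self.beta, eps=self.eps)
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Adam:
    """Adam optimizer with optional per-step learning-rate override."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
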