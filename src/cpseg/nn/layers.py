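"""Layers for the segmentation networks: convolution, batch norm, residual blocks."""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, avg_pool2, concat, conv2d, upsample2


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    @staticmethod
    def _walk(value):
        """Yield Tensors and Modules reachable through attributes and nested lists."""
        if isinstance(value, (Tensor, Module)):
            yield value
        elif isinstance(value, (list, tuple)):
            for item in value:
                yield from Module._walk(item)

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            for obj in Module._walk(v):
                if isinstance(obj, Tensor) and obj.requires_grad:
                    params.append(obj)
                elif isinstance(obj, Module):
                    params.extend(obj.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in vars(self).values():
            for obj in Module._walk(v):
                if isinstance(obj, Module):
                    mods.extend(obj.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data.copy()
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"bn_{j}_mean"] = m.running_mean.copy()
                state[f"bn_{j}_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.parameters()):
            p.data = state[f"param_{i}"].astype(DTYPE).reshape(p.shape)
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"bn_{j}_mean"].astype(DTYPE)
                m.running_var = state[f"bn_{j}_var"].astype(DTYPE)


class Conv2d(Module):
    """Same-padding stride-1 convolution with He-normal initialization."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        self.training = True
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.training = True
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ResBlock(Module):
    """conv3-bn-relu-conv3-bn plus (projected) identity, then relu."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.training = True
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)
        self.proj = Conv2d(cin, cout, 1, rng, bias=False) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        shortcut = self.proj(x) if self.proj is not None else x
        return (h + shortcut).relu()


__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "ResBlock",
    "avg_pool2", "upsample2", "concat",
]
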