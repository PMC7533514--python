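"""Layer modules and optimizers over the autodiff core.

Weights use He-normal initialization from an explicit
``numpy.random.Generator`` — no global random state.  Biases and
batch-norm shifts start at zero, batch-norm scales at one.
"""

from __future__ import annotations

import numpy as np

from . import core
from .core import Parameter, Tensor

__all__ = [
    "Module", "Conv2d", "ConvTranspose2x", "BatchNorm2d", "ReLU",
    "MaxPool2x", "Linear", "Flatten", "Sequential", "SGD", "RMSProp",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.mean"] = m.running["mean"].copy()
                state[f"__bn{i}.var"] = m.running["var"].copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].astype(p.data.dtype).copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running["mean"] = state[f"__bn{i}.mean"].copy()
                m.running["var"] = state[f"__bn{i}.var"].copy()

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


def _he(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng, stride: int = 1,
                 pad: int | None = None, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.w = Parameter(_he(rng, (cout, cin, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2x(Module):
    def __init__(self, cin: int, cout: int, rng, bias: bool = True):
        super().__init__()
        self.w = Parameter(_he(rng, (cin, cout, 2, 2), cin))
        self.b = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.conv_transpose2x(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.momentum = momentum
        self.running = {"mean": np.zeros(c, dtype=np.float32),
                        "var": np.ones(c, dtype=np.float32)}

    def forward(self, x: Tensor) -> Tensor:
        return core.batchnorm2d(x, self.gamma, self.beta, self.running,
                                self.training, momentum=self.momentum)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return core.relu(x)


class MaxPool2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return core.maxpool2x(x)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng, bias: bool = True):
        super().__init__()
        self.w = Parameter(_he(rng, (din, dout), din))
        self.b = Parameter(np.zeros(dout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.linear(x, self.w, self.b)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return core.flatten(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# optimizers


class SGD:
    """SGD with momentum and decoupled-from-nothing weight decay (classic
    L2: the decay term is added to the gradient)."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class RMSProp:
    def __init__(self, params, lr: float = 1e-3, rho: float = 0.9,
                 momentum: float = 0.9, eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.rho = rho
        self.momentum = momentum
        self.eps = eps
        self.sq = [np.zeros_like(p.data) for p in self.params]
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s, v in zip(self.params, self.sq, self.buf):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1.0 - self.rho) * p.grad * p.grad
            upd = self.lr * p.grad / (np.sqrt(s) + self.eps)
            v *= self.momentum
            v += upd
            p.data -= v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
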