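"""Neural-network building blocks on top of :mod:`ctcdet.autodiff`.

Modules register parameters and submodules by attribute assignment, expose
``named_parameters`` for checkpointing and parameter-group selection, and an
``Adam`` optimizer with decoupled freezing of named groups (used by the
freeze/unfreeze training schedule).
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Linear", "Adam", "cosine_lr"]


def _walk(obj, prefix: str):
    """Recursively discover parameters in attributes, lists and nested lists."""
    if isinstance(obj, dict):
        items = obj.items()
    else:
        items = ((str(i), v) for i, v in enumerate(obj))
    for name, val in items:
        full = f"{prefix}{name}"
        if isinstance(val, Tensor):
            if val.requires_grad:
                yield full, val
        elif isinstance(val, Module):
            yield from val.named_parameters(prefix=full + ".")
        elif isinstance(val, (list, tuple)):
            yield from _walk(val, full + ".")


class Module:
    """Base class; parameters/submodules are discovered via ``__dict__``."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        yield from _walk(vars(self), prefix)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_conv(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = pad
        self.weight = Tensor(_he_conv(rng, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = pad
        self.weight = Tensor(_he_conv(rng, (cin, cout, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / cin)
        self.weight = Tensor(rng.normal(0, std, size=(cout, cin)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, ad.transpose(self.weight, (1, 0)))
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


def cosine_lr(epoch: int, total_epochs: int, lr0: float, lr_floor: float = 1e-6) -> float:
    """Cosine-annealed learning rate over the full training horizon."""
    if total_epochs <= 1:
        return lr0
    t = min(epoch, total_epochs - 1) / (total_epochs - 1)
    return lr_floor + 0.5 * (lr0 - lr_floor) * (1.0 + math.cos(math.pi * t))


class Adam:
    """Adam with classic L2 weight decay and per-parameter freeze flags.

    Frozen parameters receive no update at all (no decay, no moment update),
    which keeps them bitwise identical through the frozen phase.
    """

    def __init__(self, named_params: list[tuple[str, Tensor]], lr: float = 6e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.named_params = list(named_params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for _, p in self.named_params]
        self._v = [np.zeros_like(p.data) for _, p in self.named_params]
        self._frozen: set[str] = set()

    def freeze(self, prefixes: tuple[str, ...]):
        self._frozen = {name for name, _ in self.named_params
                        if name.startswith(prefixes)}

    def unfreeze_all(self):
        self._frozen = set()

    def zero_grad(self):
        for _, p in self.named_params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (name, p) in enumerate(self.named_params):
            if name in self._frozen or p.grad is None:
                continue
            g = p.grad.astype(np.float32, copy=False)
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases
                g = g + self.weight_decay * p.data
            m = self._m[i]
            v = self._v[i]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
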