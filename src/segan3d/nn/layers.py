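"""Layer building blocks on top of the autodiff tensor engine."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class; collects parameters and submodules by attribute order."""

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, ModuleList):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self.__dict__.get("_params", {}).values())
        for m in self.__dict__.get("_modules", {}).values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {}
        for k, v in self.__dict__.get("_params", {}).items():
            out[prefix + k] = v
        for k, m in self.__dict__.get("_modules", {}).items():
            out.update(m.named_parameters(prefix + k + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def checksum(self) -> float:
        """Deterministic scalar fingerprint of all parameter values."""
        return float(sum(np.abs(p.data).sum() + (i + 1) * p.data.sum()
                         for i, p in enumerate(self.parameters())))


class ModuleList:
    def __init__(self, mods=()):
        self._items = list(mods)

    def append(self, m: Module):
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self._items:
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {}
        for i, m in enumerate(self._items):
            out.update(m.named_parameters(f"{prefix}{i}."))
        return out


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel ** 3
        self.stride = stride
        self.weight = _he_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, stride=self.stride)


class UpConv3d(Module):
    """Stride-2 transposed convolution (2x2x2 kernel, non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, factor: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.factor = factor
        self.weight = _he_init(rng, (c_in, c_out, factor, factor, factor), c_in)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.upconv3d(x, self.weight, self.bias, factor=self.factor)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng()
        if zero_init:
            self.weight = Tensor(np.zeros((c_in, c_out), dtype=np.float32),
                                 requires_grad=True)
        else:
            self.weight = _he_init(rng, (c_in, c_out), c_in)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        from .tensor import matmul
        return matmul(x, self.weight) + self.bias


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    With the batch size of 1 used throughout training this is the stable
    stand-in for batch normalisation (whose statistics degenerate at
    batch 1); a ``Norm`` factory selects it by default.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=np.float32),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.instance_norm3d(x, self.gamma, self.beta, eps=self.eps)


class Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


def make_norm(kind: str, channels: int) -> Module:
    if kind == "instance":
        return InstanceNorm3d(channels)
    if kind == "none":
        return Identity()
    raise ValueError(f"unknown normalisation kind: {kind!r}")
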