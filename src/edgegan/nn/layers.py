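"""Layer/module system over the autodiff engine.

Conventions follow the field's standard deep-learning APIs: modules own
named parameters and buffers, compose by attribute assignment, and expose
``state_dict``/``load_state_dict`` for checkpointing.  Conv weights are
initialised N(0, 0.02) from an explicit numpy Generator so builds are
seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .convops import batch_norm2d, conv2d, conv_transpose2d

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Linear",
    "LeakyReLU",
    "Sigmoid",
    "Sequential",
    "WEIGHT_INIT_STD",
]

WEIGHT_INIT_STD = 0.02


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            out.update(m.named_state(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, arr in state.items():
            dst = own[k]
            if dst.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: {dst.shape} vs {arr.shape}")
            dst[...] = arr

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(arr.astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, pad: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.weight = _param(rng.normal(0.0, WEIGHT_INIT_STD, (cout, cin, k, k)))
        self.bias = _param(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2, pad: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.weight = _param(rng.normal(0.0, WEIGHT_INIT_STD, (cin, cout, k, k)))
        self.bias = _param(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = _param(np.ones(c))
        self.beta = _param(np.zeros(c))
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.gamma, self.beta,
            self._buffers["running_mean"], self._buffers["running_var"],
            self.training, self.momentum, self.eps,
        )


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _param(rng.normal(0.0, WEIGHT_INIT_STD, (fin, fout)))
        self.bias = _param(np.zeros(fout))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
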