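"""Layer/module abstraction over the functional kernels.

Mirrors the familiar Module/parameter idiom: modules own parameters and
submodules, expose ``train()``/``eval()`` switching, iterate parameters for
the optimiser, and serialise to flat ``name -> ndarray`` state dicts.
Weight init is He-uniform for convolutions (zero biases) and ones/zeros for
batch-norm affine pairs; every constructor takes the RNG explicitly so a
model build is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x",
    "BatchNorm2d",
    "Identity",
    "ReLU",
    "PReLU",
    "GELU",
    "Swish",
    "Mish",
    "MaxPool2x",
    "UpsampleBilinear2x",
    "Dropout2d",
    "make_activation",
    "ACTIVATIONS",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield (prefix + n, b)
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    # -- mode & rng --------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def set_rng(self, rng: np.random.Generator) -> None:
        """Attach the stochastic-forward RNG (dropout) to every submodule."""
        for m in self.modules():
            if isinstance(m, Dropout2d):
                m.rng = rng

    # -- serialisation -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            state["buffer:" + n] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in state.items():
            if k.startswith("buffer:"):
                tgt = bufs[k[len("buffer:"):]]
                tgt[...] = v
            else:
                own[k].data[...] = v

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self._list:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        bound = np.sqrt(6.0 / fan_in)
        w = rng.uniform(
            -bound,
            bound,
            size=(out_channels, in_channels // groups, kernel_size, kernel_size),
        ).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2x(Module):
    """Kernel-2 stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_channels * 4))
        w = rng.uniform(-bound, bound, size=(in_channels, out_channels, 2, 2)).astype(
            np.float32
        )
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2x(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class PReLU(Module):
    """Single learnable negative slope, shared across channels."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.slope = Tensor(np.array([init], np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.prelu(x, self.slope)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.gelu(x)


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.swish(x)


class Mish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.mish(x)


class MaxPool2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2x(x)


class UpsampleBilinear2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_bilinear2x(x)


class Dropout2d(Module):
    """Channel dropout; inert in eval mode or at rate 0."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if self.training and self.p > 0.0 and self.rng is None:
            raise RuntimeError("Dropout2d used in training mode without set_rng()")
        return F.dropout2d(x, self.p, self.rng, self.training)


ACTIVATIONS = {
    "relu": ReLU,
    "prelu": PReLU,
    "gelu": GELU,
    "swish": Swish,
    "mish": Mish,
}


def make_activation(name: str) -> Module:
    try:
        return ACTIVATIONS[name]()
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None
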