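"""Layer abstractions over the autodiff core.

Modules own named parameters and buffers, support train/eval switching,
and initialise weights from an explicit :class:`numpy.random.Generator`
so that two networks built with the same seed are bitwise identical.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A tensor that is always part of the gradient tape."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int,
                    gain: float = np.sqrt(2.0)) -> np.ndarray:
    bound = gain * np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(T.DEFAULT_DTYPE)


class Module:
    """Minimal module base: parameter/buffer registry, train/eval mode."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, list) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value

    # ------------------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix + cname + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        self.training = True
        for c in self._children.values():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children.values():
            c.eval()
        return self

    # -- (de)serialisation ---------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{n}": p.data for n, p in self.named_parameters()}
        state.update({f"buffer.{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        if missing or unexpected:
            raise ValueError(
                f"state dict mismatch: missing={missing}, unexpected={unexpected}")
        for n, p in self.named_parameters():
            src = state[f"param.{n}"]
            if src.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {n}: checkpoint {src.shape} vs model {p.data.shape}")
            p.data = np.ascontiguousarray(src, dtype=T.DEFAULT_DTYPE)
        for n, b in self.named_buffers():
            src = state[f"buffer.{n}"]
            if src.shape != b.shape:
                raise ValueError(
                    f"shape mismatch for buffer {n}: {src.shape} vs {b.shape}")
            b[...] = src

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 convolution with "same" zero padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int] | int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if out_channels <= 0:
            raise ValueError(f"out_channels must be positive, got {out_channels}")
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        self.padding = (kh // 2, kw // 2)
        fan_in = in_channels * kh * kw
        self.weight = Parameter(
            kaiming_uniform(rng, (out_channels, in_channels, kh, kw), fan_in))
        if bias:
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Parameter(
                rng.uniform(-bound, bound, size=out_channels).astype(T.DEFAULT_DTYPE))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=T.DEFAULT_DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=T.DEFAULT_DTYPE))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(x, self.gamma, self.beta,
                            self._buffers["running_mean"],
                            self._buffers["running_var"],
                            self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(
            kaiming_uniform(rng, (out_features, in_features), in_features))
        if bias:
            bound = 1.0 / np.sqrt(in_features)
            self.bias = Parameter(
                rng.uniform(-bound, bound, size=out_features).astype(T.DEFAULT_DTYPE))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        out = x.matmul(_transpose_param(self.weight))
        if self.bias is not None:
            out = out + self.bias
        return out


def _transpose_param(p: Parameter) -> Tensor:
    """View a (out, in) weight as (in, out) for right-multiplication."""
    def bwd(g):
        p._accumulate(g.T)

    return Tensor(p.data.T, parents=(p,), backward=bwd)


class ConvReLUBN(Module):
    """Convolution followed by ReLU then batch normalisation.

    The conv -> ReLU -> BN ordering is a deliberate architectural choice
    of this network family and is kept everywhere for consistency.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x).relu())
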