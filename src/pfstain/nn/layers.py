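"""Neural-network building blocks on top of the autodiff Tensor.

Weight initialisation follows the image-translation GAN convention:
N(0, 0.02) for convolution and linear weights, zero biases, unit affine
scale for instance norm. Every layer draws its initial weights from an
explicit NumPy Generator so that model construction is fully reproducible.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "Linear",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sequential",
]

INIT_STD = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with torch-like parameter discovery over attributes."""

    def named_parameters(self, prefix: str = "") -> "OrderedDict[str, Parameter]":
        params: OrderedDict[str, Parameter] = OrderedDict()
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{key}.{i}."))
        return params

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.data.copy()) for k, v in self.named_parameters().items())

    def load_state_dict(self, state: dict) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, param in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != param.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {param.data.shape}"
                )
            param.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        pad_mode: str = "constant",
        bias: bool = True,
    ):
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode
        self.weight = Parameter(
            rng.normal(0.0, INIT_STD, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.padding:
            x = x.pad2d(self.padding, mode=self.pad_mode)
        return x.conv2d(self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(rng.normal(0.0, INIT_STD, (in_features, out_features)))
        # uniform bias init keeps projections of all-zero feature vectors
        # (possible after ReLU at narrow widths) away from zero norm
        bound = 1.0 / np.sqrt(in_features)
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        if affine:
            self.weight = Parameter(np.ones((1, channels, 1, 1)))
            self.bias = Parameter(np.zeros((1, channels, 1, 1)))
        else:
            self.weight = None
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        out = xc * (var + self.eps) ** -0.5
        if self.weight is not None:
            out = out * self.weight + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
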