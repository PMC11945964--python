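"""Neural-network layers over the autograd tensors.

Follows the familiar Module/Parameter idiom: layers own named parameters,
``train()``/``eval()`` toggle dropout and batch-norm behaviour, and
``state_dict``/``load_state_dict`` move parameters (and running statistics)
as plain numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, adaptive_avg_pool2d, conv2d

_GLOBAL_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the module-level generator used for init and dropout."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _GLOBAL_RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- parameter / submodule discovery --------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- state ----------------------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{full}.{i}.")
            elif name.startswith("running_") and isinstance(value, np.ndarray):
                yield full, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown parameter {name!r}")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or get_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or get_rng()
        fan_in = in_channels * kernel_size * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class _BatchNorm(Module):
    """Shared batch-norm core; subclasses define the reduction axes."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = eps
        self.momentum = momentum

    _axes: tuple[int, ...] = (0,)

    def _shape(self, x: Tensor):
        shape = [1] * x.ndim
        shape[1 if x.ndim > 1 else 0] = -1
        return tuple(shape)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(a for a in range(x.ndim) if a != (1 if x.ndim > 1 else 0))
        shape = self._shape(x)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            n = x.data.size / self.running_mean.size
            unbiased = var.data.reshape(-1) * n / max(n - 1, 1)
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean.data.reshape(-1)
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * unbiased
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class BatchNorm1d(_BatchNorm):
    pass


class BatchNorm2d(_BatchNorm):
    pass


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (get_rng().random(x.shape) < keep) / keep
        return x * Tensor(mask)


class AdaptiveAvgPool2d(Module):
    def __init__(self, output_size: tuple[int, int]):
        super().__init__()
        self.output_size = tuple(output_size)

    def forward(self, x: Tensor) -> Tensor:
        return adaptive_avg_pool2d(x, self.output_size)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)
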