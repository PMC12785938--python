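"""Layer primitives built on the autodiff engine.

Parameter initialization draws from a caller-supplied generator so that two
builds with the same seed have identical initial parameters.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, adaptive_maxpool1d, concat, conv1d, maxpool1d

__all__ = [
    "Module",
    "Conv1d",
    "Linear",
    "BatchNorm1d",
    "Dropout",
    "MaxPool1d",
    "AdaptiveMaxPool1d",
    "Mish",
]


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
        for i, child in enumerate(self.children()):
            cname = type(child).__name__.lower()
            yield from child.named_parameters(prefix=f"{prefix}{cname}{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def weight_parameters(self) -> list[Tensor]:
        """Multiplicative weights only (no biases, no batch-norm affines) --
        the tensors the L2 penalty applies to."""
        out = []
        for v in self.__dict__.values():
            if isinstance(v, (Conv1d, Linear)):
                out.append(v.weight)
            elif isinstance(v, Module):
                out.extend(v.weight_parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.weight_parameters())
        return out

    def train(self) -> None:
        self.training = True
        for c in self.children():
            c.train()

    def eval(self) -> None:
        self.training = False
        for c in self.children():
            c.eval()

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable data plus batch-norm running stats, for checkpoints."""
        arrays = [p.data for p in self.parameters()]
        for m in self._all_modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def _all_modules(self):
        yield self
        for c in self.children():
            yield from c._all_modules()

    def copy_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), state, strict=True):
            dst[...] = src

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | str = "same",
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding == "same":
            if stride != 1 and kernel_size != stride:
                padding = kernel_size // 2
            else:
                padding = kernel_size // 2
        self.stride = stride
        self.padding = int(padding)
        fan_in = in_channels * kernel_size
        bound = float(np.sqrt(1.0 / fan_in))
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(rng.uniform(-bound, bound, size=out_channels),
                           requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = float(np.sqrt(1.0 / in_features))
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(rng.uniform(-bound, bound, size=out_features),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over (N, F) features or (N, C, L) channels."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def __call__(self, x: Tensor) -> Tensor:
        from .autograd import batchnorm

        spatial = x.data.ndim == 3
        if self.training:
            out, mu, var = batchnorm(x, self.gamma, self.beta, eps=self.eps)
            m = x.data.shape[0] * (x.data.shape[2] if spatial else 1)
            unbias = m / max(m - 1, 1)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (unbias * var - self.running_var)
            return out
        shape = (1, -1, 1) if spatial else (1, -1)
        scale = self.gamma.data.reshape(shape) / np.sqrt(
            self.running_var.reshape(shape) + self.eps
        )
        shift = self.beta.data.reshape(shape) - self.running_mean.reshape(shape) * scale
        # eval mode is an affine map with constant statistics; route through
        # autograd only so the call still composes with Tensor inputs
        return x * Tensor(scale) + Tensor(shift)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int | None = None,
                 padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.kernel, self.stride, self.padding)


class AdaptiveMaxPool1d(Module):
    def __init__(self, output_size: int):
        super().__init__()
        self.output_size = output_size

    def __call__(self, x: Tensor) -> Tensor:
        return adaptive_maxpool1d(x, self.output_size)


class Mish(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.mish()
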