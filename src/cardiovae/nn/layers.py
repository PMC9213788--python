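"""Neural-network layers built on the :mod:`cardiovae.nn.tensor` autodiff core.

Initialisation follows the He/Glorot conventions; every layer draws its
weights from an explicitly passed ``numpy.random.Generator`` so that whole
models are pure functions of their seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, concat

__all__ = [
    "Module", "Linear", "MLP", "Conv1d", "ConvTranspose1d", "BatchNorm1d",
    "Sequential", "ELU", "ReLU", "Tanh",
]

_DTYPE = np.float32


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def visit(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in obj.__dict__.values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        for v in self.__dict__.values():
            visit(v)
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # state (de)serialisation -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        arrays = list(arrays)
        for p in self.parameters():
            a = arrays.pop(0)
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype)
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                m.running_mean = arrays.pop(0)
                m.running_var = arrays.pop(0)
        if arrays:
            raise ValueError("extra arrays in state")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_features, dtype=_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.elu(self.alpha)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MLP(Module):
    """Stack of Linear layers with a nonlinearity between (not after) them."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 activation: str = "relu", final_activation: bool = False):
        super().__init__()
        act = {"relu": ReLU, "elu": ELU, "tanh": Tanh}[activation]
        layers: list[Module] = []
        for i in range(len(widths) - 1):
            layers.append(Linear(widths[i], widths[i + 1], rng))
            if i < len(widths) - 2 or final_activation:
                layers.append(act())
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Conv1d(Module):
    """1-D convolution on (B, C, L); kernels of size k x 1 act along time."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, padding: int, rng: np.random.Generator):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.in_channels, self.out_channels = in_channels, out_channels
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.weight = Parameter(
            rng.normal(0.0, scale, (in_channels * kernel, out_channels)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_channels, dtype=_DTYPE))

    @staticmethod
    def out_len(l: int, kernel: int, stride: int, padding: int) -> int:
        return (l + 2 * padding - kernel) // stride + 1

    def forward(self, x: Tensor) -> Tensor:
        if self.padding:
            x = x.pad1d(self.padding, self.padding)
        cols = x.unfold1d(self.kernel, self.stride)          # (B, L_out, C*k)
        out = cols @ self.weight + self.bias                 # (B, L_out, C_out)
        return out.transpose(0, 2, 1)                        # (B, C_out, L_out)


class ConvTranspose1d(Module):
    """Transposed 1-D convolution; inverse length arithmetic of Conv1d."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, padding: int, output_padding: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.padding, self.output_padding = padding, output_padding
        self.in_channels, self.out_channels = in_channels, out_channels
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.weight = Parameter(
            rng.normal(0.0, scale, (in_channels, out_channels * kernel)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_channels, dtype=_DTYPE))

    @staticmethod
    def out_len(l: int, kernel: int, stride: int, padding: int,
                output_padding: int) -> int:
        return (l - 1) * stride - 2 * padding + kernel + output_padding

    def forward(self, x: Tensor) -> Tensor:
        b, c, l = x.shape
        cols = x.transpose(0, 2, 1) @ self.weight            # (B, L, C_out*k)
        full = self.out_len(l, self.kernel, self.stride, 0, 0)
        out = cols.fold1d(full, self.kernel, self.stride)    # (B, C_out, full)
        lo = self.padding
        hi = full - self.padding + self.output_padding
        if hi > full:
            out = out.pad1d(0, hi - full)
        out = out[:, :, lo:hi]
        return out + self.bias.reshape(1, self.out_channels, 1)


class BatchNorm1d(Module):
    """Batch normalisation over (B, C, L) or (B, C); running stats in eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=_DTYPE))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        three_d = x.ndim == 3
        axes = (0, 2) if three_d else (0,)
        shape = (1, -1, 1) if three_d else (1, -1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1).astype(_DTYPE))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1).astype(_DTYPE))
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * inv
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)
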