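"""Neural-network building blocks on top of the autograd engine.

Layers follow the usual conventions: ``Linear`` acts on the last axis,
``BatchNorm1d`` normalises per channel with running statistics for
evaluation, ``Conv1d`` consumes ``(batch, channels, length)``, and
``LSTM`` consumes ``(batch, length, features)`` with an optional
positions mask for padded sequences.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor, concatenate, no_grad, where_mask

__all__ = [
    "Module",
    "Linear",
    "BatchNorm1d",
    "Conv1d",
    "LSTM",
    "Sequential",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{name}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")
            elif isinstance(value, np.ndarray) and key.startswith("running_"):
                yield name, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{n}": b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name.startswith("buffer:"):
                target = buffers[name[len("buffer:"):]]
                target[...] = value
            else:
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {value.shape}")
                params[name].data[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(glorot(rng, in_features, out_features,
                                       (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Per-channel batch normalisation for (B, C) or (B, C, L) inputs."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 3:
            axes = (0, 2)
            view = (1, self.num_features, 1)
        else:
            axes = (0,)
            view = (1, self.num_features)
        if self.training:
            mean = x.mean(axis=axes[0], keepdims=True)
            if x.ndim == 3:
                mean = mean.mean(axis=2, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes[0], keepdims=True)
            if x.ndim == 3:
                var = var.mean(axis=2, keepdims=True)
            with no_grad():
                m = self.momentum
                self.running_mean *= (1 - m)
                self.running_mean += m * mean.data.reshape(self.num_features)
                self.running_var *= (1 - m)
                self.running_var += m * var.data.reshape(self.num_features)
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mean = Tensor(self.running_mean.reshape(view))
            var = Tensor(self.running_var.reshape(view))
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(*view) + self.beta.reshape(*view)


class Conv1d(Module):
    """1-D convolution, stride 1, zero 'same' padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = Parameter(glorot(rng, fan_in, out_channels,
                                       (kernel_size, in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (B, {self.in_channels}, L) input, got {x.shape}")
        b, _, length = x.shape
        pad = self.kernel_size // 2
        if pad:
            zeros = Tensor(np.zeros((b, self.in_channels, pad)))
            x = concatenate([zeros, x, zeros], axis=2)
        x = x.swapaxes(1, 2)  # (B, L+2p, C_in)
        out = None
        for j in range(self.kernel_size):
            window = x[:, j:j + length, :]
            term = window @ self.weight[j]
            out = term if out is None else out + term
        out = out + self.bias
        return out.swapaxes(1, 2)  # (B, C_out, L)


class LSTM(Module):
    """Single-layer (optionally bidirectional) LSTM over (B, L, C)."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, bidirectional: bool = True):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.bidirectional = bidirectional
        directions = 2 if bidirectional else 1
        self.w_x = [Parameter(glorot(rng, input_size, hidden_size,
                                     (input_size, 4 * hidden_size)))
                    for _ in range(directions)]
        self.w_h = [Parameter(glorot(rng, hidden_size, hidden_size,
                                     (hidden_size, 4 * hidden_size)))
                    for _ in range(directions)]
        # forget-gate bias 1: standard trick for gradient flow early on
        biases = []
        for _ in range(directions):
            b = np.zeros(4 * hidden_size)
            b[hidden_size:2 * hidden_size] = 1.0
            biases.append(Parameter(b))
        self.b = biases

    def _run(self, x: Tensor, direction: int, mask: np.ndarray | None) -> Tensor:
        batch, length, _ = x.shape
        h = Tensor(np.zeros((batch, self.hidden_size)))
        c = Tensor(np.zeros((batch, self.hidden_size)))
        steps = range(length) if direction == 0 else range(length - 1, -1, -1)
        outputs: dict[int, Tensor] = {}
        hs = self.hidden_size
        for t in steps:
            z = x[:, t, :] @ self.w_x[direction] + h @ self.w_h[direction] \
                + self.b[direction]
            i = z[:, :hs].sigmoid()
            f = z[:, hs:2 * hs].sigmoid()
            g = z[:, 2 * hs:3 * hs].tanh()
            o = z[:, 3 * hs:].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            if mask is not None:
                m = mask[:, t:t + 1]
                c = where_mask(m, c_new, c)
                h = where_mask(m, h_new, h)
            else:
                c, h = c_new, h_new
            outputs[t] = h
        from .autograd import stack
        return stack([outputs[t] for t in range(length)], axis=1)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        if x.ndim != 3:
            raise ValueError("LSTM expects (batch, length, features)")
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        fwd = self._run(x, 0, mask)
        if not self.bidirectional:
            return fwd
        bwd = self._run(x, 1, mask)
        return concatenate([fwd, bwd], axis=2)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
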