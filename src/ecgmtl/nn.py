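"""Neural-network layers and the Adam optimizer on the autodiff engine.

Layers follow the conventions of mainstream deep-learning frameworks so the
architecture modules read familiarly: channels-first sequence tensors
(batch, channels, time), Glorot-uniform weight init, batch statistics in
training mode and running statistics in eval mode for batch norm, and the
standard (reset, update, candidate) GRU gate equations.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d

__all__ = [
    "Module", "Linear", "Conv1d", "BatchNorm1d", "Dropout", "GRU", "BiGRU", "Adam",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def modules(self):
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield attr
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = [v for v in vars(self).values()
                  if isinstance(v, Tensor) and v.requires_grad]
        for m in self.modules():
            params.extend(v for v in vars(m).values()
                          if isinstance(v, Tensor) and v.requires_grad)
        return params

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameter arrays plus batch-norm running stats."""
        arrays = [p.data for p in self.parameters()]
        for m in [self, *self.modules()]:
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state size mismatch: {len(own)} vs {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            glorot_uniform(rng, (in_features, out_features), in_features, out_features),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None):
        super().__init__()
        if padding is None:  # 'same' length for stride 1, odd kernels
            padding = (kernel_size - 1) // 2
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.weight = Tensor(
            glorot_uniform(rng, (out_channels, in_channels, kernel_size),
                           fan_in, fan_out),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, time) for (N, C, T) tensors."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean += self.momentum * (
                mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1))
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class GRU(Module):
    """Single-direction gated recurrent unit.

    Gate equations (t = 1..T, h_0 = 0):
        r_t = sigmoid(x_t Wxr + h_{t-1} Whr + br)
        z_t = sigmoid(x_t Wxz + h_{t-1} Whz + bz)
        n_t = tanh(x_t Wxn + bxn + r_t * (h_{t-1} Whn + bhn))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        h = hidden_size
        self.hidden_size = h
        self.wx = Tensor(glorot_uniform(rng, (input_size, 3 * h), input_size, h),
                         requires_grad=True)
        self.wh = Tensor(glorot_uniform(rng, (h, 3 * h), h, h), requires_grad=True)
        self.bx = Tensor(np.zeros(3 * h), requires_grad=True)
        self.bh = Tensor(np.zeros(3 * h), requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        """Run over (N, T, C); return the final hidden state (N, H)."""
        n_batch, t_len, _ = x.shape
        if t_len == 0:
            raise ValueError("GRU requires a non-empty time axis")
        h_dim = self.hidden_size
        h = Tensor(np.zeros((n_batch, h_dim)))
        xw = x @ self.wx + self.bx  # precompute input projections for all steps
        steps = range(t_len - 1, -1, -1) if reverse else range(t_len)
        for t in steps:
            a = xw[:, t, :]
            hp = h @ self.wh + self.bh
            r = (a[:, :h_dim] + hp[:, :h_dim]).sigmoid()
            z = (a[:, h_dim:2 * h_dim] + hp[:, h_dim:2 * h_dim]).sigmoid()
            n = (a[:, 2 * h_dim:] + r * hp[:, 2 * h_dim:]).tanh()
            h = (1.0 - z) * n + z * h
        return h


class BiGRU(Module):
    """Bidirectional GRU; output is [h_T(forward), h_T(backward)], size 2H."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = GRU(input_size, hidden_size, rng)
        self.bwd = GRU(input_size, hidden_size, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x, reverse=True)], axis=1)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
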