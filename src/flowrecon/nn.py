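"""Small neural-network layer zoo on top of the autodiff core.

Provides exactly what the coupling subnetworks and conditioning networks
need: 2-D convolutions, leaky-ReLU stacks, average pooling, nearest
upsampling and an Adam optimizer.  Weights are ``float64`` throughout.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor, conv2d

__all__ = [
    "Module",
    "Conv2d",
    "Sequential",
    "LeakyReLU",
    "conv_subnet",
    "avg_pool2x",
    "Adam",
]


class Module:
    """Container tracking parameter tensors through attribute assignment."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj) -> None:
            if id(obj) in seen:
                return
            seen.add(id(obj))
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    params.append(obj)
            elif isinstance(obj, Module):
                for value in vars(obj).values():
                    visit(value)
            elif isinstance(obj, (list, tuple)):
                for value in obj:
                    visit(value)

        visit(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """k x k convolution, zero-padded, He-initialized (or zero-initialized)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng()
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            scale = np.sqrt(2.0 / (c_in * kernel * kernel))
            w = rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = (kernel - 1) // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(as_tensor(x), self.weight, self.bias,
                      stride=self.stride, pad=self.pad)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x).leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def conv_subnet(c_in: int, c_out: int, hidden: int = 64, kernel: int = 3,
                rng: np.random.Generator | None = None) -> Sequential:
    """Default coupling subnetwork: 3 convolutions, zero-initialized output.

    The zero-initialized final layer makes every coupling start as the
    identity map, which keeps early training stable.
    """
    rng = rng or np.random.default_rng()
    return Sequential(
        Conv2d(c_in, hidden, kernel, rng=rng),
        LeakyReLU(),
        Conv2d(hidden, hidden, kernel, rng=rng),
        LeakyReLU(),
        Conv2d(hidden, c_out, kernel, rng=rng, zero_init=True),
    )


def avg_pool2x(x: Tensor) -> Tensor:
    """2x2 average pooling of a (B,C,H,W) tensor."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2x requires even spatial dimensions")
    return (
        x.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)) * 0.25
    )


class Adam:
    """Adaptive-moment gradient descent (Kingma & Ba) over parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, clip_norm: float | None = None) -> None:
        self.t += 1
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad**2))
                                for p in self.params if p.grad is not None))
            scale = min(1.0, clip_norm / (total + 1e-12))
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
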