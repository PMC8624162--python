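"""Invertible building blocks for normalizing flows on images.

Every layer maps a ``(B, C, H, W)`` batch to an output of identical total
element count and reports the exact per-sample log-determinant of its
Jacobian (natural log).  Layers expose

* ``forward(x, cond) -> (y, logdet)`` on autodiff tensors (x -> z direction,
  gradients available), and
* ``inverse(y, cond) -> x`` on plain numpy arrays (sampling direction).

Coupling layers split the channel axis into two blocks ``I1 = x[:c1]`` and
``I2 = x[c1:]``; ``I1`` passes through unchanged while ``I2`` is shifted
(additive) or scaled-and-shifted (affine) by a subnetwork of ``I1`` and,
optionally, conditioning features.  The affine log-scale is soft-clamped to
``[-clamp, clamp]`` via ``clamp * tanh(s / clamp)`` so the inverse pass
cannot blow up (the "exploding inverse" failure mode of unbounded scales).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, concatenate
from .nn import Module, conv_subnet

__all__ = [
    "CouplingSpec",
    "FlowStepResult",
    "AdditiveCoupling",
    "AffineCoupling",
    "MixChannels",
    "CheckerboardDownsample",
    "HaarDownsample",
    "coupling_forward",
    "coupling_inverse",
    "mix_channels",
    "checkerboard_downsample",
    "checkerboard_upsample",
    "haar_downsample",
    "haar_upsample",
    "split_channels",
    "merge_channels",
    "pad_to_multiple",
]

HAAR_MATRIX = 0.5 * np.array(
    [
        [1.0, 1.0, 1.0, 1.0],    # average
        [1.0, -1.0, 1.0, -1.0],  # horizontal detail
        [1.0, 1.0, -1.0, -1.0],  # vertical detail
        [1.0, -1.0, -1.0, 1.0],  # diagonal detail
    ]
)


@dataclass
class CouplingSpec:
    """Blueprint for one coupling layer.

    ``split_sizes = (c1, c2)`` partitions the channel axis; ``clamp`` bounds
    the effective affine log-scale; ``hidden_width``/``kernel`` describe the
    subnetwork; ``conditional`` appends conditioning channels to the
    subnetwork input.
    """

    kind: str = "affine"
    split_sizes: tuple[int, int] = (1, 1)
    clamp: float = 2.0
    hidden_width: int = 64
    kernel: int = 3
    conditional: bool = False
    cond_channels: int = 0

    def __post_init__(self):
        if self.kind not in ("additive", "affine"):
            raise ValueError(f"unknown coupling kind {self.kind!r}")
        c1, c2 = self.split_sizes
        if c1 < 1 or c2 < 1:
            raise ValueError("both channel blocks must be non-empty")
        if self.clamp <= 0:
            raise ValueError("clamp must be positive")
        if self.conditional and self.cond_channels < 1:
            raise ValueError("conditional coupling needs cond_channels >= 1")

    def build(self, rng: np.random.Generator) -> "AdditiveCoupling | AffineCoupling":
        cls = AffineCoupling if self.kind == "affine" else AdditiveCoupling
        return cls(self, rng=rng)


@dataclass
class FlowStepResult:
    """Transformed array plus accumulated per-sample log-determinant."""

    output: np.ndarray
    logdet: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.logdet)):
            raise FloatingPointError("non-finite log-determinant")


def _check_input(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in coupling input")


class _Coupling(Module):
    """Common channel-split plumbing for both coupling laws."""

    def __init__(self, spec: CouplingSpec, rng: np.random.Generator | None = None,
                 subnet=None):
        self.spec = spec
        c1, c2 = spec.split_sizes
        self.c1, self.c2 = c1, c2
        out_mult = 2 if spec.kind == "affine" else 1
        if subnet is None:
            n_in = c1 + (spec.cond_channels if spec.conditional else 0)
            subnet = conv_subnet(n_in, out_mult * c2, hidden=spec.hidden_width,
                                 kernel=spec.kernel, rng=rng or np.random.default_rng())
        self.subnet = subnet

    def _validate(self, x, cond) -> None:
        c = x.shape[1]
        if c != self.c1 + self.c2:
            raise ValueError(
                f"input has {c} channels, split_sizes expect {self.c1 + self.c2}"
            )
        if self.spec.conditional and cond is None:
            raise ValueError("conditional coupling called without conditioning")
        if not self.spec.conditional and cond is not None:
            raise ValueError("unconditional coupling given conditioning input")
        if cond is not None and cond.shape[2:] != x.shape[2:]:
            raise ValueError("conditioning spatial size must match the input")

    def _net_input(self, x1: Tensor, cond) -> Tensor:
        if self.spec.conditional:
            return concatenate([x1, as_tensor(cond)], axis=1)
        return x1


class AdditiveCoupling(_Coupling):
    """y2 = x2 + M(x1[, cond]); unit Jacobian determinant."""

    def forward(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        _check_input(x.data)
        self._validate(x.data, None if cond is None else as_tensor(cond).data)
        x1, x2 = x[:, : self.c1], x[:, self.c1 :]
        t = self.subnet(self._net_input(x1, cond))
        y = concatenate([x1, x2 + t], axis=1)
        logdet = Tensor(np.zeros(x.shape[0]))
        self.last_max_scale = 0.0
        return y, logdet

    def inverse(self, y: np.ndarray, cond=None) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        _check_input(y)
        self._validate(y, cond)
        y1, y2 = y[:, : self.c1], y[:, self.c1 :]
        t = self.subnet(self._net_input(Tensor(y1), cond)).data
        return np.concatenate([y1, y2 - t], axis=1)


class AffineCoupling(_Coupling):
    """y2 = x2 * exp(s) + t with s soft-clamped; logdet = sum of log-scales."""

    def _scale_shift(self, x1: Tensor, cond) -> tuple[Tensor, Tensor]:
        out = self.subnet(self._net_input(x1, cond))
        raw_s, t = out[:, : self.c2], out[:, self.c2 :]
        clamp = self.spec.clamp
        s = (raw_s * (1.0 / clamp)).tanh() * clamp
        return s, t

    def forward(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        _check_input(x.data)
        self._validate(x.data, None if cond is None else as_tensor(cond).data)
        x1, x2 = x[:, : self.c1], x[:, self.c1 :]
        s, t = self._scale_shift(x1, cond)
        y = concatenate([x1, x2 * s.exp() + t], axis=1)
        logdet = s.sum(axis=(1, 2, 3))
        self.last_max_scale = float(np.abs(s.data).max())
        return y, logdet

    def inverse(self, y: np.ndarray, cond=None) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        _check_input(y)
        self._validate(y, cond)
        y1, y2 = y[:, : self.c1], y[:, self.c1 :]
        s, t = self._scale_shift(Tensor(y1), cond)
        x2 = (y2 - t.data) * np.exp(-s.data)
        return np.concatenate([y1, x2], axis=1)


class MixChannels(Module):
    """Fixed invertible 1x1 convolution: every pixel's channel vector is
    multiplied by a frozen matrix Q (orthogonal by default, so logdet = 0)."""

    def __init__(self, n_channels: int, rng: np.random.Generator | None = None,
                 matrix: np.ndarray | None = None, mode: str = "orthogonal"):
        if matrix is None:
            rng = rng or np.random.default_rng()
            if mode == "orthogonal":
                a = rng.normal(size=(n_channels, n_channels))
                q, r = np.linalg.qr(a)
                matrix = q * np.sign(np.diag(r))
            elif mode == "permutation":
                matrix = np.eye(n_channels)[rng.permutation(n_channels)]
            else:
                raise ValueError(f"unknown mixing mode {mode!r}")
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("mixing matrix must be square")
        if matrix.shape[0] != n_channels:
            raise ValueError("mixing matrix side must equal channel count")
        sign, logabsdet = np.linalg.slogdet(matrix)
        if sign == 0 or not np.isfinite(logabsdet):
            raise ValueError("mixing matrix must be invertible")
        self.q = matrix
        self.q_inv = np.linalg.inv(matrix)
        self.logabsdet = float(logabsdet)

    def _apply(self, x: Tensor, m: np.ndarray) -> Tensor:
        B, C, H, W = x.shape
        # (B,C,H,W) -> (B,HW,C) @ m.T -> back
        xt = x.reshape(B, C, H * W).transpose(0, 2, 1)
        yt = xt @ Tensor(m.T)
        return yt.transpose(0, 2, 1).reshape(B, C, H, W)

    def forward(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        B, C, H, W = x.shape
        y = self._apply(x, self.q)
        logdet = Tensor(np.full(B, H * W * self.logabsdet))
        return y, logdet

    def inverse(self, y: np.ndarray, cond=None) -> np.ndarray:
        return self._apply(Tensor(np.asarray(y, dtype=np.float64)), self.q_inv).data


def _check_even(x) -> None:
    if x.shape[2] % 2 or x.shape[3] % 2:
        raise ValueError(
            f"spatial size {x.shape[2:]} must be even; pad with pad_to_multiple first"
        )


class CheckerboardDownsample(Module):
    """Rearrange pixels: (B,C,H,W) -> (B,4C,H/2,W/2), a pure permutation.

    Output channel 4c+k holds polyphase component k = 2*di+dj of input
    channel c, i.e. pixels at offsets (di, dj) within each 2x2 block.
    """

    def forward(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        _check_even(x)
        B, C, H, W = x.shape
        y = (
            x.reshape(B, C, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(B, 4 * C, H // 2, W // 2)
        )
        return y, Tensor(np.zeros(B))

    def inverse_t(self, y: Tensor) -> Tensor:
        y = as_tensor(y)
        B, C4, H2, W2 = y.shape
        if C4 % 4:
            raise ValueError("channel count must be a multiple of 4")
        return (
            y.reshape(B, C4 // 4, 2, 2, H2, W2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, C4 // 4, 2 * H2, 2 * W2)
        )

    def inverse(self, y: np.ndarray, cond=None) -> np.ndarray:
        return self.inverse_t(Tensor(np.asarray(y, dtype=np.float64))).data


class HaarDownsample(Module):
    """Orthonormal 2-D Haar transform of each 2x2 block.

    Each input channel yields (average, horizontal, vertical, diagonal)
    coefficient channels; the transform is an isometry so logdet = 0.
    """

    def __init__(self):
        self.squeeze = CheckerboardDownsample()

    def _mix(self, c: int) -> np.ndarray:
        return np.kron(np.eye(c), HAAR_MATRIX)

    def forward(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        _check_even(x)
        B, C, H, W = x.shape
        y, _ = self.squeeze.forward(x)
        m = Tensor(self._mix(C).T)
        yt = y.reshape(B, 4 * C, (H // 2) * (W // 2)).transpose(0, 2, 1) @ m
        y = yt.transpose(0, 2, 1).reshape(B, 4 * C, H // 2, W // 2)
        return y, Tensor(np.zeros(B))

    def inverse_t(self, y: Tensor) -> Tensor:
        y = as_tensor(y)
        B, C4, H2, W2 = y.shape
        # orthonormal: inverse mix = transpose of the forward mix
        m_inv = Tensor(self._mix(C4 // 4))
        yt = y.reshape(B, C4, H2 * W2).transpose(0, 2, 1) @ m_inv
        return self.squeeze.inverse_t(yt.transpose(0, 2, 1).reshape(B, C4, H2, W2))

    def inverse(self, y: np.ndarray, cond=None) -> np.ndarray:
        return self.inverse_t(Tensor(np.asarray(y, dtype=np.float64))).data


# ---------------------------------------------------------------------------
# Functional wrappers (numpy in / numpy out)
# ---------------------------------------------------------------------------

def _as_result(y: Tensor, logdet: Tensor) -> FlowStepResult:
    return FlowStepResult(output=y.data, logdet=np.atleast_1d(logdet.data))


def coupling_forward(x: np.ndarray, cond: np.ndarray | None, spec: CouplingSpec,
                     subnet=None, rng: np.random.Generator | None = None
                     ) -> FlowStepResult:
    """One coupling step.  ``subnet`` may be any callable Tensor -> Tensor
    (e.g. a stub for testing); otherwise a fresh default subnetwork is built."""
    layer = _make_coupling(spec, subnet, rng)
    y, logdet = layer.forward(Tensor(np.asarray(x, dtype=np.float64)), cond)
    return _as_result(y, logdet)


def coupling_inverse(y: np.ndarray, cond: np.ndarray | None, spec: CouplingSpec,
                     subnet=None, rng: np.random.Generator | None = None
                     ) -> np.ndarray:
    layer = _make_coupling(spec, subnet, rng)
    return layer.inverse(np.asarray(y, dtype=np.float64), cond)


def _make_coupling(spec, subnet, rng):
    cls = AffineCoupling if spec.kind == "affine" else AdditiveCoupling
    return cls(spec, rng=rng or np.random.default_rng(0), subnet=subnet)


def mix_channels(x: np.ndarray, q: np.ndarray) -> FlowStepResult:
    x = np.asarray(x, dtype=np.float64)
    layer = MixChannels(x.shape[1], matrix=q)
    y, logdet = layer.forward(Tensor(x))
    return _as_result(y, logdet)


def checkerboard_downsample(x: np.ndarray) -> FlowStepResult:
    y, logdet = CheckerboardDownsample().forward(Tensor(np.asarray(x, dtype=np.float64)))
    return _as_result(y, logdet)


def checkerboard_upsample(y: np.ndarray) -> FlowStepResult:
    x = CheckerboardDownsample().inverse(np.asarray(y, dtype=np.float64))
    return FlowStepResult(output=x, logdet=np.zeros(x.shape[0]))


def haar_downsample(x: np.ndarray) -> FlowStepResult:
    y, logdet = HaarDownsample().forward(Tensor(np.asarray(x, dtype=np.float64)))
    return _as_result(y, logdet)


def haar_upsample(y: np.ndarray) -> FlowStepResult:
    x = HaarDownsample().inverse(np.asarray(y, dtype=np.float64))
    return FlowStepResult(output=x, logdet=np.zeros(x.shape[0]))


def split_channels(x: np.ndarray, n_keep: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Partition channels into (kept, forwarded); default keeps half."""
    x = np.asarray(x)
    c = x.shape[1]
    if c < 2:
        raise ValueError("split requires at least 2 channels")
    if n_keep is None:
        n_keep = c // 2
    if not 1 <= n_keep < c:
        raise ValueError(f"n_keep={n_keep} must lie in [1, {c - 1}]")
    return x[:, :n_keep], x[:, n_keep:]


def merge_channels(kept: np.ndarray, forwarded: np.ndarray) -> np.ndarray:
    return np.concatenate([kept, forwarded], axis=1)


def pad_to_multiple(x: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad the trailing spatial axes of ``x`` up to a multiple.

    Invertible layers reject odd spatial sizes, so callers pad images to a
    multiple of ``2**L`` before building a flow.  Returns the padded array
    and the (bottom, right) padding applied.
    """
    h, w = x.shape[-2], x.shape[-1]
    ph = (-h) % multiple
    pw = (-w) % multiple
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, pad), (ph, pw)
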