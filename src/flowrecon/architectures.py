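"""Conditional flow architectures: multi-scale flow and invertible UNet.

Both assemble the invertible building blocks of :mod:`flowrecon.layers`
into an exact bijection between image space and a latent space of equal
total dimension, exposing

* ``forward(x, cond) -> (latent, per-sample logdet)``  (density direction),
* ``inverse(latent, cond) -> x``                       (sampling direction).

Multi-scale flow
    Per scale: couplings (with channel mixing) -> invertible downsampling
    -> couplings -> channel split; the split-off half exits directly to the
    latent output, so deeper scales process progressively fewer channels at
    lower resolution.  The latent is an ordered list of chunks
    ``z = (z_1, ..., z_L)``.

Invertible UNet (iUNet)
    A down path (coupling -> channel split -> invertible downsampling, with
    the split-off part kept as a skip), a bottom coupling, and an up path
    (invertible upsampling -> concat skip -> coupling) that re-absorbs the
    skips step by step, producing a single latent image of the input's
    shape.  Additive couplings are the default here: their unit Jacobian
    keeps the inverse pass numerically exact, which this deep nested
    topology otherwise struggles with (exploding inverses).

Inputs with a single channel are first passed through a fixed checkerboard
rearrangement ("initial squeeze") so that couplings have at least two
channels to split; it is a permutation, costs no log-determinant, and is
undone on the inverse pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, concatenate
from .layers import (
    AdditiveCoupling,
    AffineCoupling,
    CheckerboardDownsample,
    CouplingSpec,
    HaarDownsample,
    MixChannels,
)
from .nn import Module

__all__ = [
    "MultiScaleConfig",
    "IUNetConfig",
    "LatentSplit",
    "MultiScaleFlow",
    "IUNet",
    "build_flow",
    "multiscale_forward",
    "multiscale_inverse",
    "iunet_forward",
    "iunet_inverse",
]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class MultiScaleConfig:
    input_shape: tuple[int, int, int] = (1, 8, 8)
    n_scales: int = 2
    blocks_per_scale: int = 2
    coupling: str = "affine"
    downsampling: str = "checkerboard"
    clamp: float = 2.0
    hidden_width: int = 64
    kernel: int = 3
    mixing: str | None = "orthogonal"   # 'orthogonal' | 'permutation' | None
    cond_channels: tuple[int, ...] | int | None = None
    split_fraction: float = 0.5
    initial_squeeze: bool | None = None  # None -> auto (squeeze 1-channel inputs)

    def __post_init__(self):
        c, h, w = self.input_shape
        if self.n_scales < 1:
            raise ValueError("need at least one scale")
        if self.downsampling not in ("checkerboard", "haar"):
            raise ValueError(f"unknown downsampling {self.downsampling!r}")
        squeeze = self.initial_squeeze
        if squeeze is None:
            squeeze = c < 2
        factor = 2 ** (self.n_scales - 1) * (2 if squeeze else 1)
        if h % factor or w % factor:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by {factor} "
                f"for {self.n_scales} scales"
            )

    def cond_channels_at(self, level: int) -> int:
        if self.cond_channels is None:
            return 0
        if isinstance(self.cond_channels, int):
            return self.cond_channels
        return self.cond_channels[level]


@dataclass
class IUNetConfig(MultiScaleConfig):
    coupling: str = "additive"


@dataclass
class LatentSplit:
    """Ordered latent chunks plus the accumulated per-sample logdet."""

    chunks: list[np.ndarray]
    logdet: np.ndarray

    @property
    def n_elements(self) -> int:
        return int(sum(c[0].size for c in self.chunks))

    def to_vector(self) -> np.ndarray:
        """Serialize chunks in scale order, each flattened row-major."""
        b = self.chunks[0].shape[0]
        return np.concatenate([c.reshape(b, -1) for c in self.chunks], axis=1)

    @staticmethod
    def vector_to_chunks(vec: np.ndarray, shapes: list[tuple[int, ...]]
                         ) -> list[np.ndarray]:
        vec = np.atleast_2d(vec)
        sizes = [int(np.prod(s)) for s in shapes]
        if vec.shape[1] != sum(sizes):
            raise ValueError("latent vector length does not match chunk shapes")
        out, start = [], 0
        for s, size in zip(shapes, sizes):
            out.append(vec[:, start : start + size].reshape(vec.shape[0], *s))
            start += size
        return out


def _make_downsampler(kind: str):
    return CheckerboardDownsample() if kind == "checkerboard" else HaarDownsample()


def _split_cond(cond, n_levels: int):
    """Normalize the conditioning argument to (down_list, up_list) or None."""
    if cond is None:
        return None, None
    if isinstance(cond, tuple) and len(cond) == 2 and isinstance(cond[0], (list, tuple)):
        down, up = cond
    else:
        features = list(cond.features) if hasattr(cond, "features") else list(cond)
        down = up = features
    if len(down) != n_levels or len(up) != n_levels:
        raise ValueError(
            f"conditioning pyramid must have {n_levels} levels, "
            f"got {len(down)}/{len(up)}"
        )
    return [as_tensor(f) for f in down], [as_tensor(f) for f in up]


class _FlowBase(Module):
    """Shared plumbing: initial squeeze, coupling construction, monitors."""

    def __init__(self, cfg: MultiScaleConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.rng = rng or np.random.default_rng(0)
        c, h, w = cfg.input_shape
        self.squeeze_input = cfg.initial_squeeze if cfg.initial_squeeze is not None else c < 2
        self._squeezer = CheckerboardDownsample()
        self.n_latent = int(c * h * w)
        self.max_abs_scale_ = 0.0
        self._couplings: list = []

    def _entry_shape(self) -> tuple[int, int, int]:
        c, h, w = self.cfg.input_shape
        if self.squeeze_input:
            return 4 * c, h // 2, w // 2
        return c, h, w

    def _new_coupling(self, c: int, level: int):
        cfg = self.cfg
        cond_ch = cfg.cond_channels_at(level)
        spec = CouplingSpec(
            kind=cfg.coupling,
            split_sizes=((c + 1) // 2, c // 2),
            clamp=cfg.clamp,
            hidden_width=cfg.hidden_width,
            kernel=cfg.kernel,
            conditional=cond_ch > 0,
            cond_channels=cond_ch,
        )
        layer = spec.build(self.rng)
        self._couplings.append(layer)
        return layer

    def _new_mix(self, c: int):
        if self.cfg.mixing is None or self.cfg.mixing == "none":
            return None
        return MixChannels(c, rng=self.rng, mode=self.cfg.mixing)

    def _update_monitor(self):
        self.max_abs_scale_ = max(
            (getattr(cp, "last_max_scale", 0.0) for cp in self._couplings),
            default=0.0,
        )

    def cond_shapes(self) -> list[tuple[int, int, int]]:
        """(channels, h, w) required of the conditioning pyramid per level."""
        c, h, w = self._entry_shape()
        shapes = []
        for level in range(self.cfg.n_scales):
            shapes.append(
                (self.cfg.cond_channels_at(level), h // 2**level, w // 2**level)
            )
        return shapes


# ---------------------------------------------------------------------------
# Multi-scale architecture
# ---------------------------------------------------------------------------

class MultiScaleFlow(_FlowBase):
    """Real-NVP-style multi-scale conditional flow."""

    def __init__(self, cfg: MultiScaleConfig, rng: np.random.Generator | None = None):
        super().__init__(cfg, rng)
        L, b = cfg.n_scales, cfg.blocks_per_scale
        c, h, w = self._entry_shape()
        self.scales: list[dict] = []
        self.latent_shapes: list[tuple[int, int, int]] = []
        for i in range(L):
            last = i == L - 1
            pre_n = (b + 1) // 2 if not last else b
            post_n = b - pre_n if not last else 0
            stage = {"pre": [], "post": [], "down": None, "n_split": 0}
            for _ in range(pre_n):
                stage["pre"].append((self._new_coupling(c, i), self._new_mix(c)))
            if not last:
                stage["down"] = _make_downsampler(cfg.downsampling)
                c, h, w = 4 * c, h // 2, w // 2
                for _ in range(post_n):
                    stage["post"].append(
                        (self._new_coupling(c, i + 1), self._new_mix(c))
                    )
                n_split = max(1, int(round(c * cfg.split_fraction)))
                n_split = min(n_split, c - 1)
                stage["n_split"] = n_split
                self.latent_shapes.append((n_split, h, w))
                c = c - n_split
            else:
                self.latent_shapes.append((c, h, w))
            self.scales.append(stage)

    # -- density direction ---------------------------------------------------
    def forward(self, x: Tensor, cond=None) -> tuple[list[Tensor], Tensor]:
        x = as_tensor(x)
        down, _ = _split_cond(cond, self.cfg.n_scales)
        B = x.shape[0]
        logdet = Tensor(np.zeros(B))
        if self.squeeze_input:
            x, _ = self._squeezer.forward(x)
        chunks: list[Tensor] = []
        for i, stage in enumerate(self.scales):
            for coupling, mix in stage["pre"]:
                x, ld = coupling.forward(x, None if down is None else down[i])
                logdet = logdet + ld
                if mix is not None:
                    x, ld = mix.forward(x)
                    logdet = logdet + ld
            if stage["down"] is not None:
                x, ld = stage["down"].forward(x)
                logdet = logdet + ld
                for coupling, mix in stage["post"]:
                    x, ld = coupling.forward(x, None if down is None else down[i + 1])
                    logdet = logdet + ld
                    if mix is not None:
                        x, ld = mix.forward(x)
                        logdet = logdet + ld
                n_split = stage["n_split"]
                chunks.append(x[:, :n_split])
                x = x[:, n_split:]
            else:
                chunks.append(x)
        self._update_monitor()
        return chunks, logdet

    def forward_vector(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        chunks, logdet = self.forward(x, cond)
        B = chunks[0].shape[0]
        flat = [c.reshape(B, -1) for c in chunks]
        return concatenate(flat, axis=1), logdet

    # -- sampling direction ---------------------------------------------------
    def inverse(self, latent, cond=None) -> np.ndarray:
        if isinstance(latent, LatentSplit):
            chunks = latent.chunks
        elif isinstance(latent, np.ndarray) and latent.ndim <= 2:
            chunks = LatentSplit.vector_to_chunks(latent, self.latent_shapes)
        else:
            chunks = list(latent)
        down, _ = _split_cond(cond, self.cfg.n_scales)
        down_np = None if down is None else [f.data for f in down]
        x = np.asarray(chunks[-1], dtype=np.float64)
        for i in range(self.cfg.n_scales - 1, -1, -1):
            stage = self.scales[i]
            if stage["down"] is not None:
                x = np.concatenate([np.asarray(chunks[i], dtype=np.float64), x], axis=1)
                for coupling, mix in reversed(stage["post"]):
                    if mix is not None:
                        x = mix.inverse(x)
                    x = coupling.inverse(x, None if down_np is None else down_np[i + 1])
                x = stage["down"].inverse(x)
            for coupling, mix in reversed(stage["pre"]):
                if mix is not None:
                    x = mix.inverse(x)
                x = coupling.inverse(x, None if down_np is None else down_np[i])
        if self.squeeze_input:
            x = self._squeezer.inverse(x)
        return x


# ---------------------------------------------------------------------------
# Invertible UNet
# ---------------------------------------------------------------------------

class IUNet(_FlowBase):
    """Invertible UNet: down path with skips, bottom coupling, up path."""

    def __init__(self, cfg: IUNetConfig | MultiScaleConfig,
                 rng: np.random.Generator | None = None):
        super().__init__(cfg, rng)
        L = cfg.n_scales
        c, h, w = self._entry_shape()
        if c < 2:
            raise ValueError("iUNet needs at least 2 channels after the entry squeeze")
        self.down_steps: list[dict] = []
        self.skip_channels: list[int] = []
        channels = [c]
        for i in range(L - 1):
            step = {"coupling": self._new_coupling(c, i), "mix": self._new_mix(c),
                    "down": _make_downsampler(cfg.downsampling)}
            n_skip = c // 2
            step["n_skip"] = n_skip
            self.skip_channels.append(n_skip)
            c = 4 * (c - n_skip)
            channels.append(c)
            self.down_steps.append(step)
        self.bottom = (self._new_coupling(c, L - 1), self._new_mix(c))
        self.up_steps: list[dict] = []
        for i in range(L - 2, -1, -1):
            c_here = channels[i]  # after concat with the skip
            self.up_steps.append(
                {"level": i, "coupling": self._new_coupling(c_here, i),
                 "mix": self._new_mix(c_here),
                 "up": _make_downsampler(cfg.downsampling)}
            )
        out_c, out_h, out_w = self._entry_shape()
        self.latent_shapes = [self.cfg.input_shape]

    # -- density direction ---------------------------------------------------
    def forward(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        down_c, up_c = _split_cond(cond, self.cfg.n_scales)
        B = x.shape[0]
        logdet = Tensor(np.zeros(B))
        if self.squeeze_input:
            x, _ = self._squeezer.forward(x)
        skips: list[Tensor] = []
        for i, step in enumerate(self.down_steps):
            x, ld = step["coupling"].forward(x, None if down_c is None else down_c[i])
            logdet = logdet + ld
            if step["mix"] is not None:
                x, ld = step["mix"].forward(x)
                logdet = logdet + ld
            n_skip = step["n_skip"]
            skips.append(x[:, :n_skip])
            x, ld = step["down"].forward(x[:, n_skip:])
            logdet = logdet + ld
        coupling, mix = self.bottom
        x, ld = coupling.forward(
            x, None if down_c is None else down_c[self.cfg.n_scales - 1]
        )
        logdet = logdet + ld
        if mix is not None:
            x, ld = mix.forward(x)
            logdet = logdet + ld
        for step in self.up_steps:
            i = step["level"]
            x = step["up"].inverse_t(x)  # invertible upsampling, logdet 0
            x = concatenate([skips[i], x], axis=1)
            x, ld = step["coupling"].forward(x, None if up_c is None else up_c[i])
            logdet = logdet + ld
            if step["mix"] is not None:
                x, ld = step["mix"].forward(x)
                logdet = logdet + ld
        if self.squeeze_input:
            x = self._squeezer.inverse_t(x)
        self._update_monitor()
        return x, logdet

    def forward_vector(self, x: Tensor, cond=None) -> tuple[Tensor, Tensor]:
        z, logdet = self.forward(x, cond)
        return z.reshape(z.shape[0], -1), logdet

    # -- sampling direction ---------------------------------------------------
    def inverse(self, latent, cond=None) -> np.ndarray:
        down_c, up_c = _split_cond(cond, self.cfg.n_scales)
        down_np = None if down_c is None else [f.data for f in down_c]
        up_np = None if up_c is None else [f.data for f in up_c]
        z = np.asarray(latent, dtype=np.float64)
        if z.ndim <= 2:
            z = np.atleast_2d(z).reshape(-1, *self.cfg.input_shape)
        x = z
        if self.squeeze_input:
            x, _ = self._squeezer.forward(Tensor(x))
            x = x.data
        skips: dict[int, np.ndarray] = {}
        for step in reversed(self.up_steps):
            i = step["level"]
            if step["mix"] is not None:
                x = step["mix"].inverse(x)
            x = step["coupling"].inverse(x, None if up_np is None else up_np[i])
            n_skip = self.skip_channels[i]
            skips[i] = x[:, :n_skip]
            x, _ = step["up"].forward(Tensor(x[:, n_skip:]))
            x = x.data
        coupling, mix = self.bottom
        if mix is not None:
            x = mix.inverse(x)
        x = coupling.inverse(
            x, None if down_np is None else down_np[self.cfg.n_scales - 1]
        )
        for i in range(len(self.down_steps) - 1, -1, -1):
            step = self.down_steps[i]
            x = step["down"].inverse(x)
            x = np.concatenate([skips[i], x], axis=1)
            if step["mix"] is not None:
                x = step["mix"].inverse(x)
            x = step["coupling"].inverse(x, None if down_np is None else down_np[i])
        if self.squeeze_input:
            x = self._squeezer.inverse(x)
        return x


def build_flow(cfg: MultiScaleConfig | IUNetConfig, kind: str | None = None,
               rng: np.random.Generator | None = None):
    """Construct a flow from a config; ``kind`` overrides the config class."""
    if kind is None:
        kind = "iunet" if isinstance(cfg, IUNetConfig) else "multiscale"
    if kind == "multiscale":
        return MultiScaleFlow(cfg, rng=rng)
    if kind == "iunet":
        return IUNet(cfg, rng=rng)
    raise ValueError(f"unknown architecture {kind!r}")


# ---------------------------------------------------------------------------
# Functional wrappers (numpy in / numpy out)
# ---------------------------------------------------------------------------

def multiscale_forward(flow: MultiScaleFlow, x: np.ndarray, pyramid=None) -> LatentSplit:
    chunks, logdet = flow.forward(Tensor(np.asarray(x, dtype=np.float64)), pyramid)
    return LatentSplit([c.data for c in chunks], np.atleast_1d(logdet.data))


def multiscale_inverse(flow: MultiScaleFlow, latent, pyramid=None) -> np.ndarray:
    return flow.inverse(latent, pyramid)


def iunet_forward(flow: IUNet, x: np.ndarray, pyramid=None
                  ) -> tuple[np.ndarray, np.ndarray]:
    z, logdet = flow.forward(Tensor(np.asarray(x, dtype=np.float64)), pyramid)
    return z.data, np.atleast_1d(logdet.data)


def iunet_inverse(flow: IUNet, z, pyramid=None) -> np.ndarray:
    return flow.inverse(z, pyramid)
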