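"""Conditioning network: model-based inversion layer + feature pyramid.

Measurements live in spaces whose topology differs sharply from image
space (line integrals for CT, k-space for MRI), which plain CNNs handle
poorly.  The conditioning path therefore starts with a classical, linear
*model-based inversion layer* A-dagger that maps measurements into image
space — the Moore-Penrose pseudo-inverse or a TV-regularized inverse for
compressed sensing, filtered back-projection for CT, the zero-filled
inverse FFT for MRI — followed by a learned feature extractor that emits
one feature array per flow scale (spatial size halving per scale).

Four extractor families are provided, in increasing capacity:

* ``avg_pool`` — one learned convolution to blow up the channel count,
  then average pooling down to each scale;
* ``cnn``      — a fully convolutional stack between poolings;
* ``resnet``   — residual blocks with strided convolutions in place of
  pooling;
* ``unet``     — an encoder-decoder whose per-scale activations condition
  the iUNet's down and up paths and whose final output lives in image
  space (enabling the supervised conditional loss term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


from ._autodiff import Tensor, as_tensor, concatenate, upsample2x
from .nn import Conv2d, LeakyReLU, Module, Sequential, avg_pool2x
from .operators import FourierMasked, LinearForwardModel, RadonTransformModel

__all__ = [
    "InversionLayer",
    "ConditioningPyramid",
    "apply_inversion",
    "build_pyramid",
    "conditioning_head",
    "make_conditioning_net",
    "AvgPoolConditioner",
    "CNNConditioner",
    "ResNetConditioner",
    "UNetConditioner",
    "gradient_operator",
]

_INVERSION_KINDS = ("pseudo_inverse", "tv_regularized", "fbp", "zero_filled_ifft")


def gradient_operator(h: int, w: int) -> sparse.csr_matrix:
    """Discrete 2-D gradient (forward differences, zero-flux boundary),
    stacked as a (2 h w, h w) sparse matrix."""
    n = h * w
    idx = np.arange(n).reshape(h, w)
    rows, cols, vals = [], [], []
    r = 0
    for i in range(h):
        for j in range(w):
            if j + 1 < w:
                rows += [r, r]
                cols += [idx[i, j + 1], idx[i, j]]
                vals += [1.0, -1.0]
            r += 1
    for i in range(h):
        for j in range(w):
            if i + 1 < h:
                rows += [r, r]
                cols += [idx[i + 1, j], idx[i, j]]
                vals += [1.0, -1.0]
            r += 1
    return sparse.coo_matrix((vals, (rows, cols)), shape=(2 * n, n)).tocsr()


@dataclass
class InversionLayer:
    """Linear map A-dagger from measurement space to image space."""

    kind: str
    model: LinearForwardModel
    tv_lambda: float = 0.02
    fbp_cutoff: float = 1.0
    _solver: object = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in _INVERSION_KINDS:
            raise ValueError(f"unknown inversion kind {self.kind!r}")
        if self.kind == "pseudo_inverse":
            if hasattr(self.model, "matrix") and not sparse.issparse(self.model.matrix):
                self._solver = np.linalg.pinv(self.model.matrix)
        elif self.kind == "tv_regularized":
            if not hasattr(self.model, "matrix") or sparse.issparse(self.model.matrix):
                raise ValueError("tv_regularized inversion needs a dense operator matrix")
            A = self.model.matrix
            _, h, w = self.model.domain_shape
            G = gradient_operator(h, w)
            system = A.T @ A + self.tv_lambda * (G.T @ G).toarray()
            from scipy.linalg import lu_factor

            self._solver = (lu_factor(system), A)
        elif self.kind == "fbp" and not isinstance(self.model, RadonTransformModel):
            raise ValueError("fbp inversion requires a Radon forward model")
        elif self.kind == "zero_filled_ifft" and not isinstance(self.model, FourierMasked):
            raise ValueError("zero_filled_ifft requires a masked Fourier model")

    def apply(self, y: np.ndarray) -> np.ndarray:
        """Image batch of shape (B, c, h, w)."""
        y = np.asarray(y)
        if self.kind == "pseudo_inverse":
            if self._solver is not None:
                single = y.ndim == 1
                x = np.atleast_2d(y) @ np.asarray(self._solver).T
                x = x.reshape(-1, *self.model.domain_shape)
                return x if not single else x
            # fall back: adjoint of a (sub)unitary operator is its pseudo-inverse
            x = self.model.adjoint(y)
            return x.reshape(-1, *self.model.domain_shape)
        if self.kind == "tv_regularized":
            from scipy.linalg import lu_solve

            lu, A = self._solver
            rhs = np.atleast_2d(y) @ A
            x = lu_solve(lu, rhs.T).T
            return x.reshape(-1, *self.model.domain_shape)
        if self.kind == "fbp":
            rec = self.model.fbp(y, cutoff=self.fbp_cutoff)
            return rec.reshape(-1, *self.model.domain_shape)
        # zero-filled inverse FFT, magnitude image
        rec = self.model.zero_filled(y)
        return rec.reshape(-1, *self.model.domain_shape)


def apply_inversion(y: np.ndarray, layer: InversionLayer) -> np.ndarray:
    return layer.apply(y)


def default_inversion(model: LinearForwardModel) -> InversionLayer:
    """The paper-style default A-dagger for each operator family."""
    if isinstance(model, RadonTransformModel):
        return InversionLayer("fbp", model)
    if isinstance(model, FourierMasked):
        return InversionLayer("zero_filled_ifft", model)
    return InversionLayer("tv_regularized", model)


# ---------------------------------------------------------------------------
# Feature pyramids
# ---------------------------------------------------------------------------

@dataclass
class ConditioningPyramid:
    """One feature tensor per flow scale (spatial sizes halving), plus, for
    the UNet variant, separate down/up-path features and an image-space
    head output."""

    features: list
    source: str
    up_features: list | None = None
    head: Tensor | None = None

    def as_cond(self):
        if self.up_features is not None:
            return (list(self.features), list(self.up_features))
        return list(self.features)

    def detached(self):
        feats = [Tensor(f.data if isinstance(f, Tensor) else f) for f in self.features]
        ups = None
        if self.up_features is not None:
            ups = [Tensor(f.data if isinstance(f, Tensor) else f) for f in self.up_features]
        return ConditioningPyramid(feats, self.source, ups, None)


class _Conditioner(Module):
    """Base: maps a reconstruction batch to per-scale features.

    ``shapes`` lists the (channels, h, w) each flow scale expects; the
    input reconstruction may sit one halving above the first scale (flows
    with an entry squeeze), handled by an extra rearrangement step.

    Unless disabled, a fixed *reconstruction bypass* is prepended to the
    learned features at every scale: the inversion-layer output itself,
    checkerboard-rearranged to the first scale's resolution and then
    average-pooled down the pyramid.  The learned path then only has to
    model what the classical reconstruction misses, which speeds up
    conditional training considerably.
    """

    source = "base"

    def __init__(self, in_shape: tuple[int, int, int],
                 shapes: list[tuple[int, int, int]],
                 rng: np.random.Generator | None = None,
                 bypass: bool = True):
        self.in_shape = in_shape
        self.shapes = list(shapes)
        self.rng = rng or np.random.default_rng(0)
        c, h, w = in_shape
        h0 = shapes[0][1]
        if h % h0:
            raise ValueError("input size must be a multiple of the first scale size")
        self.pre_pools = int(np.log2(h // h0))
        for lvl in range(1, len(shapes)):
            if shapes[lvl][1] * 2 != shapes[lvl - 1][1]:
                raise ValueError("pyramid spatial sizes must halve per scale")
        self.bypass_channels = c * 4**self.pre_pools if bypass else 0
        if any(s[0] <= self.bypass_channels for s in shapes):
            raise ValueError(
                f"cond channels must exceed the {self.bypass_channels} "
                "reconstruction-bypass channels (or disable the bypass)"
            )
        self.learned_channels = [s[0] - self.bypass_channels for s in shapes]

    def _bypass_features(self, recon: Tensor) -> list[Tensor] | None:
        if not self.bypass_channels:
            return None
        from .layers import CheckerboardDownsample

        x = recon
        squeezer = CheckerboardDownsample()
        for _ in range(self.pre_pools):
            x, _ = squeezer.forward(x)
        feats = [x]
        for _ in range(len(self.shapes) - 1):
            x = avg_pool2x(x)
            feats.append(x)
        return feats

    def _assemble(self, recon: Tensor, learned: list[Tensor]) -> list[Tensor]:
        bypass = self._bypass_features(recon)
        if bypass is None:
            return learned
        return [concatenate([b, f], axis=1) for b, f in zip(bypass, learned)]

    def forward(self, recon: Tensor) -> ConditioningPyramid:
        raise NotImplementedError


class AvgPoolConditioner(_Conditioner):
    """One learned convolution, then average pooling to every scale; each
    scale takes a fixed channel slice of the blown-up features."""

    source = "avg_pool"

    def __init__(self, in_shape, shapes, rng=None, bypass=True):
        super().__init__(in_shape, shapes, rng, bypass)
        width = max(self.learned_channels)
        self.conv = Conv2d(in_shape[0], width, 3, rng=self.rng)

    def forward(self, recon: Tensor) -> ConditioningPyramid:
        recon = as_tensor(recon)
        x = self.conv(recon).leaky_relu(0.1)
        for _ in range(self.pre_pools):
            x = avg_pool2x(x)
        feats = []
        for lvl, ch in enumerate(self.learned_channels):
            feats.append(x[:, :ch])
            if lvl + 1 < len(self.shapes):
                x = avg_pool2x(x)
        return ConditioningPyramid(self._assemble(recon, feats), self.source)


class CNNConditioner(_Conditioner):
    """Fully convolutional stack: conv-relu-conv between poolings."""

    source = "cnn"

    def __init__(self, in_shape, shapes, rng=None, bypass=True, hidden: int = 32):
        super().__init__(in_shape, shapes, rng, bypass)
        self.stages = []
        c = in_shape[0]
        for ch in self.learned_channels:
            self.stages.append(
                Sequential(
                    Conv2d(c, hidden, 3, rng=self.rng), LeakyReLU(),
                    Conv2d(hidden, ch, 3, rng=self.rng),
                )
            )
            c = ch
        self.stages = list(self.stages)

    def forward(self, recon: Tensor) -> ConditioningPyramid:
        recon = as_tensor(recon)
        x = recon
        for _ in range(self.pre_pools):
            x = avg_pool2x(x)
        feats = []
        for i, stage in enumerate(self.stages):
            x = stage(x).leaky_relu(0.1)
            feats.append(x)
            if i + 1 < len(self.stages):
                x = avg_pool2x(x)
        return ConditioningPyramid(self._assemble(recon, feats), self.source)


class _ResBlock(Module):
    def __init__(self, c: int, hidden: int, rng):
        self.conv1 = Conv2d(c, hidden, 3, rng=rng)
        self.conv2 = Conv2d(hidden, c, 3, rng=rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).leaky_relu(0.1))


class ResNetConditioner(_Conditioner):
    """Residual blocks; strided convolutions replace the pooling steps."""

    source = "resnet"

    def __init__(self, in_shape, shapes, rng=None, bypass=True,
                 hidden: int = 48, blocks: int = 2):
        super().__init__(in_shape, shapes, rng, bypass)
        lc = self.learned_channels
        self.entry = Conv2d(in_shape[0], lc[0], 3, rng=self.rng)
        self.pre_strides = [
            Conv2d(lc[0], lc[0], 3, stride=2, rng=self.rng)
            for _ in range(self.pre_pools)
        ]
        self.stages, self.strides = [], []
        for lvl, ch in enumerate(lc):
            self.stages.append([_ResBlock(ch, hidden, self.rng) for _ in range(blocks)])
            if lvl + 1 < len(lc):
                self.strides.append(Conv2d(ch, lc[lvl + 1], 3, stride=2, rng=self.rng))

    def forward(self, recon: Tensor) -> ConditioningPyramid:
        recon = as_tensor(recon)
        x = self.entry(recon).leaky_relu(0.1)
        for conv in self.pre_strides:
            x = conv(x).leaky_relu(0.1)
        feats = []
        for lvl, blocks in enumerate(self.stages):
            for block in blocks:
                x = block(x)
            feats.append(x)
            if lvl < len(self.strides):
                x = self.strides[lvl](x).leaky_relu(0.1)
        return ConditioningPyramid(self._assemble(recon, feats), self.source)


class UNetConditioner(_Conditioner):
    """Encoder-decoder producing encoder features (flow down path), decoder
    features (flow up path) and an image-space head output."""

    source = "unet"

    def __init__(self, in_shape, shapes, rng=None, bypass=True, hidden: int = 32):
        super().__init__(in_shape, shapes, rng, bypass)
        lc = self.learned_channels
        L = len(shapes)
        self.enc_convs, self.dec_convs = [], []
        c = in_shape[0]
        for ch in lc:
            self.enc_convs.append(
                Sequential(Conv2d(c, ch, 3, rng=self.rng), LeakyReLU(),
                           Conv2d(ch, ch, 3, rng=self.rng), LeakyReLU())
            )
            c = ch
        for lvl in range(L - 2, -1, -1):
            ch = lc[lvl]
            c_in = lc[lvl + 1] + ch  # upsampled deeper features + skip
            self.dec_convs.append(
                Sequential(Conv2d(c_in, ch, 3, rng=self.rng), LeakyReLU(),
                           Conv2d(ch, ch, 3, rng=self.rng), LeakyReLU())
            )
        self.head_conv = Conv2d(lc[0], in_shape[0], 3, rng=self.rng,
                                zero_init=True)
        self.head_upsamples = self.pre_pools

    def forward(self, recon: Tensor) -> ConditioningPyramid:
        recon = as_tensor(recon)
        x = recon
        for _ in range(self.pre_pools):
            x = avg_pool2x(x)
        enc = []
        for i, conv in enumerate(self.enc_convs):
            x = conv(x)
            enc.append(x)
            if i + 1 < len(self.enc_convs):
                x = avg_pool2x(x)
        dec = [enc[-1]]
        x = enc[-1]
        for k, conv in enumerate(self.dec_convs):
            lvl = len(self.enc_convs) - 2 - k
            x = conv(concatenate([upsample2x(x), enc[lvl]], axis=1))
            dec.append(x)
        dec = dec[::-1]  # index by scale level
        head = self.head_conv(dec[0])
        for _ in range(self.head_upsamples):
            head = upsample2x(head)
        return ConditioningPyramid(features=self._assemble(recon, enc),
                                   source=self.source,
                                   up_features=self._assemble(recon, dec),
                                   head=head)


_CONDITIONERS = {
    "avg_pool": AvgPoolConditioner,
    "cnn": CNNConditioner,
    "resnet": ResNetConditioner,
    "unet": UNetConditioner,
}


def make_conditioning_net(net_kind: str, in_shape, shapes, rng=None, **kwargs):
    if net_kind not in _CONDITIONERS:
        raise ValueError(f"unknown conditioning network {net_kind!r}")
    return _CONDITIONERS[net_kind](in_shape, shapes, rng=rng, **kwargs)


def build_pyramid(recon: np.ndarray, net_kind: str, L: int,
                  cond_channels: int | list[int] = 32,
                  rng: np.random.Generator | None = None,
                  net: _Conditioner | None = None) -> ConditioningPyramid:
    """Feature pyramid with L scales from a reconstruction batch."""
    recon = np.asarray(recon, dtype=np.float64)
    if recon.ndim == 3:
        recon = recon[:, None]
    _, c, h, w = recon.shape
    if h % 2 ** (L - 1) or w % 2 ** (L - 1):
        raise ValueError(f"spatial size {h}x{w} not divisible by 2^{L - 1}")
    if net is None:
        chs = [cond_channels] * L if isinstance(cond_channels, int) else list(cond_channels)
        shapes = [(chs[i], h // 2**i, w // 2**i) for i in range(L)]
        net = make_conditioning_net(net_kind, (c, h, w), shapes, rng=rng)
    return net(Tensor(recon))


def conditioning_head(pyramid: ConditioningPyramid) -> np.ndarray:
    """Image-space output H(y) of the UNet conditioner (used by the
    supervised conditional-loss term)."""
    if pyramid.source != "unet" or pyramid.head is None:
        raise ValueError("only the unet conditioning variant has an image-space head")
    return pyramid.head.data
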