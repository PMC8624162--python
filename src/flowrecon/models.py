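"""The conditional invertible neural network (cINN) model.

Couples an invertible flow T (multi-scale or iUNet), a latent base
density p_z (standard normal or radial Gaussian), and a conditioning path
(model-based inversion layer + feature-extractor network) into a single
conditional density model

    log p(x | y) = log p_z(T^{-1}(x; H(y))) + log |det J_{T^{-1}}(x; H(y))|

trained by maximum likelihood and sampled by pushing base draws through T.
"""

from __future__ import annotations

import json

import numpy as np

from ._autodiff import Tensor
from .architectures import IUNet, IUNetConfig, MultiScaleConfig, build_flow
from .base_dists import BaseDistribution, make_base
from .conditioning import ConditioningPyramid, InversionLayer, make_conditioning_net
from .nn import Module

__all__ = ["CINNModel", "save_checkpoint", "load_checkpoint"]


class CINNModel(Module):
    """Conditional flow + base distribution + conditioning path.

    An optional input-normalization stage (set once from training-data
    statistics via :meth:`set_input_stats`) maps images to roughly unit
    scale before the flow; it is a fixed elementwise affine map whose
    log-determinant, ``-sum(log std)``, is accounted exactly.
    """

    def __init__(self, flow, base: BaseDistribution,
                 cond_net=None, inversion: InversionLayer | None = None,
                 freeze_conditioning: bool = False):
        if base.n != flow.n_latent:
            raise ValueError(
                f"base dimension {base.n} != flow latent size {flow.n_latent}"
            )
        self.flow = flow
        self.base = base
        self.cond_net = cond_net
        self.inversion = inversion
        self.freeze_conditioning = freeze_conditioning
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

    # -- input normalization ---------------------------------------------------
    def set_input_stats(self, images: np.ndarray, min_std: float = 1e-2) -> None:
        """Freeze per-pixel normalization statistics from a training stack."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[:, None]
        self.input_mean = images.mean(axis=0)
        self.input_std = np.maximum(images.std(axis=0), min_std)

    def _norm_logdet(self) -> float:
        if self.input_std is None:
            return 0.0
        return float(-np.sum(np.log(self.input_std)))

    # -- conditioning ---------------------------------------------------------
    def condition(self, y: np.ndarray | None,
                  with_grad: bool = True) -> ConditioningPyramid | None:
        """Measurements -> inversion layer -> feature pyramid."""
        if self.cond_net is None:
            return None
        if y is None:
            raise ValueError("model is conditional but no measurements given")
        recon = self.inversion.apply(y) if self.inversion is not None else np.asarray(y)
        if recon.ndim == 3:
            recon = recon[:, None]
        pyramid = self.cond_net(Tensor(np.asarray(recon, dtype=np.float64)))
        if not with_grad or self.freeze_conditioning:
            pyramid = ConditioningPyramid(
                features=[Tensor(f.data) for f in pyramid.features],
                source=pyramid.source,
                up_features=None if pyramid.up_features is None else
                [Tensor(f.data) for f in pyramid.up_features],
                head=pyramid.head,
            )
        return pyramid

    def trainable_parameters(self):
        params = self.flow.parameters()
        if self.cond_net is not None and not self.freeze_conditioning:
            params = params + self.cond_net.parameters()
        return params

    # -- density direction ----------------------------------------------------
    def forward_vector(self, x: Tensor, pyramid: ConditioningPyramid | None
                       ) -> tuple[Tensor, Tensor]:
        cond = None if pyramid is None else pyramid.as_cond()
        if self.input_mean is not None:
            x = (x - Tensor(self.input_mean)) * Tensor(1.0 / self.input_std)
        z, logdet = self.flow.forward_vector(x, cond)
        if self.input_mean is not None:
            logdet = logdet + self._norm_logdet()
        return z, logdet

    def log_prob_t(self, x: Tensor, pyramid: ConditioningPyramid | None) -> Tensor:
        z, logdet = self.forward_vector(x, pyramid)
        return self.base.log_prob_t(z) + logdet

    def log_prob(self, x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        pyramid = self.condition(y, with_grad=False)
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        return self.log_prob_t(Tensor(x), pyramid).data

    # -- sampling direction ---------------------------------------------------
    def _ensure_batch_y(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        if self.inversion is not None:
            rs = tuple(self.inversion.model.range_shape)
        elif self.cond_net is not None:
            rs = tuple(self.cond_net.in_shape)
        else:
            return y
        if y.shape == rs or (len(rs) > 1 and y.shape == rs[1:]):
            y = y[None]
        return y

    def sample(self, y: np.ndarray | None, n_samples: int,
               rng: np.random.Generator) -> np.ndarray:
        """Posterior samples x_i = T(z_i; H(y)) for a single measurement y."""
        pyramid = None
        if self.cond_net is not None:
            yb = self._ensure_batch_y(y)
            if yb.shape[0] != 1:
                raise ValueError("sample() draws from the posterior of one y")
            pyramid = self.condition(yb, with_grad=False)
        z = self.base.sample(n_samples, rng)
        cond = None
        if pyramid is not None:
            cond = _tile_cond(pyramid.as_cond(), n_samples)
        x = self.flow.inverse(z, cond)
        if self.input_mean is not None:
            x = x * self.input_std + self.input_mean
        return x

    def n_parameters(self) -> int:
        n = self.flow.n_parameters()
        if self.cond_net is not None:
            n += self.cond_net.n_parameters()
        return n


def _tile_cond(cond, n: int):
    if isinstance(cond, tuple):
        return (_tile_list(cond[0], n), _tile_list(cond[1], n))
    return _tile_list(cond, n)


def _tile_list(features, n: int):
    out = []
    for f in features:
        data = f.data if isinstance(f, Tensor) else np.asarray(f)
        if data.shape[0] == 1:
            data = np.repeat(data, n, axis=0)
        elif data.shape[0] != n:
            raise ValueError("conditioning batch does not match sample count")
        out.append(Tensor(data))
    return out


# ---------------------------------------------------------------------------
# Checkpoints: one .npz archive holding config (JSON) + weights.
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str, model: CINNModel, extra: dict | None = None) -> None:
    """Single-archive checkpoint: structured config + all weight arrays.

    The inversion layer and forward operator are *not* serialized (they are
    data-dependent); supply them again via ``load_checkpoint``.
    """
    cfg = model.flow.cfg
    config = {
        "version": CHECKPOINT_VERSION,
        "arch": "iunet" if isinstance(model.flow, IUNet) else "multiscale",
        "flow_cfg": {
            "input_shape": list(cfg.input_shape),
            "n_scales": cfg.n_scales,
            "blocks_per_scale": cfg.blocks_per_scale,
            "coupling": cfg.coupling,
            "downsampling": cfg.downsampling,
            "clamp": cfg.clamp,
            "hidden_width": cfg.hidden_width,
            "kernel": cfg.kernel,
            "mixing": cfg.mixing,
            "cond_channels": cfg.cond_channels,
            "split_fraction": cfg.split_fraction,
            "initial_squeeze": cfg.initial_squeeze,
        },
        "base": model.base.kind,
        "cond_net": None,
        "extra": extra or {},
    }
    arrays = {}
    if model.input_mean is not None:
        arrays["input_mean"] = model.input_mean
        arrays["input_std"] = model.input_std
    for i, p in enumerate(model.flow.parameters()):
        arrays[f"flow_{i}"] = p.data
    # fixed mixing matrices are part of the architecture state
    mix_arrays = _collect_mixing(model.flow)
    for i, q in enumerate(mix_arrays):
        arrays[f"mix_{i}"] = q
    if model.cond_net is not None:
        config["cond_net"] = {
            "kind": model.cond_net.source,
            "in_shape": list(model.cond_net.in_shape),
            "shapes": [list(s) for s in model.cond_net.shapes],
            "bypass": model.cond_net.bypass_channels > 0,
        }
        for i, p in enumerate(model.cond_net.parameters()):
            arrays[f"cond_{i}"] = p.data
    np.savez(path, config=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8),
             **arrays)


def _collect_mixing(flow) -> list[np.ndarray]:
    from .layers import MixChannels

    out = []
    seen = set()
    stack = [flow]
    while stack:
        obj = stack.pop()
        if id(obj) in seen:
            continue
        seen.add(id(obj))
        if isinstance(obj, MixChannels):
            out.append(obj.q)
        elif isinstance(obj, Module):
            stack.extend(v for v in vars(obj).values()
                         if isinstance(v, (Module, list, tuple, dict)))
        elif isinstance(obj, dict):
            stack.extend(obj.values())
        elif isinstance(obj, (list, tuple)):
            stack.extend(obj)
    return out


def _restore_mixing(flow, arrays: list[np.ndarray]) -> None:
    from .layers import MixChannels

    idx = 0
    seen = set()
    stack = [flow]
    while stack:
        obj = stack.pop()
        if id(obj) in seen:
            continue
        seen.add(id(obj))
        if isinstance(obj, MixChannels):
            obj.q = arrays[idx]
            obj.q_inv = np.linalg.inv(arrays[idx])
            sign, lad = np.linalg.slogdet(arrays[idx])
            obj.logabsdet = float(lad)
            idx += 1
        elif isinstance(obj, Module):
            stack.extend(v for v in vars(obj).values()
                         if isinstance(v, (Module, list, tuple, dict)))
        elif isinstance(obj, dict):
            stack.extend(obj.values())
        elif isinstance(obj, (list, tuple)):
            stack.extend(obj)


def load_checkpoint(path: str, inversion: InversionLayer | None = None) -> CINNModel:
    with np.load(path) as data:
        config = json.loads(bytes(data["config"]).decode())
        if config["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {config['version']}")
        fc = config["flow_cfg"]
        cls = IUNetConfig if config["arch"] == "iunet" else MultiScaleConfig
        cond_ch = fc["cond_channels"]
        cfg = cls(
            input_shape=tuple(fc["input_shape"]), n_scales=fc["n_scales"],
            blocks_per_scale=fc["blocks_per_scale"], coupling=fc["coupling"],
            downsampling=fc["downsampling"], clamp=fc["clamp"],
            hidden_width=fc["hidden_width"], kernel=fc["kernel"],
            mixing=fc["mixing"],
            cond_channels=tuple(cond_ch) if isinstance(cond_ch, list) else cond_ch,
            split_fraction=fc["split_fraction"],
            initial_squeeze=fc["initial_squeeze"],
        )
        flow = build_flow(cfg, kind=config["arch"])
        flow_arrays = [data[f"flow_{i}"] for i in range(len(flow.parameters()))]
        flow.load_state_arrays(flow_arrays)
        mix_arrays = []
        i = 0
        while f"mix_{i}" in data:
            mix_arrays.append(data[f"mix_{i}"])
            i += 1
        _restore_mixing(flow, mix_arrays)
        cond_net = None
        if config["cond_net"] is not None:
            cn = config["cond_net"]
            cond_net = make_conditioning_net(
                cn["kind"], tuple(cn["in_shape"]), [tuple(s) for s in cn["shapes"]],
                bypass=cn.get("bypass", True),
            )
            cond_arrays = [data[f"cond_{i}"] for i in range(len(cond_net.parameters()))]
            cond_net.load_state_arrays(cond_arrays)
        base = make_base(config["base"], flow.n_latent)
        model = CINNModel(flow, base, cond_net=cond_net, inversion=inversion)
        if "input_mean" in data:
            model.input_mean = data["input_mean"]
            model.input_std = data["input_std"]
        return model
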