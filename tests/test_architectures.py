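"""Multi-scale flow and invertible UNet: bijectivity, logdet oracle,
dimension conservation, conditioning contracts, checkpoints."""

import numpy as np
import pytest

from flowrecon._autodiff import Tensor
from flowrecon.architectures import (
    IUNet,
    IUNetConfig,
    LatentSplit,
    MultiScaleConfig,
    MultiScaleFlow,
    build_flow,
    iunet_forward,
    iunet_inverse,
    multiscale_forward,
    multiscale_inverse,
)
from flowrecon.models import CINNModel, load_checkpoint, save_checkpoint
from flowrecon.base_dists import make_base

from conftest import fd_slogdet


def _perturb(flow, rng, scale=0.05):
    for p in flow.parameters():
        p.data = p.data + scale * rng.standard_normal(p.data.shape)
    return flow


def _random_pyramid(flow, batch, rng):
    return [rng.normal(size=(batch, c, h, w)) for c, h, w in flow.cond_shapes()]


@pytest.mark.parametrize("arch,cfg_cls", [("multiscale", MultiScaleConfig),
                                          ("iunet", IUNetConfig)])
@pytest.mark.parametrize("downsampling", ["checkerboard", "haar"])
def test_roundtrip_random_weights(arch, cfg_cls, downsampling, rng):
    cfg = cfg_cls(input_shape=(1, 8, 8), n_scales=2, hidden_width=8,
                  downsampling=downsampling)
    flow = _perturb(build_flow(cfg, kind=arch), rng)
    x = rng.normal(size=(4, 1, 8, 8))
    z, _ = flow.forward_vector(Tensor(x))
    x_rec = flow.inverse(z.data)
    assert np.abs(x_rec - x).max() < 1e-10


def test_iunet_additive_couplings_zero_logdet_and_tight_roundtrip(rng):
    cfg = IUNetConfig(input_shape=(1, 8, 8), n_scales=2, hidden_width=8)
    assert cfg.coupling == "additive"
    flow = _perturb(build_flow(cfg, kind="iunet"), rng)
    x = rng.normal(size=(2, 1, 8, 8))
    z, logdet = flow.forward_vector(Tensor(x))
    np.testing.assert_allclose(logdet.data, 0.0, atol=1e-10)
    assert np.abs(flow.inverse(z.data) - x).max() < 1e-10
    assert flow.max_abs_scale_ == 0.0  # stability monitor: additive => 0


@pytest.mark.parametrize("arch", ["multiscale", "iunet"])
def test_logdet_matches_full_jacobian_oracle(arch, rng):
    cfg_cls = IUNetConfig if arch == "iunet" else MultiScaleConfig
    cfg = cfg_cls(input_shape=(1, 8, 8), n_scales=2, hidden_width=6,
                  coupling="affine")
    flow = _perturb(build_flow(cfg, kind=arch), rng)
    x0 = rng.normal(size=(1, 1, 8, 8))
    _, logdet = flow.forward_vector(Tensor(x0))

    def f(v):
        z, _ = flow.forward_vector(Tensor(v.reshape(1, 1, 8, 8)))
        return z.data

    oracle = fd_slogdet(f, x0)
    assert logdet.data[0] == pytest.approx(oracle, rel=1e-4, abs=1e-6)


@pytest.mark.parametrize("arch", ["multiscale", "iunet"])
def test_conditional_logdet_matches_oracle_and_roundtrip(arch, rng):
    cfg_cls = IUNetConfig if arch == "iunet" else MultiScaleConfig
    cfg = cfg_cls(input_shape=(1, 8, 8), n_scales=2, hidden_width=6,
                  coupling="affine", cond_channels=3)
    flow = _perturb(build_flow(cfg, kind=arch), rng)
    pyramid = _random_pyramid(flow, 1, rng)
    x0 = rng.normal(size=(1, 1, 8, 8))
    z, logdet = flow.forward_vector(Tensor(x0), pyramid)
    assert np.abs(flow.inverse(z.data, pyramid) - x0).max() < 1e-8

    def f(v):
        zz, _ = flow.forward_vector(Tensor(v.reshape(1, 1, 8, 8)), pyramid)
        return zz.data

    assert logdet.data[0] == pytest.approx(fd_slogdet(f, x0), rel=1e-4, abs=1e-6)


def test_identity_initialization_is_a_permutation(rng):
    # zero-initialized subnets + permutation mixing: z is a permutation of x
    cfg = MultiScaleConfig(input_shape=(1, 8, 8), n_scales=2, hidden_width=4,
                           mixing="permutation")
    flow = build_flow(cfg, kind="multiscale", rng=rng)
    x = rng.normal(size=(1, 1, 8, 8))
    z, logdet = flow.forward_vector(Tensor(x))
    np.testing.assert_array_equal(np.sort(z.data.ravel()), np.sort(x.ravel()))
    np.testing.assert_array_equal(logdet.data, [0.0])
    # the inverse of the identity-initialized network is the exact
    # inverse permutation
    np.testing.assert_array_equal(flow.inverse(z.data), x)


def test_iunet_identity_initialization_is_a_permutation(rng):
    cfg = IUNetConfig(input_shape=(1, 8, 8), n_scales=2, hidden_width=4,
                      mixing="permutation")
    flow = build_flow(cfg, kind="iunet", rng=rng)
    x = rng.normal(size=(1, 1, 8, 8))
    z, logdet = flow.forward_vector(Tensor(x))
    np.testing.assert_array_equal(np.sort(z.data.ravel()), np.sort(x.ravel()))
    np.testing.assert_array_equal(logdet.data, [0.0])


@pytest.mark.parametrize("L", [1, 2])
def test_latent_element_count_conserved(L, rng):
    cfg = MultiScaleConfig(input_shape=(1, 8, 8), n_scales=L, hidden_width=4)
    flow = build_flow(cfg, kind="multiscale")
    chunks, _ = flow.forward(Tensor(rng.normal(size=(2, 1, 8, 8))))
    assert sum(c.data[0].size for c in chunks) == 64
    assert [c.data.shape[1:] for c in chunks] == [tuple(s) for s in flow.latent_shapes]


def test_latent_vector_serialization_roundtrip(rng):
    cfg = MultiScaleConfig(input_shape=(1, 8, 8), n_scales=2, hidden_width=4)
    flow = _perturb(build_flow(cfg, kind="multiscale"), rng)
    x = rng.normal(size=(3, 1, 8, 8))
    split = multiscale_forward(flow, x)
    vec = split.to_vector()
    assert vec.shape == (3, 64)
    chunks = LatentSplit.vector_to_chunks(vec, flow.latent_shapes)
    for a, b in zip(chunks, split.chunks):
        np.testing.assert_array_equal(a, b)
    np.testing.assert_allclose(multiscale_inverse(flow, split), x, atol=1e-10)


def test_sampling_deterministic_given_seed(rng):
    cfg = MultiScaleConfig(input_shape=(1, 8, 8), n_scales=2, hidden_width=4)
    flow = _perturb(build_flow(cfg, kind="multiscale"), rng)
    base = make_base("normal", 64)
    z1 = base.sample(5, np.random.default_rng(3))
    z2 = base.sample(5, np.random.default_rng(3))
    np.testing.assert_array_equal(flow.inverse(z1), flow.inverse(z2))


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        MultiScaleConfig(input_shape=(1, 6, 6), n_scales=3)
    with pytest.raises(ValueError, match="scale"):
        MultiScaleConfig(input_shape=(1, 8, 8), n_scales=0)
    with pytest.raises(ValueError, match="downsampling"):
        MultiScaleConfig(input_shape=(1, 8, 8), downsampling="strided")


def test_pyramid_level_count_enforced(rng):
    cfg = MultiScaleConfig(input_shape=(1, 8, 8), n_scales=2, hidden_width=4,
                           cond_channels=2)
    flow = build_flow(cfg, kind="multiscale", rng=rng)
    bad_pyramid = _random_pyramid(flow, 1, rng)[:1]
    with pytest.raises(ValueError, match="levels"):
        flow.forward(Tensor(rng.normal(size=(1, 1, 8, 8))), bad_pyramid)


def test_functional_iunet_wrappers(rng):
    cfg = IUNetConfig(input_shape=(1, 4, 4), n_scales=1, hidden_width=4)
    flow = _perturb(build_flow(cfg, kind="iunet"), rng)
    x = rng.normal(size=(2, 1, 4, 4))
    z, logdet = iunet_forward(flow, x)
    assert z.shape == x.shape and logdet.shape == (2,)
    np.testing.assert_allclose(iunet_inverse(flow, z), x, atol=1e-10)


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = MultiScaleConfig(input_shape=(1, 8, 8), n_scales=2, hidden_width=6,
                           cond_channels=8)
    flow = _perturb(build_flow(cfg, kind="multiscale", rng=rng), rng)
    from flowrecon.conditioning import make_conditioning_net

    cond = make_conditioning_net("cnn", (1, 8, 8), flow.cond_shapes(), rng=rng)
    model = CINNModel(flow, make_base("radial", 64), cond_net=cond)
    path = str(tmp_path / "ckpt.npz")
    save_checkpoint(path, model)
    restored = load_checkpoint(path)
    x = rng.normal(size=(2, 1, 8, 8))
    recon = rng.normal(size=(2, 1, 8, 8))
    p1 = model.cond_net(Tensor(recon))
    p2 = restored.cond_net(Tensor(recon))
    z1, ld1 = model.forward_vector(Tensor(x), p1)
    z2, ld2 = restored.forward_vector(Tensor(x), p2)
    np.testing.assert_array_equal(z1.data, z2.data)
    np.testing.assert_array_equal(ld1.data, ld2.data)
    assert restored.base.kind == "radial"
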