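"""Training loss correctness and optimization behaviour."""

import numpy as np
import pytest

from flowrecon._autodiff import Tensor
from flowrecon.architectures import MultiScaleConfig, build_flow
from flowrecon.base_dists import StandardNormal, make_base
from flowrecon.conditioning import InversionLayer, make_conditioning_net
from flowrecon.models import CINNModel
from flowrecon.operators import NoiseSpec, SyntheticDataset, make_gaussian_cs
from flowrecon.training import TrainConfig, nll_loss, total_loss, train

from conftest import fd_slogdet


def test_nll_identity_flow_closed_form():
    # identity flow (logdet 0), normal base, x = 0, n = 16: NLL = 8 ln(2 pi)
    base = StandardNormal(16)
    z = np.zeros((3, 16))
    out = nll_loss(z, np.zeros(3), base)
    np.testing.assert_allclose(out.data, 8 * np.log(2 * np.pi), rtol=1e-12)


def test_nll_matches_brute_force_change_of_variables(rng):
    """Loss equals -ln p computed with the finite-difference Jacobian."""
    cfg = MultiScaleConfig(input_shape=(1, 4, 4), n_scales=1, hidden_width=6,
                           coupling="affine")
    flow = build_flow(cfg, kind="multiscale", rng=rng)
    for p in flow.parameters():
        p.data = p.data + 0.1 * rng.standard_normal(p.data.shape)
    base = make_base("normal", 16)
    x0 = rng.normal(size=(1, 1, 4, 4))
    z, logdet = flow.forward_vector(Tensor(x0))
    loss = nll_loss(z, logdet, base).data[0]

    def f(v):
        zz, _ = flow.forward_vector(Tensor(v.reshape(1, 1, 4, 4)))
        return zz.data

    brute = -(base.log_prob(f(x0.ravel()))[0] + fd_slogdet(f, x0))
    assert loss == pytest.approx(brute, rel=1e-6)


def test_constant_logdet_shifts_loss_exactly(rng):
    base = StandardNormal(8)
    z = rng.normal(size=(5, 8))
    base_loss = nll_loss(z, np.zeros(5), base).data
    shifted = nll_loss(z, np.full(5, 1.7), base).data
    np.testing.assert_allclose(shifted, base_loss - 1.7, rtol=1e-12)


def test_nll_raises_on_nonfinite_latents():
    with pytest.raises(FloatingPointError):
        nll_loss(np.full((1, 4), np.nan), np.zeros(1), StandardNormal(4))


def _tiny_conditional_model(rng, conditioning="cnn", alpha=0.0):
    model_fwd = make_gaussian_cs(64, 256, seed=0)
    cfg = MultiScaleConfig(input_shape=(1, 16, 16), n_scales=2, hidden_width=8,
                           cond_channels=8)
    flow = build_flow(cfg, kind="multiscale", rng=rng)
    cond = make_conditioning_net(conditioning, (1, 16, 16), flow.cond_shapes(),
                                 rng=rng)
    inv = InversionLayer("pseudo_inverse", model_fwd)
    model = CINNModel(flow, make_base("normal", 256), cond_net=cond, inversion=inv)
    return model, model_fwd


def test_total_loss_alpha_zero_equals_nll(rng):
    model, fwd = _tiny_conditional_model(rng)
    data = SyntheticDataset.generate(fwd, 4, seed=3)
    loss, nll, mse = total_loss(data.images, data.measurements, model,
                                TrainConfig(alpha=0.0))
    assert mse is None
    assert loss.data == pytest.approx(nll.data, rel=1e-12)


def test_total_loss_alpha_requires_unet_head(rng):
    model, fwd = _tiny_conditional_model(rng, conditioning="cnn")
    data = SyntheticDataset.generate(fwd, 2, seed=3)
    with pytest.raises(ValueError, match="unet"):
        total_loss(data.images, data.measurements, model, TrainConfig(alpha=1.0))


def test_total_loss_perfect_head_adds_zero(rng):
    model, fwd = _tiny_conditional_model(rng, conditioning="unet")
    data = SyntheticDataset.generate(fwd, 2, seed=3)
    cfg = TrainConfig(alpha=1.0)
    loss, nll, mse = total_loss(data.images, data.measurements, model, cfg)
    # zero-initialized head: MSE term equals mean x^2; with alpha weighting
    expected_mse = float(np.mean(np.asarray(data.images) ** 2))
    assert mse.data == pytest.approx(expected_mse, rel=1e-10)
    assert loss.data == pytest.approx(nll.data + expected_mse, rel=1e-10)


def test_conditioning_head_learns_reconstruction_under_large_alpha(rng):
    """With a heavily weighted conditional loss, the UNet head output
    approaches the training images in MSE on an overfit single batch."""
    from flowrecon.nn import Adam

    model, fwd = _tiny_conditional_model(rng, conditioning="unet")
    data = SyntheticDataset.generate(fwd, 4, seed=9, phantom_kind="digits_like")
    cfg = TrainConfig(alpha=50.0)
    opt = Adam(model.trainable_parameters(), lr=3e-3)
    first = None
    for _ in range(150):
        loss, _, mse = total_loss(data.images, data.measurements, model, cfg)
        if first is None:
            first = float(mse.data)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert float(mse.data) < 0.5 * first


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(alpha=-1.0)
    with pytest.raises(ValueError):
        TrainConfig(plateau_factor=1.5)
    with pytest.raises(ValueError):
        TrainConfig(train_noise_variance=-0.1)


def test_overfit_single_batch_reduces_nll(rng):
    """A small model on one fixed batch of 8 images gains >= 1 nat in 200 steps."""
    from flowrecon.nn import Adam

    model, fwd = _tiny_conditional_model(rng)
    data = SyntheticDataset.generate(fwd, 8, seed=5, phantom_kind="digits_like")
    x = data.images + 0.05 * rng.standard_normal(data.images.shape)
    y = data.measurements
    cfg = TrainConfig(alpha=0.0)
    opt = Adam(model.trainable_parameters(), lr=3e-3)
    first = None
    for step in range(200):
        loss, nll, _ = total_loss(x, y, model, cfg)
        if first is None:
            first = float(nll.data)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert first - float(nll.data) >= 1.0


def test_gradients_reach_flow_and_conditioning(rng):
    model, fwd = _tiny_conditional_model(rng)
    # move off the identity initialization (zero-init output layers block
    # upstream gradients exactly at step 0)
    for p in model.trainable_parameters():
        p.data = p.data + 0.05 * rng.standard_normal(p.data.shape)
    data = SyntheticDataset.generate(fwd, 4, seed=3)
    loss, _, _ = total_loss(data.images, data.measurements, model, TrainConfig())
    for p in model.trainable_parameters():
        p.grad = None
    loss.backward()
    flow_norm = sum(float(np.abs(p.grad).sum()) for p in model.flow.parameters()
                    if p.grad is not None)
    cond_norm = sum(float(np.abs(p.grad).sum()) for p in model.cond_net.parameters()
                    if p.grad is not None)
    assert flow_norm > 0 and cond_norm > 0


def test_frozen_conditioning_excluded_from_training(rng):
    model, fwd = _tiny_conditional_model(rng)
    model.freeze_conditioning = True
    n_flow = len(model.flow.parameters())
    assert len(model.trainable_parameters()) == n_flow


def test_train_returns_best_validation_checkpoint(rng):
    model, fwd = _tiny_conditional_model(rng)
    data = SyntheticDataset.generate(fwd, 40, seed=7)
    cfg = TrainConfig(learning_rate=3e-3, epochs=4, batch_size=8, seed=0,
                      val_fraction=0.2)
    model, history = train(model, data, cfg)
    assert len(history.val_nll) == 4
    assert history.best_val_nll == min(history.val_nll)
    assert history.val_nll[history.best_epoch] == history.best_val_nll


def test_train_deterministic_given_seed():
    def run():
        rng = np.random.default_rng(0)
        model, fwd = _tiny_conditional_model(rng)
        data = SyntheticDataset.generate(fwd, 20, seed=7)
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=8, seed=0)
        _, history = train(model, data, cfg)
        return history

    h1, h2 = run(), run()
    assert h1.train_nll == h2.train_nll
    assert h1.val_nll == h2.val_nll


def test_train_rejects_empty_dataset(rng):
    model, fwd = _tiny_conditional_model(rng)
    empty = SyntheticDataset(images=np.zeros((0, 1, 16, 16)),
                             measurements=np.zeros((0, 64)), seed=0,
                             forward_model=fwd, noise_spec=NoiseSpec())
    with pytest.raises(ValueError, match="empty"):
        train(model, empty, TrainConfig())


def test_unconditional_2d_density_reaches_analytic_nll(rng):
    """Flow trained on 2-D standard-normal data approaches ln(2 pi) + 1."""
    from flowrecon.estimators import FlowDensity

    X = np.random.default_rng(42).standard_normal((3000, 2))
    est = FlowDensity(n_blocks=4, hidden_width=16, epochs=15,
                      learning_rate=1e-3, seed=0)
    est.fit(X)
    analytic = np.log(2 * np.pi) + 1.0
    assert abs(est.validation_nll_ - analytic) < 0.05
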