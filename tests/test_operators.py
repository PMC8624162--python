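"""Forward operators, noise models, phantoms and datasets."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import flowrecon.radon as fr_radon
from flowrecon.operators import (
    FourierMasked,
    GaussianCS,
    NoiseSpec,
    RadonTransformModel,
    SamplingMask,
    SyntheticDataset,
    add_noise,
    add_training_noise,
    make_gaussian_cs,
    make_linear_gaussian_problem,
    make_mri_mask,
    make_phantoms,
)


# ---------------------------------------------------------------------------
# Gaussian compressed sensing
# ---------------------------------------------------------------------------

def test_gaussian_cs_default_is_4x_undersampling():
    model = make_gaussian_cs(seed=0)
    assert model.matrix.shape == (196, 784)
    assert model.domain_shape == (1, 28, 28)


def test_gaussian_cs_entry_variance(rng):
    m, n = 196, 784
    model = make_gaussian_cs(m, n, seed=3)
    var = model.matrix.var()
    assert abs(var - 1.0 / m) / (1.0 / m) < 0.1
    assert abs(model.matrix.mean()) < 3.0 / np.sqrt(m * n)


def test_gaussian_cs_seed_determinism():
    a = make_gaussian_cs(16, 64, seed=5).matrix
    b = make_gaussian_cs(16, 64, seed=5).matrix
    c = make_gaussian_cs(16, 64, seed=6).matrix
    np.testing.assert_array_equal(a, b)
    assert np.abs(a - c).max() > 0


def test_gaussian_cs_rejects_oversampling():
    with pytest.raises(ValueError):
        GaussianCS(65, 64, seed=0)


# ---------------------------------------------------------------------------
# Radon / FBP
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def radon128():
    return RadonTransformModel(128, 128)


def _disc(n, r):
    yy, xx = np.mgrid[:n, :n].astype(np.float64)
    half = (n - 1) / 2.0
    dist = np.sqrt((xx - half) ** 2 + (yy - half) ** 2)
    return np.clip(r - dist + 0.5, 0.0, 1.0)  # anti-aliased edge


def test_radon_linearity(radon128, rng):
    assert np.abs(radon128.apply(np.zeros((128, 128)))).max() == 0.0
    x1 = rng.random((128, 128))
    x2 = rng.random((128, 128))
    lhs = radon128.apply(2.0 * x1 - 3.0 * x2)
    rhs = 2.0 * radon128.apply(x1) - 3.0 * radon128.apply(x2)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_radon_disc_matches_analytic_chord_length(radon128):
    r = 40.0
    sino = radon128.apply(_disc(128, r)).reshape(radon128.range_shape)
    s = radon128.geometry.detector_offsets
    chord = 2.0 * np.sqrt(np.maximum(r * r - s * s, 0.0))
    interior = np.abs(s) < 0.9 * r
    rel = np.abs(sino[:, interior] - chord[interior]) / chord[interior]
    assert rel.max() < 0.02


def test_fbp_self_consistency_on_smooth_phantom(radon128, rng):
    n = 128
    ph = gaussian_filter(rng.random((n, n)), 6)
    ph = (ph - ph.min()) / (ph.max() - ph.min())
    ph *= np.outer(np.hanning(n), np.hanning(n))  # keep support inside FOV
    rec = radon128.fbp(radon128.apply(ph)).reshape(n, n)
    assert np.linalg.norm(rec - ph) / np.linalg.norm(ph) < 0.05


def test_radon_geometry_validation():
    with pytest.raises(ValueError, match="increasing"):
        fr_radon.RadonGeometry(angles=np.array([0.5, 0.2]),
                               detector_offsets=np.arange(-100, 101.0),
                               img_size=64)
    with pytest.raises(ValueError, match="span"):
        fr_radon.RadonGeometry(angles=np.array([0.0, 0.5]),
                               detector_offsets=np.arange(-10, 11.0),
                               img_size=64)


# ---------------------------------------------------------------------------
# MRI mask and masked Fourier operator
# ---------------------------------------------------------------------------

def test_mri_mask_counting_rules(rng):
    width = 320
    mask = make_mri_mask(width, rng=rng)  # defaults: acceleration 4, 8% center
    assert mask.acceleration == 4.0 and mask.center_fraction == 0.08
    assert mask.columns.sum() == width // 4
    n_center = round(0.08 * width)
    lo = (width - n_center) // 2
    assert mask.columns[lo : lo + n_center].all()


def test_mri_mask_center_always_kept_across_draws(rng):
    width = 64
    n_center = round(0.08 * width)
    lo = (width - n_center) // 2
    for _ in range(20):
        mask = make_mri_mask(width, rng=rng)
        assert mask.columns[lo : lo + n_center].all()
        assert mask.columns.sum() == 16


def test_mri_mask_infeasible_fractions_rejected(rng):
    with pytest.raises(ValueError):
        make_mri_mask(64, acceleration=4.0, center_fraction=0.3, rng=rng)
    with pytest.raises(ValueError):
        SamplingMask(columns=np.zeros(16, dtype=bool), acceleration=16.0,
                     center_fraction=0.08)


def test_fourier_full_mask_inverts_exactly(rng):
    mask = SamplingMask(columns=np.ones(16, dtype=bool), acceleration=1.0,
                        center_fraction=0.08)
    op = FourierMasked((16, 16), mask)
    x = rng.random((16, 16))
    rec = op.zero_filled(op.apply(x))
    assert np.abs(rec.reshape(16, 16) - x).max() < 1e-10


def test_fourier_masking_reduces_energy(rng):
    full = SamplingMask(columns=np.ones(32, dtype=bool), acceleration=1.0,
                        center_fraction=0.08)
    sub = make_mri_mask(32, rng=rng)
    x = rng.random((32, 32))
    e_full = np.sum(np.abs(FourierMasked((32, 32), full).apply(x)) ** 2)
    e_sub = np.sum(np.abs(FourierMasked((32, 32), sub).apply(x)) ** 2)
    assert e_sub <= e_full + 1e-12
    # Parseval with the full mask
    assert e_full == pytest.approx(np.sum(x**2), rel=1e-12)


@pytest.mark.parametrize("factory", [
    lambda rng: make_gaussian_cs(16, 64, seed=1),
    lambda rng: RadonTransformModel(16, 12),
    lambda rng: FourierMasked((16, 16), make_mri_mask(16, rng=rng)),
])
def test_adjoint_dot_product(factory, rng):
    model = factory(rng)
    assert model.dot_product_test(rng) < 1e-6


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def test_zero_noise_is_bit_exact(rng):
    y = rng.random((4, 10))
    out = add_noise(y, NoiseSpec(kind="relative_gaussian", level=0.0), rng)
    np.testing.assert_array_equal(out, y)


def test_relative_noise_level_monte_carlo(rng):
    y = rng.random(196)
    ratios = []
    for _ in range(100):
        noisy = add_noise(y, NoiseSpec(level=0.1), rng)
        ratios.append(np.linalg.norm(noisy - y) / np.linalg.norm(y))
    assert 0.08 < np.mean(ratios) < 0.12


def test_poisson_noise_vanishes_at_high_intensity(rng):
    y = np.linspace(0.1, 2.0, 50).reshape(1, 50)
    noisy = add_noise(y, NoiseSpec(kind="poisson", photons=1e12), rng)
    assert np.abs(noisy - y).max() / y.max() < 1e-3


def test_noise_validation():
    with pytest.raises(ValueError):
        NoiseSpec(level=-0.1)
    with pytest.raises(ValueError):
        NoiseSpec(kind="salt_pepper")


def test_training_noise_variance(rng):
    x = np.zeros((1, 1, 1000, 1000))
    noisy = add_training_noise(x, 0.005, rng)
    assert abs(noisy.var() - 0.005) / 0.005 < 0.05
    np.testing.assert_array_equal(add_training_noise(x, 0.0, rng), x)


# ---------------------------------------------------------------------------
# Phantoms & datasets
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["ellipses", "digits_like"])
def test_phantoms_range_and_determinism(kind):
    a = make_phantoms(4, 16, kind, np.random.default_rng(7))
    b = make_phantoms(4, 16, kind, np.random.default_rng(7))
    c = make_phantoms(4, 16, kind, np.random.default_rng(8))
    assert a.shape == (4, 1, 16, 16)
    assert a.min() >= 0.0 and a.max() <= 1.0
    np.testing.assert_array_equal(a, b)
    assert np.abs(a - c).max() > 0
    with pytest.raises(ValueError):
        make_phantoms(1, 8)


def test_dataset_regenerates_bit_identically():
    model = make_gaussian_cs(64, 256, seed=2)
    d1 = SyntheticDataset.generate(model, 8, seed=11, phantom_kind="digits_like")
    d2 = SyntheticDataset.generate(model, 8, seed=11, phantom_kind="digits_like")
    np.testing.assert_array_equal(d1.images, d2.images)
    np.testing.assert_array_equal(d1.measurements, d2.measurements)


def test_mask_text_roundtrip_and_png_export(tmp_path, rng):
    mask = make_mri_mask(32, rng=rng)
    path = str(tmp_path / "mask.txt")
    mask.save_text(path)
    loaded = SamplingMask.load_text(path, mask.acceleration, mask.center_fraction)
    np.testing.assert_array_equal(loaded.columns, mask.columns)
    model = make_gaussian_cs(64, 256, seed=2)
    data = SyntheticDataset.generate(model, 2, seed=1)
    data.save_png(str(tmp_path / "pngs"))
    assert sorted(p.name for p in (tmp_path / "pngs").iterdir()) == [
        "image_0000.png", "image_0001.png"]


def test_dataset_split_and_h5_roundtrip(tmp_path):
    model = make_gaussian_cs(64, 256, seed=2)
    data = SyntheticDataset.generate(model, 10, seed=1)
    train, val = data.split(0.2)
    assert len(train) == 8 and len(val) == 2
    path = str(tmp_path / "data.h5")
    data.save_h5(path)
    loaded = SyntheticDataset.load_h5(path, model)
    np.testing.assert_array_equal(loaded.images, data.images)
    np.testing.assert_array_equal(loaded.measurements, data.measurements)
    assert loaded.seed == data.seed
    assert loaded.noise_spec == data.noise_spec


# ---------------------------------------------------------------------------
# Linear-Gaussian reference problem
# ---------------------------------------------------------------------------

def test_linear_gaussian_posterior_is_bayes_optimal(rng):
    """The attached closed form must beat any perturbation of itself in
    posterior mean squared error (sanity for the analytic oracle)."""
    prob = make_linear_gaussian_problem(image_size=4, m=8, seed=0)
    x, y = prob.sample_joint(4000, rng)
    mu = prob.posterior_mean(y)
    resid = (x - mu).reshape(len(x), -1)
    mse_opt = np.mean(np.sum(resid**2, axis=1))
    # perturbed estimator: shrink the gain by 20%
    mu0 = prob.mu0
    mu_bad = mu0 + 0.8 * (mu.reshape(len(x), -1) - mu0)
    mse_bad = np.mean(np.sum((x.reshape(len(x), -1) - mu_bad) ** 2, axis=1))
    assert mse_opt < mse_bad
    # predicted risk: trace of posterior covariance
    assert mse_opt == pytest.approx(np.trace(prob.posterior_cov), rel=0.1)


def test_linear_gaussian_posterior_mean_interpolates(rng):
    prob = make_linear_gaussian_problem(image_size=4, m=8, seed=0)
    # noiseless measurement of the prior mean maps to the prior mean
    y0 = prob.model.apply(prob.mu0.reshape(1, 1, 4, 4))
    np.testing.assert_allclose(prob.posterior_mean(y0)[0].ravel(), prob.mu0,
                               atol=1e-8)
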