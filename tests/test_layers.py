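"""Invertible building blocks: exact inverses and exact log-determinants.

Every layer's reported logdet is validated against the sign-log-determinant
of the full Jacobian computed by finite differences on small inputs.
"""

import numpy as np
import pytest

from flowrecon._autodiff import Tensor
from flowrecon.layers import (
    AdditiveCoupling,
    AffineCoupling,
    CheckerboardDownsample,
    CouplingSpec,
    HaarDownsample,
    MixChannels,
    checkerboard_downsample,
    checkerboard_upsample,
    coupling_forward,
    coupling_inverse,
    haar_downsample,
    haar_upsample,
    merge_channels,
    mix_channels,
    pad_to_multiple,
    split_channels,
    HAAR_MATRIX,
)

from conftest import fd_slogdet


class _StubScaleNet:
    """Subnetwork emitting constant s = log(2), t = 0 (affine: 2*c2 channels)."""

    def __init__(self, c2, s_value):
        self.c2 = c2
        self.s_value = s_value

    def __call__(self, x):
        b, _, h, w = x.shape
        out = np.zeros((b, 2 * self.c2, h, w))
        out[:, : self.c2] = self.s_value
        return Tensor(out)

    def parameters(self):
        return []


# ---------------------------------------------------------------------------
# Coupling layers
# ---------------------------------------------------------------------------

def test_affine_identity_subnet_gives_identity_and_zero_logdet(rng):
    spec = CouplingSpec(kind="affine", split_sizes=(1, 1))
    x = rng.normal(size=(2, 2, 4, 4))
    res = coupling_forward(x, None, spec, subnet=_StubScaleNet(1, 0.0))
    np.testing.assert_array_equal(res.output, x)
    np.testing.assert_array_equal(res.logdet, np.zeros(2))


def test_additive_coupling_logdet_identically_zero(rng):
    spec = CouplingSpec(kind="additive", split_sizes=(2, 2))
    layer = AdditiveCoupling(spec, rng=rng)
    for p in layer.subnet.parameters():
        p.data = rng.normal(size=p.data.shape) * 0.3
    x = Tensor(rng.normal(size=(3, 4, 4, 4)))
    _, logdet = layer.forward(x)
    np.testing.assert_array_equal(logdet.data, np.zeros(3))


def test_affine_logdet_constant_scale_matches_closed_form_and_fd_oracle(rng):
    # s = log 2 on every transformed entry of a (1, 2, 2, 2) input: 4 entries
    s_val = np.log(2.0)
    spec = CouplingSpec(kind="affine", split_sizes=(1, 1), clamp=2.0)
    subnet = _StubScaleNet(1, s_val)
    x0 = rng.normal(size=(1, 2, 2, 2))
    res = coupling_forward(x0, None, spec, subnet=subnet)
    clamped = 2.0 * np.tanh(s_val / 2.0)
    assert res.logdet[0] == pytest.approx(4 * clamped, rel=1e-12)

    def f(v):
        return coupling_forward(v.reshape(1, 2, 2, 2), None, spec, subnet=subnet).output

    assert fd_slogdet(f, x0) == pytest.approx(res.logdet[0], rel=1e-6)


@pytest.mark.parametrize("kind", ["additive", "affine"])
def test_coupling_logdet_matches_fd_jacobian_with_random_subnet(kind, rng):
    spec = CouplingSpec(kind=kind, split_sizes=(1, 1), hidden_width=6)
    layer = (AffineCoupling if kind == "affine" else AdditiveCoupling)(spec, rng=rng)
    for p in layer.subnet.parameters():
        p.data = rng.normal(size=p.data.shape) * 0.3
    x0 = rng.normal(size=(1, 2, 4, 4))
    _, logdet = layer.forward(Tensor(x0))

    def f(v):
        y, _ = layer.forward(Tensor(v.reshape(1, 2, 4, 4)))
        return y.data

    assert fd_slogdet(f, x0) == pytest.approx(logdet.data[0], rel=1e-4, abs=1e-6)


@pytest.mark.parametrize("kind", ["additive", "affine"])
@pytest.mark.parametrize("conditional", [False, True])
def test_coupling_roundtrip_random_subnet(kind, conditional, rng):
    spec = CouplingSpec(kind=kind, split_sizes=(2, 1), hidden_width=8,
                        conditional=conditional, cond_channels=3)
    layer = (AffineCoupling if kind == "affine" else AdditiveCoupling)(spec, rng=rng)
    for p in layer.subnet.parameters():
        p.data = rng.normal(size=p.data.shape) * 0.4
    x = rng.normal(size=(4, 3, 4, 4))
    cond = rng.normal(size=(4, 3, 4, 4)) if conditional else None
    y, _ = layer.forward(Tensor(x), cond)
    x_rec = layer.inverse(y.data, cond)
    assert np.abs(x_rec - x).max() < 1e-10


def test_affine_inverse_reduces_to_additive_when_scale_zero(rng):
    spec = CouplingSpec(kind="affine", split_sizes=(1, 1))
    layer = AffineCoupling(spec, rng=rng, subnet=_StubScaleNet(1, 0.0))
    y = rng.normal(size=(2, 2, 3, 3))
    # s = 0, t = 0: inverse(y) = y
    np.testing.assert_allclose(layer.inverse(y), y)


def test_coupling_validates_channel_split_and_finiteness(rng):
    spec = CouplingSpec(kind="affine", split_sizes=(1, 1))
    x_bad = rng.normal(size=(1, 3, 4, 4))
    with pytest.raises(ValueError, match="channels"):
        coupling_forward(x_bad, None, spec, subnet=_StubScaleNet(1, 0.0))
    x_nan = np.full((1, 2, 4, 4), np.nan)
    with pytest.raises(ValueError, match="non-finite"):
        coupling_forward(x_nan, None, spec, subnet=_StubScaleNet(1, 0.0))
    with pytest.raises(ValueError):
        CouplingSpec(kind="affine", split_sizes=(0, 2))
    with pytest.raises(ValueError):
        CouplingSpec(kind="glow")


def test_conditional_coupling_requires_conditioning(rng):
    spec = CouplingSpec(kind="additive", split_sizes=(1, 1), conditional=True,
                        cond_channels=2)
    layer = AdditiveCoupling(spec, rng=rng)
    with pytest.raises(ValueError, match="conditioning"):
        layer.forward(Tensor(rng.normal(size=(1, 2, 4, 4))), None)


def test_affine_clamp_bounds_effective_log_scale(rng):
    clamp = 1.5
    spec = CouplingSpec(kind="affine", split_sizes=(1, 1), clamp=clamp)
    layer = AffineCoupling(spec, rng=rng, subnet=_StubScaleNet(1, 50.0))
    x = rng.normal(size=(1, 2, 4, 4))
    _, logdet = layer.forward(Tensor(x))
    # 16 transformed entries, each log-scale clamped into [-clamp, clamp]
    assert logdet.data[0] <= 16 * clamp + 1e-9
    assert layer.last_max_scale <= clamp + 1e-9


# ---------------------------------------------------------------------------
# Channel mixing
# ---------------------------------------------------------------------------

def test_mix_identity_matrix_is_identity():
    x = np.arange(24, dtype=float).reshape(1, 3, 2, 4)
    res = mix_channels(x, np.eye(3))
    np.testing.assert_array_equal(res.output, x)
    np.testing.assert_array_equal(res.logdet, [0.0])


def test_mix_orthogonal_default_has_zero_logdet(rng):
    layer = MixChannels(4, rng=rng)
    x = rng.normal(size=(2, 4, 3, 3))
    _, logdet = layer.forward(Tensor(x))
    np.testing.assert_allclose(logdet.data, 0.0, atol=1e-10)
    np.testing.assert_allclose(layer.q @ layer.q.T, np.eye(4), atol=1e-12)


def test_mix_random_matrix_logdet_matches_fd_oracle(rng):
    q = rng.normal(size=(3, 3)) + 2 * np.eye(3)
    x0 = rng.normal(size=(1, 3, 2, 2))
    res = mix_channels(x0, q)
    expected = 4 * np.linalg.slogdet(q)[1]
    assert res.logdet[0] == pytest.approx(expected, rel=1e-12)

    def f(v):
        return mix_channels(v.reshape(1, 3, 2, 2), q).output

    assert fd_slogdet(f, x0) == pytest.approx(res.logdet[0], rel=1e-5)


def test_mix_rejects_singular_matrix():
    with pytest.raises(ValueError, match="invertible"):
        MixChannels(2, matrix=np.ones((2, 2)))


def test_mix_roundtrip(rng):
    layer = MixChannels(5, rng=rng)
    x = rng.normal(size=(2, 5, 4, 4))
    y, _ = layer.forward(Tensor(x))
    np.testing.assert_allclose(layer.inverse(y.data), x, atol=1e-12)


# ---------------------------------------------------------------------------
# Invertible downsampling
# ---------------------------------------------------------------------------

def test_checkerboard_shape_rule_and_bitexact_roundtrip(rng):
    x = rng.normal(size=(2, 3, 8, 6))
    res = checkerboard_downsample(x)
    assert res.output.shape == (2, 12, 4, 3)
    np.testing.assert_array_equal(res.logdet, np.zeros(2))
    back = checkerboard_upsample(res.output)
    np.testing.assert_array_equal(back.output, x)
    # permutation: multiset of values preserved exactly
    np.testing.assert_array_equal(np.sort(res.output.ravel()), np.sort(x.ravel()))


def test_checkerboard_rejects_odd_spatial_size(rng):
    with pytest.raises(ValueError, match="even"):
        checkerboard_downsample(rng.normal(size=(1, 1, 7, 8)))


def test_haar_constant_image_concentrates_on_average_channel():
    v = 0.7
    x = np.full((1, 1, 4, 4), v)
    res = haar_downsample(x)
    np.testing.assert_allclose(res.output[0, 0], 2 * v)      # average channel
    np.testing.assert_allclose(res.output[0, 1:], 0.0, atol=1e-15)


def test_haar_is_isometry_and_exact_inverse(rng):
    x = rng.normal(size=(3, 2, 6, 6))
    res = haar_downsample(x)
    assert np.linalg.norm(res.output) == pytest.approx(np.linalg.norm(x), rel=1e-12)
    np.testing.assert_array_equal(res.logdet, np.zeros(3))
    back = haar_upsample(res.output)
    np.testing.assert_allclose(back.output, x, atol=1e-12)


def test_haar_matches_explicit_block_matrix(rng):
    # each 2x2 block flattened [p00, p01, p10, p11] times the orthonormal
    # 4x4 haar matrix must equal the 4 output channels at that location
    x = rng.normal(size=(1, 1, 4, 4))
    out = haar_downsample(x).output[0]
    for bi in range(2):
        for bj in range(2):
            block = x[0, 0, 2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2].ravel()
            np.testing.assert_allclose(out[:, bi, bj], HAAR_MATRIX @ block,
                                       atol=1e-12)
    np.testing.assert_allclose(HAAR_MATRIX @ HAAR_MATRIX.T, np.eye(4), atol=1e-15)


# ---------------------------------------------------------------------------
# Split / merge and padding
# ---------------------------------------------------------------------------

def test_split_merge_partition(rng):
    x = rng.normal(size=(2, 8, 3, 3))
    kept, fwd = split_channels(x)
    assert kept.shape[1] == 4 and fwd.shape[1] == 4   # default half/half
    assert kept.size + fwd.size == x.size
    np.testing.assert_array_equal(merge_channels(kept, fwd), x)


def test_split_validates_sizes(rng):
    x = rng.normal(size=(1, 4, 2, 2))
    with pytest.raises(ValueError):
        split_channels(x, n_keep=4)
    with pytest.raises(ValueError):
        split_channels(rng.normal(size=(1, 1, 2, 2)))


def test_pad_to_multiple(rng):
    x = rng.normal(size=(2, 1, 7, 5))
    padded, (ph, pw) = pad_to_multiple(x, 4)
    assert padded.shape == (2, 1, 8, 8)
    assert (ph, pw) == (1, 3)
    np.testing.assert_array_equal(padded[:, :, :7, :5], x)
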