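"""Linear forward operators, noise models and the synthetic-data generator.

Three measurement operators cover the toy problems the package ships with:

* ``GaussianCS`` — a dense m x n compressed-sensing matrix with i.i.d.
  N(0, 1/m) entries (default m = 196, n = 784, i.e. 4x undersampling);
* ``RadonTransformModel`` — the discrete 2-D parallel-beam Radon transform
  with filtered back-projection (see :mod:`flowrecon.radon`);
* ``FourierMasked`` — the centered, orthonormal 2-D DFT with a Cartesian
  column mask (acceleration 4, 8% center fraction by default).

All operators expose ``apply``/``adjoint`` and pass the adjoint dot-product
test; the synthetic datasets built on top regenerate bit-identically from
their seed.  "10% relative noise" means additive Gaussian noise whose
expected norm is 10% of the per-sample measurement norm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from . import radon as radon_mod

__all__ = [
    "LinearForwardModel",
    "GaussianCS",
    "RadonTransformModel",
    "FourierMasked",
    "SamplingMask",
    "NoiseSpec",
    "SyntheticDataset",
    "LinearGaussianProblem",
    "make_gaussian_cs",
    "make_mri_mask",
    "fourier_masked_forward",
    "add_noise",
    "add_training_noise",
    "make_phantoms",
    "make_linear_gaussian_problem",
]


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

class LinearForwardModel:
    """Operator A with apply, adjoint, and shape metadata."""

    kind: str
    domain_shape: tuple[int, ...]   # image shape (c, h, w)
    range_shape: tuple[int, ...]

    def apply(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _flatten_domain(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=np.float64)
        n = int(np.prod(self.domain_shape))
        # a single image, with or without its channel axis (batches always
        # carry one more dimension than the domain shape)
        if x.shape == tuple(self.domain_shape) or x.shape == tuple(self.domain_shape)[1:]:
            return x.reshape(1, n), True
        return x.reshape(-1, n), False

    def dot_product_test(self, rng: np.random.Generator) -> float:
        """Relative error of <A x, y> vs <x, A^T y> on random inputs."""
        x = rng.standard_normal((1, *self.domain_shape))
        ax = self.apply(x)
        y = rng.standard_normal(ax.shape)
        if np.iscomplexobj(ax):
            y = y + 1j * rng.standard_normal(ax.shape)
            lhs = np.real(np.sum(ax * np.conj(y)))
        else:
            lhs = float(np.sum(ax * y))
        aty = self.adjoint(y)
        rhs = float(np.sum(x * np.real(aty) if np.iscomplexobj(aty) else x * aty))
        return abs(lhs - rhs) / max(abs(lhs), 1e-12)


class GaussianCS(LinearForwardModel):
    """Dense compressed-sensing operator with A_ij ~ N(0, 1/m)."""

    kind = "gaussian_cs"

    def __init__(self, m: int, n: int, seed: int, image_shape=None):
        if not 1 <= m <= n:
            raise ValueError("undersampling assumed: need 1 <= m <= n")
        if image_shape is None:
            side = int(round(np.sqrt(n)))
            if side * side != n:
                raise ValueError("n is not a perfect square; pass image_shape")
            image_shape = (1, side, side)
        if int(np.prod(image_shape)) != n:
            raise ValueError("image_shape does not match n")
        self.m, self.n = int(m), int(n)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.matrix = rng.normal(0.0, 1.0 / np.sqrt(m), size=(m, n))
        self.domain_shape = tuple(image_shape)
        self.range_shape = (m,)

    def apply(self, x: np.ndarray) -> np.ndarray:
        flat, single = self._flatten_domain(x)
        y = flat @ self.matrix.T
        return y[0] if single else y

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        single = y.ndim == 1
        x = np.atleast_2d(y) @ self.matrix
        x = x.reshape(-1, *self.domain_shape)
        return x[0] if single else x


def make_gaussian_cs(m: int = 196, n: int = 784, seed: int = 0,
                     image_shape=None) -> GaussianCS:
    return GaussianCS(m, n, seed, image_shape=image_shape)


class RadonTransformModel(LinearForwardModel):
    """Sparse-matrix Radon transform with FBP inversion."""

    kind = "radon"

    def __init__(self, img_size: int, n_angles: int,
                 geometry: radon_mod.RadonGeometry | None = None):
        self.geometry = geometry or radon_mod.make_geometry(img_size, n_angles)
        self.matrix = radon_mod.build_radon_matrix(self.geometry)
        self.domain_shape = (1, img_size, img_size)
        self.range_shape = (self.geometry.n_angles, self.geometry.n_detectors)

    def apply(self, x: np.ndarray) -> np.ndarray:
        flat, single = self._flatten_domain(x)
        sino = (self.matrix @ flat.T).T.reshape(-1, *self.range_shape)
        return sino[0] if single else sino

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        single = y.ndim == 2
        flat = y.reshape(-1, int(np.prod(self.range_shape)))
        x = (self.matrix.T @ flat.T).T.reshape(-1, *self.domain_shape)
        return x[0] if single else x

    def fbp(self, sino: np.ndarray, cutoff: float = 1.0) -> np.ndarray:
        single = sino.ndim == 2
        rec = radon_mod.fbp_reconstruct(
            np.atleast_3d(sino).reshape(-1, *self.range_shape),
            self.geometry, self.matrix, cutoff=cutoff,
        ).reshape(-1, *self.domain_shape)
        return rec[0] if single else rec


@dataclass
class SamplingMask:
    """Boolean Cartesian column mask over the (centered) k-space width."""

    columns: np.ndarray
    acceleration: float
    center_fraction: float

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=bool)
        width = len(self.columns)
        n_keep = int(round(width / self.acceleration))
        if int(self.columns.sum()) != n_keep:
            raise ValueError("kept-column count does not match the acceleration")
        n_center = int(round(self.center_fraction * width))
        lo = (width - n_center) // 2
        if not np.all(self.columns[lo : lo + n_center]):
            raise ValueError("all center columns must be kept")

    @property
    def width(self) -> int:
        return len(self.columns)

    def save_text(self, path: str) -> None:
        """Flat 0/1 column vector, one value per line."""
        np.savetxt(path, self.columns.astype(int), fmt="%d",
                   header=f"acceleration={self.acceleration} "
                          f"center_fraction={self.center_fraction}")

    @staticmethod
    def load_text(path: str, acceleration: float, center_fraction: float
                  ) -> "SamplingMask":
        cols = np.loadtxt(path).astype(bool)
        return SamplingMask(columns=cols, acceleration=acceleration,
                            center_fraction=center_fraction)


def make_mri_mask(width: int, acceleration: float = 4.0,
                  center_fraction: float = 0.08,
                  rng: np.random.Generator | None = None) -> SamplingMask:
    """Keep round(width/acceleration) columns: all round(cf * width) center
    columns plus uniformly random higher-frequency columns."""
    if center_fraction >= 1.0 / acceleration:
        raise ValueError("center_fraction must be below 1/acceleration")
    rng = rng or np.random.default_rng()
    n_keep = int(round(width / acceleration))
    n_center = int(round(center_fraction * width))
    cols = np.zeros(width, dtype=bool)
    lo = (width - n_center) // 2
    cols[lo : lo + n_center] = True
    remaining = np.flatnonzero(~cols)
    extra = rng.choice(remaining, size=n_keep - n_center, replace=False)
    cols[extra] = True
    return SamplingMask(columns=cols, acceleration=acceleration,
                        center_fraction=center_fraction)


class FourierMasked(LinearForwardModel):
    """Masked, centered, orthonormal 2-D discrete Fourier transform.

    The zero frequency sits at the array center; unmeasured k-space columns
    are zeroed.  ``zero_filled`` is the magnitude of the inverse transform
    of the zero-filled spectrum (the classical undersampled-MRI baseline).
    """

    kind = "fourier_masked"

    def __init__(self, img_shape: tuple[int, int], mask: SamplingMask):
        h, w = img_shape
        if mask.width != w:
            raise ValueError("mask width must equal the image width")
        self.mask = mask
        self.domain_shape = (1, h, w)
        self.range_shape = (h, w)

    def _mask2d(self) -> np.ndarray:
        return self.mask.columns[None, :]

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2 or x.shape == self.domain_shape
        imgs = x.reshape(-1, *self.domain_shape[1:])
        k = np.fft.fftshift(np.fft.fft2(imgs, norm="ortho"), axes=(-2, -1))
        k = k * self._mask2d()
        return k[0] if single else k

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        single = y.ndim == 2
        ks = y.reshape(-1, *self.range_shape) * self._mask2d()
        x = np.fft.ifft2(np.fft.ifftshift(ks, axes=(-2, -1)), norm="ortho")
        x = np.real(x).reshape(-1, *self.domain_shape)
        return x[0] if single else x

    def zero_filled(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        single = y.ndim == 2
        ks = y.reshape(-1, *self.range_shape) * self._mask2d()
        x = np.fft.ifft2(np.fft.ifftshift(ks, axes=(-2, -1)), norm="ortho")
        x = np.abs(x).reshape(-1, *self.domain_shape)
        return x[0] if single else x


def fourier_masked_forward(x: np.ndarray, mask: SamplingMask) -> np.ndarray:
    h = np.asarray(x).shape[-2]
    return FourierMasked((h, mask.width), mask).apply(x)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """``relative_gaussian``: y + level * (||y|| / sqrt(m)) * g with g
    standard normal, so E||noise|| ~= level * ||y|| per sample.
    ``poisson``: photon-count noise on exponentiated line integrals with
    ``photons`` incident counts, log-transformed back (a single-parameter
    low-dose CT emulation)."""

    kind: str = "relative_gaussian"
    level: float = 0.1
    photons: float = 4096.0

    def __post_init__(self):
        if self.kind not in ("none", "relative_gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


def add_noise(y: np.ndarray, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    y = np.asarray(y)
    if spec.kind == "none" or (spec.kind == "relative_gaussian" and spec.level == 0):
        return y.copy()
    single = y.ndim == 1 or (y.ndim == 2 and spec.kind == "poisson")
    if spec.kind == "relative_gaussian":
        flat = y.reshape(1, -1) if y.ndim == 1 else y.reshape(y.shape[0], -1)
        m = flat.shape[1]
        norms = np.linalg.norm(flat, axis=1, keepdims=True)
        if np.iscomplexobj(flat):
            g = (rng.standard_normal(flat.shape)
                 + 1j * rng.standard_normal(flat.shape)) / np.sqrt(2.0)
        else:
            g = rng.standard_normal(flat.shape)
        noisy = flat + spec.level * (norms / np.sqrt(m)) * g
        return noisy.reshape(y.shape)
    # poisson on line integrals
    counts = rng.poisson(spec.photons * np.exp(-np.asarray(y, dtype=np.float64)))
    counts = np.maximum(counts, 1)
    return -np.log(counts / spec.photons)


def add_training_noise(x: np.ndarray, variance: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Dequantization-style augmentation: x + N(0, variance) per pixel."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return np.asarray(x).copy()
    return np.asarray(x) + rng.normal(0.0, np.sqrt(variance), np.shape(x))


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def make_phantoms(count: int, size: int, kind: str = "ellipses",
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Random ground-truth images in [0, 1], shape (count, 1, size, size)."""
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = rng or np.random.default_rng()
    if kind == "ellipses":
        return _ellipse_phantoms(count, size, rng)
    if kind == "digits_like":
        return _stroke_phantoms(count, size, rng)
    raise ValueError(f"unknown phantom kind {kind!r}")


def _ellipse_phantoms(count: int, size: int, rng) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size].astype(np.float64)
    out = np.zeros((count, 1, size, size))
    for i in range(count):
        img = np.zeros((size, size))
        for _ in range(int(rng.integers(3, 9))):
            cx, cy = rng.uniform(0.2 * size, 0.8 * size, size=2)
            ax_, ay = rng.uniform(0.05 * size, 0.3 * size, size=2)
            phi = rng.uniform(0, np.pi)
            inten = rng.uniform(0.15, 0.7) * rng.choice([1.0, 1.0, -0.5])
            c, s = np.cos(phi), np.sin(phi)
            u = (xx - cx) * c + (yy - cy) * s
            v = -(xx - cx) * s + (yy - cy) * c
            img += inten * ((u / ax_) ** 2 + (v / ay) ** 2 <= 1.0)
        out[i, 0] = np.clip(img, 0.0, 1.0)
    return out


def _stroke_phantoms(count: int, size: int, rng) -> np.ndarray:
    """Sparse stroke patterns loosely resembling handwritten digits."""
    from scipy.ndimage import gaussian_filter

    out = np.zeros((count, 1, size, size))
    for i in range(count):
        img = np.zeros((size, size))
        n_strokes = int(rng.integers(2, 5))
        for _ in range(n_strokes):
            p = rng.uniform(0.2 * size, 0.8 * size, size=2)
            direction = rng.uniform(-1, 1, size=2)
            direction /= np.linalg.norm(direction) + 1e-9
            n_steps = int(rng.integers(size // 2, size))
            for _ in range(n_steps):
                r, c = int(round(p[0])), int(round(p[1]))
                if 0 <= r < size and 0 <= c < size:
                    img[r, c] = 1.0
                direction += 0.35 * rng.uniform(-1, 1, size=2)
                direction /= np.linalg.norm(direction) + 1e-9
                p = p + direction
        img = gaussian_filter(img, sigma=size / 28.0)
        peak = img.max()
        if peak > 0:
            img = img / peak
        out[i, 0] = np.clip(img, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Paired (image, measurement) stack regenerable from its seed."""

    images: np.ndarray
    measurements: np.ndarray
    seed: int
    forward_model: LinearForwardModel
    noise_spec: NoiseSpec
    phantom_kind: str = "ellipses"

    @classmethod
    def generate(cls, forward_model: LinearForwardModel, count: int, seed: int,
                 noise_spec: NoiseSpec | None = None,
                 phantom_kind: str = "ellipses") -> "SyntheticDataset":
        noise_spec = noise_spec or NoiseSpec()
        rng = np.random.default_rng(seed)
        size = forward_model.domain_shape[-1]
        images = make_phantoms(count, size, kind=phantom_kind, rng=rng)
        clean = forward_model.apply(images)
        measurements = add_noise(clean, noise_spec, rng)
        return cls(images=images, measurements=measurements, seed=seed,
                   forward_model=forward_model, noise_spec=noise_spec,
                   phantom_kind=phantom_kind)

    def __len__(self) -> int:
        return len(self.images)

    def split(self, val_fraction: float = 0.1
              ) -> tuple["SyntheticDataset", "SyntheticDataset"]:
        """Deterministic train/validation split by index (before shuffling)."""
        n_val = max(1, int(round(len(self) * val_fraction)))
        n_train = len(self) - n_val
        train = SyntheticDataset(self.images[:n_train], self.measurements[:n_train],
                                 self.seed, self.forward_model, self.noise_spec,
                                 self.phantom_kind)
        val = SyntheticDataset(self.images[n_train:], self.measurements[n_train:],
                               self.seed, self.forward_model, self.noise_spec,
                               self.phantom_kind)
        return train, val

    def save_h5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images)
            if np.iscomplexobj(self.measurements):
                f.create_dataset("measurements_real", data=self.measurements.real)
                f.create_dataset("measurements_imag", data=self.measurements.imag)
            else:
                f.create_dataset("measurements", data=self.measurements)
            f.attrs["seed"] = self.seed
            f.attrs["operator_kind"] = self.forward_model.kind
            f.attrs["noise_spec"] = json.dumps(asdict(self.noise_spec))
            f.attrs["phantom_kind"] = self.phantom_kind

    def save_png(self, directory: str) -> None:
        """Ground-truth images as 8-bit PNGs for visual inspection."""
        import pathlib

        from PIL import Image

        out = pathlib.Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(self.images):
            arr = np.clip(np.squeeze(img), 0.0, 1.0)
            Image.fromarray((arr * 255).astype(np.uint8)).save(
                out / f"image_{i:04d}.png")

    @staticmethod
    def load_h5(path: str, forward_model: LinearForwardModel) -> "SyntheticDataset":
        import h5py

        with h5py.File(path, "r") as f:
            images = f["images"][...]
            if "measurements" in f:
                measurements = f["measurements"][...]
            else:
                measurements = f["measurements_real"][...] + 1j * f["measurements_imag"][...]
            spec = NoiseSpec(**json.loads(f.attrs["noise_spec"]))
            return SyntheticDataset(images=images, measurements=measurements,
                                    seed=int(f.attrs["seed"]),
                                    forward_model=forward_model, noise_spec=spec,
                                    phantom_kind=str(f.attrs["phantom_kind"]))


# ---------------------------------------------------------------------------
# Linear-Gaussian reference problem (closed-form posterior)
# ---------------------------------------------------------------------------

@dataclass
class LinearGaussianProblem:
    """Gaussian prior x ~ N(mu0, Sigma0), y = A x + N(0, sigma^2 I).

    The posterior is Gaussian with

        Sigma_post = (Sigma0^-1 + A^T A / sigma^2)^-1
        mu_post(y) = mu0 + Sigma0 A^T (A Sigma0 A^T + sigma^2 I)^-1 (y - A mu0)

    and serves as the analytic oracle for posterior-sampling models.
    """

    model: GaussianCS
    mu0: np.ndarray
    sigma0: np.ndarray
    noise_std: float

    def __post_init__(self):
        A = self.model.matrix
        S = self.sigma0
        self._gain = S @ A.T @ np.linalg.inv(A @ S @ A.T + self.noise_std**2 * np.eye(A.shape[0]))
        self.posterior_cov = S - self._gain @ A @ S
        self.posterior_std_image = np.sqrt(np.diag(self.posterior_cov)).reshape(
            self.model.domain_shape
        )

    @property
    def image_shape(self) -> tuple[int, ...]:
        return self.model.domain_shape

    def sample_images(self, count: int, rng: np.random.Generator) -> np.ndarray:
        L = np.linalg.cholesky(self.sigma0 + 1e-12 * np.eye(len(self.mu0)))
        x = self.mu0 + rng.standard_normal((count, len(self.mu0))) @ L.T
        return x.reshape(count, *self.model.domain_shape)

    def sample_joint(self, count: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
        x = self.sample_images(count, rng)
        y = self.model.apply(x)
        y = y + self.noise_std * rng.standard_normal(y.shape)
        return x, y

    def posterior_mean(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(y)
        resid = y - self.model.apply(self.mu0.reshape(self.model.domain_shape))
        mu = self.mu0 + resid @ self._gain.T
        return mu.reshape(-1, *self.model.domain_shape)


def make_linear_gaussian_problem(image_size: int = 4, m: int = 8, seed: int = 0,
                                 noise_std: float = 0.08,
                                 prior_mean: float = 0.5,
                                 prior_scale: float = 0.3,
                                 prior_length: float = 1.0,
                                 prior_nugget: float = 0.005
                                 ) -> LinearGaussianProblem:
    """Smooth-prior reference problem on ``image_size**2`` pixels.

    The prior is a squared-exponential (RBF) covariance over the pixel grid
    with a white-noise nugget that keeps the covariance well away from
    singularity; the default measurement noise corresponds to roughly 10%
    relative noise for draws from this prior.
    """
    n = image_size * image_size
    model = GaussianCS(m, n, seed, image_shape=(1, image_size, image_size))
    yy, xx = np.mgrid[:image_size, :image_size].astype(np.float64)
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    sigma0 = (prior_scale**2 * np.exp(-d2 / (2 * prior_length**2))
              + prior_nugget * np.eye(n))
    mu0 = np.full(n, prior_mean)
    return LinearGaussianProblem(model=model, mu0=mu0, sigma0=sigma0,
                                 noise_std=noise_std)
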