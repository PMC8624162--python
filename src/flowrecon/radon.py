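"""Discrete 2-D parallel-beam Radon transform and filtered back-projection.

The forward operator is assembled once as a sparse matrix using a
ray-driven discretization: for each (angle, detector offset) pair the line

    p(t) = s * (cos phi, sin phi) + t * (-sin phi, cos phi)

is sampled at spacing ``step`` (in pixel units) and each sample deposits
bilinear interpolation weights, scaled by ``step``, onto the image grid.
The adjoint is then the exact matrix transpose, so the operator passes the
dot-product test to machine precision.

Filtered back-projection applies the Ram-Lak ramp filter |nu| along the
detector axis in the Fourier domain and back-projects with the adjoint.
With unit detector spacing the discrete inversion formula is

    x ~= (pi / n_angles) * A^T ( F^{-1}[ |nu| F[sinogram] ] ),

exact in the continuum limit; at finite resolution the residual error is a
few percent for smooth phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["RadonGeometry", "make_geometry", "build_radon_matrix",
           "radon_transform", "fbp_reconstruct"]


@dataclass
class RadonGeometry:
    """Parallel-beam geometry: projection angles (radians, in [0, pi)),
    detector offsets (pixel units, centered), and the square image size."""

    angles: np.ndarray
    detector_offsets: np.ndarray
    img_size: int

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.detector_offsets = np.asarray(self.detector_offsets, dtype=np.float64)
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[0] < 0 or self.angles[-1] >= np.pi:
            raise ValueError("angles must lie in [0, pi)")
        diag = np.sqrt(2.0) * self.img_size
        span = self.detector_offsets[-1] - self.detector_offsets[0]
        if span + 1.0 < diag:
            raise ValueError("detector span does not cover the image diagonal")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_offsets)

    @property
    def detector_spacing(self) -> float:
        return float(self.detector_offsets[1] - self.detector_offsets[0])


def make_geometry(img_size: int, n_angles: int) -> RadonGeometry:
    """Default geometry: angles uniform on [0, pi), unit detector spacing,
    detector count ceil(img_size * sqrt(2)) covering the diagonal."""
    angles = np.arange(n_angles) * np.pi / n_angles
    n_det = int(np.ceil(img_size * np.sqrt(2.0))) + 1
    offsets = (np.arange(n_det) - (n_det - 1) / 2.0) * 1.0
    return RadonGeometry(angles=angles, detector_offsets=offsets, img_size=img_size)


def build_radon_matrix(geom: RadonGeometry, step: float = 0.5) -> sparse.csr_matrix:
    """Sparse (n_angles * n_det, img_size**2) line-integral matrix."""
    n = geom.img_size
    half = (n - 1) / 2.0
    t_max = np.sqrt(2.0) * n / 2.0 + 1.0
    ts = np.arange(-t_max, t_max + step, step)
    rows_all, cols_all, vals_all = [], [], []
    s = geom.detector_offsets
    for a_idx, phi in enumerate(geom.angles):
        c, si = np.cos(phi), np.sin(phi)
        # sample positions for all (detector, t) pairs: (n_det, n_t)
        px = s[:, None] * c - ts[None, :] * si
        py = s[:, None] * si + ts[None, :] * c
        col_f = px + half
        row_f = py + half
        j0 = np.floor(col_f).astype(np.int64)
        i0 = np.floor(row_f).astype(np.int64)
        fj = col_f - j0
        fi = row_f - i0
        for di, dj, w in (
            (0, 0, (1 - fi) * (1 - fj)),
            (0, 1, (1 - fi) * fj),
            (1, 0, fi * (1 - fj)),
            (1, 1, fi * fj),
        ):
            ii = i0 + di
            jj = j0 + dj
            valid = (ii >= 0) & (ii < n) & (jj >= 0) & (jj < n) & (w > 0)
            det_idx = np.broadcast_to(np.arange(len(s))[:, None], ii.shape)[valid]
            rows_all.append(a_idx * len(s) + det_idx)
            cols_all.append(ii[valid] * n + jj[valid])
            vals_all.append(w[valid] * step)
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)
    shape = (geom.n_angles * geom.n_detectors, n * n)
    return sparse.coo_matrix((vals, (rows, cols)), shape=shape).tocsr()


def radon_transform(x: np.ndarray, geom: RadonGeometry,
                    matrix: sparse.csr_matrix | None = None) -> np.ndarray:
    """Sinogram of shape (..., n_angles, n_detectors)."""
    if matrix is None:
        matrix = build_radon_matrix(geom)
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 2
    imgs = x.reshape(-1, geom.img_size * geom.img_size)
    sino = (matrix @ imgs.T).T.reshape(-1, geom.n_angles, geom.n_detectors)
    return sino[0] if single else sino


def _ramp_filter(sino: np.ndarray, spacing: float, cutoff: float) -> np.ndarray:
    """Band-limited Ram-Lak filtering along the detector axis.

    Uses the spatial-domain ramp kernel (h[0] = 1/(4 ds^2),
    h[n] = -1/(pi n ds)^2 for odd n, 0 for even n) evaluated in the Fourier
    domain with zero padding; the naive |nu| sampling underestimates the DC
    component and produces a cupping bias.
    """
    n_det = sino.shape[-1]
    n_pad = int(2 ** np.ceil(np.log2(2 * n_det)))
    ks = np.arange(n_pad)
    ks = np.where(ks > n_pad // 2, ks - n_pad, ks)
    h = np.zeros(n_pad)
    h[0] = 1.0 / (4.0 * spacing**2)
    odd = ks % 2 == 1
    h[odd] = -1.0 / (np.pi * ks[odd] * spacing) ** 2
    filt = np.real(np.fft.fft(h))
    if cutoff < 1.0:
        freqs = np.fft.fftfreq(n_pad, d=spacing)
        filt[np.abs(freqs) > cutoff * 0.5 / spacing] = 0.0
    spectrum = np.fft.fft(sino, n=n_pad, axis=-1) * filt
    return np.real(np.fft.ifft(spectrum, axis=-1))[..., :n_det] * spacing


def fbp_reconstruct(sino: np.ndarray, geom: RadonGeometry,
                    matrix: sparse.csr_matrix | None = None,
                    filter_name: str = "ramlak", cutoff: float = 1.0) -> np.ndarray:
    """Filtered back-projection with the Ram-Lak (ramp) filter.

    ``cutoff`` expresses an optional frequency cutoff as a fraction of the
    detector Nyquist frequency (1.0 keeps the full ramp).
    """
    if filter_name != "ramlak":
        raise ValueError(f"unsupported filter {filter_name!r}")
    if matrix is None:
        matrix = build_radon_matrix(geom)
    sino = np.asarray(sino, dtype=np.float64)
    single = sino.ndim == 2
    sinos = sino.reshape(-1, geom.n_angles, geom.n_detectors)
    filtered = _ramp_filter(sinos, geom.detector_spacing, cutoff)
    flat = filtered.reshape(len(sinos), -1)
    back = (matrix.T @ flat.T).T
    scale = np.pi / geom.n_angles * geom.detector_spacing
    imgs = (scale * back).reshape(-1, geom.img_size, geom.img_size)
    return imgs[0] if single else imgs
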