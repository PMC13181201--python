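"""Parallel-beam forward projection, sparse-sampling degradation physics, and FBP.

Geometry: ``m2`` angles uniform on the half-open interval ``[0, pi)``
(angle j = j*pi/m2) and ``m1`` detector bins centered on the origin with
uniform spacing.  A sinogram column is the projection at one angle.

The sparse-sampling physics: reducing the dose at angle theta by the factor
``beta`` adds the log-domain degradation ``M'' = -ln(beta)`` to every
log-attenuation line integral at that angle (superposition with the original
sinogram).  ``measure_sparse`` implements this simulation path; the
differentiable network path instead scales sinogram columns by the encoding
(see :mod:`sparsect.encoding`).  The photon-noise option perturbs each entry
with a Gaussian whose standard deviation follows photon-counting statistics,
``sigma = 1 / sqrt(I0 * beta * exp(-M))``.

FBP follows the classical inversion: ramp-filter each detector profile in the
frequency domain (pure Ram-Lak, zero-padded to the next power of two), then
back-project with linear interpolation at ``t = x cos(theta) + y sin(theta)``
and scale by ``pi / m2``.  ``filter_sinogram`` / ``backproject`` /
``backproject_adjoint`` are the single implementations shared by the plain
:func:`fbp` and the autodiff wrapper in :mod:`sparsect.nn.ops`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantoms import Image

__all__ = [
    "Geometry",
    "Sinogram",
    "PhotonModel",
    "DegradationField",
    "BETA_FLOOR",
    "default_m1",
    "radon",
    "degradation_field",
    "measure_sparse",
    "ramp_filter",
    "filter_sinogram",
    "backproject",
    "backproject_adjoint",
    "fbp",
]

#: default floor on the per-angle dose fraction; keeps -ln(beta) bounded by 10
BETA_FLOOR = float(np.exp(-10.0))


def default_m1(n: int) -> int:
    """Smallest odd integer >= n*sqrt(2) (covers the image diagonal)."""
    m1 = int(np.ceil(n * np.sqrt(2.0)))
    return m1 if m1 % 2 == 1 else m1 + 1


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam sampling: m1 detector bins x m2 angles on [0, pi)."""

    m1: int
    m2: int
    detector_spacing: float

    def __post_init__(self):
        if self.m1 < 2 or self.m2 < 1:
            raise ValueError(f"invalid geometry m1={self.m1}, m2={self.m2}")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.m2) * np.pi / self.m2

    @property
    def detector_coords(self) -> np.ndarray:
        return (np.arange(self.m1) - (self.m1 - 1) / 2.0) * self.detector_spacing

    @classmethod
    def for_image(cls, n: int, m2: int, m1: int | None = None) -> "Geometry":
        """Geometry matched to an n x n image on [-1,1]^2: detector spacing
        equals the pixel size, m1 covers the diagonal."""
        if m1 is None:
            m1 = default_m1(n)
        return cls(m1=m1, m2=m2, detector_spacing=2.0 / n)


@dataclass(frozen=True)
class Sinogram:
    """m1 x m2 matrix of log-attenuation line integrals; column j is angle j."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.geometry.m1, self.geometry.m2):
            raise ValueError(
                f"sinogram shape {v.shape} does not match geometry "
                f"({self.geometry.m1}, {self.geometry.m2})")
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PhotonModel:
    """Incident photon count per ray; Gaussian photon-statistics noise toggle."""

    I0: float = 1e5
    noise_enabled: bool = False

    def __post_init__(self):
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")


@dataclass(frozen=True)
class DegradationField:
    """The additive log-domain term M''(theta, i) = -ln(beta), per entry."""

    values: np.ndarray
    beta_floor: float = BETA_FLOOR


def radon(image: Image, geometry: Geometry) -> Sinogram:
    """Discrete line-integral (radon) transform of an image.

    Each ray is sampled at half-pixel steps with bilinear interpolation and
    summed; linear in the image.
    """
    n = image.n
    px = image.pixel_size
    half = n * px / 2.0
    step = px / 2.0
    # sample parameter along the ray, covering the diagonal of the support
    t = np.arange(-half * np.sqrt(2), half * np.sqrt(2) + step, step)
    s = geometry.detector_coords
    out = np.empty((geometry.m1, geometry.m2))
    for j, theta in enumerate(geometry.angles):
        ct, st = np.cos(theta), np.sin(theta)
        # p(t) = s*(ct, st) + t*(-st, ct)
        x = s[:, None] * ct - t[None, :] * st
        y = s[:, None] * st + t[None, :] * ct
        # image frame: col = (x+1)/px - 0.5, row = (1-y)/px - 0.5
        col = (x + half) / px - 0.5
        row = (half - y) / px - 0.5
        vals = ndimage.map_coordinates(image.pixels, [row, col], order=1,
                                       mode="constant", cval=0.0)
        out[:, j] = vals.sum(axis=1) * step
    return Sinogram(out, geometry)


def degradation_field(encoding: np.ndarray, geometry: Geometry,
                      beta_floor: float = BETA_FLOOR) -> DegradationField:
    """Broadcast -ln(max(e_j, beta_floor)) across the detector axis."""
    e = np.asarray(encoding, dtype=np.float64).ravel()
    if e.shape[0] != geometry.m2:
        raise ValueError(f"encoding length {e.shape[0]} != m2 {geometry.m2}")
    if not (0.0 < beta_floor < 1.0):
        raise ValueError("beta_floor must lie in (0, 1)")
    col = -np.log(np.maximum(e, beta_floor))
    return DegradationField(np.broadcast_to(col, (geometry.m1, geometry.m2)).copy(),
                            beta_floor)


def measure_sparse(sinogram: Sinogram, encoding: np.ndarray,
                   photon: PhotonModel = PhotonModel(), seed: int = 0,
                   beta_floor: float = BETA_FLOOR) -> Sinogram:
    """Simulate a sparse-dose measurement of a full sinogram.

    Noise off: exact superposition, ``output = M + M''``.  Noise on: adds
    independent Gaussians with per-entry standard deviation
    ``1/sqrt(I0 * max(e_j, beta_floor) * exp(-M_ij))``.
    """
    field = degradation_field(encoding, sinogram.geometry, beta_floor)
    out = sinogram.values + field.values
    if photon.noise_enabled:
        e = np.maximum(np.asarray(encoding, dtype=np.float64).ravel(), beta_floor)
        expected_counts = photon.I0 * e[None, :] * np.exp(-sinogram.values)
        sigma = 1.0 / np.sqrt(expected_counts)
        rng = np.random.default_rng(seed)
        out = out + rng.standard_normal(out.shape) * sigma
    return Sinogram(out, sinogram.geometry)


def _next_pow2(x: int) -> int:
    return 1 << (int(x) - 1).bit_length()


def ramp_filter(m1: int, detector_spacing: float = 1.0) -> np.ndarray:
    """Discrete ramp |omega| frequency response on the FFT grid of length
    next_pow2(2*m1); zero at DC, symmetric, maximal at Nyquist."""
    if m1 < 2:
        raise ValueError("m1 must be >= 2")
    nfft = _next_pow2(2 * m1)
    freqs = np.fft.fftfreq(nfft, d=detector_spacing)
    return np.abs(freqs)


def filter_sinogram(values: np.ndarray, detector_spacing: float) -> np.ndarray:
    """Ramp-filter every column (detector profile) of an m1 x m2 array.

    Zero-pads to the FFT grid, multiplies by the |omega| response, and crops
    back.  This linear map is symmetric (real even response, zero pad/crop
    are mutual adjoints), a fact the autodiff wrapper relies on.
    """
    m1 = values.shape[0]
    resp = ramp_filter(m1, detector_spacing)
    nfft = resp.shape[0]
    padded = np.zeros((nfft,) + values.shape[1:])
    padded[:m1] = values
    filtered = np.fft.ifft(np.fft.fft(padded, axis=0) * resp[(...,) + (None,) * (values.ndim - 1)],
                           axis=0).real
    return filtered[:m1]


def _backproject_coords(geometry: Geometry, n: int, pixel_size: float):
    """Fractional detector-bin index of t = x cos + y sin for every pixel/angle."""
    half = n * pixel_size / 2.0
    x = -half + (np.arange(n) + 0.5) * pixel_size
    y = half - (np.arange(n) + 0.5) * pixel_size
    xx, yy = np.meshgrid(x, y)
    s0 = geometry.detector_coords[0]
    idx = []
    for theta in geometry.angles:
        t = xx * np.cos(theta) + yy * np.sin(theta)
        idx.append((t - s0) / geometry.detector_spacing)
    return np.stack(idx, axis=0)  # (m2, n, n)


def backproject(filtered: np.ndarray, geometry: Geometry, n: int,
                pixel_size: float | None = None) -> np.ndarray:
    """Back-project a filtered sinogram onto an n x n grid (scale pi/m2)."""
    if geometry.m2 == 0:
        raise ValueError("geometry has no angles")
    if pixel_size is None:
        pixel_size = 2.0 / n
    idx = _backproject_coords(geometry, n, pixel_size)
    m1 = geometry.m1
    lo = np.clip(np.floor(idx).astype(np.int64), 0, m1 - 1)
    hi = np.clip(lo + 1, 0, m1 - 1)
    w = np.clip(idx - lo, 0.0, 1.0)
    inside = (idx >= 0) & (idx <= m1 - 1)
    out = np.zeros((n, n))
    for j in range(geometry.m2):
        q = filtered[:, j]
        contrib = (1.0 - w[j]) * q[lo[j]] + w[j] * q[hi[j]]
        out += np.where(inside[j], contrib, 0.0)
    return out * (np.pi / geometry.m2)


def backproject_adjoint(image_grad: np.ndarray, geometry: Geometry,
                        pixel_size: float | None = None) -> np.ndarray:
    """Adjoint of :func:`backproject`: scatter an image back into sinogram bins
    with the same interpolation weights and pi/m2 scale."""
    n = image_grad.shape[0]
    if pixel_size is None:
        pixel_size = 2.0 / n
    idx = _backproject_coords(geometry, n, pixel_size)
    m1 = geometry.m1
    lo = np.clip(np.floor(idx).astype(np.int64), 0, m1 - 1)
    hi = np.clip(lo + 1, 0, m1 - 1)
    w = np.clip(idx - lo, 0.0, 1.0)
    inside = (idx >= 0) & (idx <= m1 - 1)
    out = np.zeros((m1, geometry.m2))
    g = image_grad * (np.pi / geometry.m2)
    for j in range(geometry.m2):
        gj = np.where(inside[j], g, 0.0).ravel()
        np.add.at(out[:, j], lo[j].ravel(), (1.0 - w[j]).ravel() * gj)
        np.add.at(out[:, j], hi[j].ravel(), w[j].ravel() * gj)
    return out


def fbp(sinogram: Sinogram, n: int | None = None,
        pixel_size: float | None = None) -> Image:
    """Filtered back-projection: ramp filter + linear-interpolated
    back-projection at t = x cos(theta) + y sin(theta), scaled by pi/m2.

    Linear in the sinogram.  ``n`` defaults to the largest image whose
    diagonal the detector covers, with pixel size equal to the detector
    spacing.
    """
    geo = sinogram.geometry
    if n is None:
        n = int(np.floor(geo.m1 / np.sqrt(2.0)))
    if pixel_size is None:
        pixel_size = 2.0 / n
    q = filter_sinogram(sinogram.values, geo.detector_spacing)
    recon = backproject(q, geo, n, pixel_size)
    return Image(recon, pixel_size=pixel_size)
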