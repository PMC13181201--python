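"""Synthetic attenuation phantoms with analytically known projections.

Every image lives on the same coordinate frame: pixel centers on a uniform
grid over ``[-1, 1]^2``, row index increasing downward (row 0 is the top of
the image, ``y ~ +1``).  All downstream modules (radon, FBP, the networks)
share this convention.

The random-ellipse generator stands in for real CT training data: it produces
piecewise-smooth objects with internal structure, which is the statistical
role the training set plays.  Ellipse intensities are additive attenuation
values; overlaps add before a final clip to ``[0, 1]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "Image",
    "render",
    "make_shepp_logan",
    "make_random_phantom",
    "make_dataset",
    "analytic_projection",
]


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: center and semi-axes in image coords, rotation in radians."""

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float
    intensity: float


@dataclass(frozen=True)
class PhantomSpec:
    """A phantom as a list of additive ellipses (may be empty)."""

    ellipses: tuple[Ellipse, ...] = ()

    def to_json(self) -> str:
        return json.dumps([vars(e) for e in self.ellipses])

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls(tuple(Ellipse(**d) for d in json.loads(text)))


@dataclass(frozen=True)
class Image:
    """Square n x n attenuation map with values in [0, 1].

    ``pixel_size`` defaults to 2/n so the image spans ``[-1, 1]^2``.
    """

    pixels: np.ndarray
    pixel_size: float = field(default=0.0)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"image must be square 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "pixels", px)
        if self.pixel_size <= 0:
            object.__setattr__(self, "pixel_size", 2.0 / px.shape[0])

    @property
    def n(self) -> int:
        return self.pixels.shape[0]


def pixel_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinates of pixel centers; row 0 at the top (y ~ +1)."""
    px = 2.0 / n
    x = -1.0 + (np.arange(n) + 0.5) * px
    y = 1.0 - (np.arange(n) + 0.5) * px
    return np.meshgrid(x, y)  # xx varies along columns, yy along rows


def render(spec: PhantomSpec, n: int, clip: bool = True,
           supersample: int = 4) -> Image:
    """Rasterize a spec at n x n: each pixel sums the intensities of the
    ellipses covering it, then clips to [0, 1].

    ``supersample`` subpixel samples per axis are averaged, so boundary
    pixels take partial (area-weighted) values — the partial-volume effect a
    real detector sees.  ``supersample=1`` reduces to pure center-membership.
    """
    if n < 16:
        raise ValueError(f"n must be >= 16, got {n}")
    m = n * supersample
    xx, yy = pixel_grid(m)
    fine = np.zeros((m, m), dtype=np.float64)
    for e in spec.ellipses:
        c, s = np.cos(e.rotation), np.sin(e.rotation)
        xr = (xx - e.center_x) * c + (yy - e.center_y) * s
        yr = -(xx - e.center_x) * s + (yy - e.center_y) * c
        inside = (xr / e.semi_axis_a) ** 2 + (yr / e.semi_axis_b) ** 2 <= 1.0
        fine[inside] += e.intensity
    out = fine.reshape(n, supersample, n, supersample).mean(axis=(1, 3))
    if clip:
        np.clip(out, 0.0, 1.0, out=out)
    return Image(out)


# Standard 10-ellipse head phantom (Shepp & Logan parameter table:
# intensity, a, b, x0, y0, rotation in degrees).
_SHEPP_LOGAN_TABLE = [
    (2.00, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.98, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.01, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.01, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.01, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.01, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.605, 0.0),
]


def shepp_logan_spec() -> PhantomSpec:
    """The classic head phantom, intensities rescaled so the rendered image
    spans [0, 1] (raw values lie in [0, 2]; the skull ring dominates)."""
    ells = tuple(
        Ellipse(x0, y0, a, b, np.deg2rad(rot), inten / 2.0)
        for inten, a, b, x0, y0, rot in _SHEPP_LOGAN_TABLE
    )
    return PhantomSpec(ells)


def make_shepp_logan(n: int) -> Image:
    """Render the standard 10-ellipse head phantom at n x n, values in [0, 1]."""
    if n < 16:
        raise ValueError(f"n must be >= 16, got {n}")
    # Raw Shepp-Logan summed intensities lie in [0, 2]; the /2 rescale in
    # shepp_logan_spec maps them into [0, 1] without clipping anything.
    return render(shepp_logan_spec(), n, clip=True)


#: documented uniform ranges for random phantoms
RANDOM_AXIS_RANGE = (0.05, 0.5)
RANDOM_INTENSITY_RANGE = (0.1, 0.5)
_BODY_AXIS_RANGE = (0.6, 0.9)


def make_random_phantom(n: int, k: int, seed: int) -> tuple[Image, PhantomSpec]:
    """k random ellipses; when k >= 1 the first is an enclosing "body" ellipse.

    Parameters are drawn uniformly: semi-axes from ``RANDOM_AXIS_RANGE``
    (body from a larger range), intensity from ``RANDOM_INTENSITY_RANGE``,
    rotation over [0, pi), centers inside the body.  Deterministic per seed.
    """
    if n < 16:
        raise ValueError(f"n must be >= 16, got {n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    rng = np.random.default_rng(seed)
    ells: list[Ellipse] = []
    if k >= 1:
        a = rng.uniform(*_BODY_AXIS_RANGE)
        b = rng.uniform(*_BODY_AXIS_RANGE)
        ells.append(Ellipse(0.0, 0.0, a, b, rng.uniform(0, np.pi),
                            rng.uniform(*RANDOM_INTENSITY_RANGE)))
        for _ in range(k - 1):
            aa = rng.uniform(*RANDOM_AXIS_RANGE)
            bb = rng.uniform(*RANDOM_AXIS_RANGE)
            # keep inner structure inside the body's inscribed circle
            r = 0.55 * min(a, b)
            cx, cy = rng.uniform(-r, r, size=2)
            ells.append(Ellipse(cx, cy, aa, bb, rng.uniform(0, np.pi),
                                rng.uniform(*RANDOM_INTENSITY_RANGE)))
    spec = PhantomSpec(tuple(ells))
    return render(spec, n), spec


def _derive_seed(master_seed: int, index: int) -> int:
    # stable per-item seed independent of count
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def make_dataset(count: int, n: int, k_range: tuple[int, int] = (3, 8),
                 seed: int = 0) -> list[tuple[Image, PhantomSpec]]:
    """``count`` random phantoms with per-item seeds derived from ``seed``.

    Item i uses ``make_random_phantom(n, k_i, derive(seed, i))`` where k_i is
    drawn uniformly from ``k_range`` with the same derived seed.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    lo, hi = k_range
    out = []
    for i in range(count):
        s = _derive_seed(seed, i)
        k = int(np.random.default_rng(s).integers(lo, hi + 1))
        out.append(make_random_phantom(n, k, s))
    return out


def analytic_projection(spec: PhantomSpec, theta: float, s) -> np.ndarray | float:
    """Exact line integral of a phantom spec along the ray at angle ``theta``
    and detector offset(s) ``s``.

    The ray is ``p(t) = s*(cos(theta), sin(theta)) + t*(-sin(theta), cos(theta))``;
    the value is the sum over ellipses of intensity times the chord length of
    the ray through that ellipse.  Serves as the brute-force oracle for the
    discrete radon operator.  Note: no clipping is applied, so this matches
    the rendered image only where summed intensities stay within [0, 1].
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=np.float64))
    total = np.zeros_like(s_arr)
    ct, st = np.cos(theta), np.sin(theta)
    for e in spec.ellipses:
        # offset of the ray relative to the ellipse center, in the frame
        # where the ellipse is axis-aligned
        phi = theta - e.rotation
        # distance from center to ray: project center onto detector axis
        s_rel = s_arr - (e.center_x * ct + e.center_y * st)
        # chord of an axis-aligned ellipse for a ray at angle phi, offset s_rel:
        # effective half-width w(phi)^2 = a^2 cos^2 + b^2 sin^2
        w2 = (e.semi_axis_a * np.cos(phi)) ** 2 + (e.semi_axis_b * np.sin(phi)) ** 2
        inside = s_rel**2 < w2
        chord = np.zeros_like(s_rel)
        chord[inside] = (2.0 * e.semi_axis_a * e.semi_axis_b
                         * np.sqrt(w2 - s_rel[inside] ** 2) / w2)
        total += e.intensity * chord
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(total[0])
    return total
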