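"""Autodiff wrappers around the tomography kernels.

Filtering and back-projection are linear maps; their backward passes are the
adjoint maps, implemented once in :mod:`sparsect.tomography` and reused here.
The ramp-filter map is symmetric (real, even frequency response with
zero-pad/crop), so its adjoint is itself.
"""

from __future__ import annotations

from .. import tomography as tg
from .autodiff import Tensor

__all__ = ["filter_sinogram_t", "backproject_t", "fbp_t"]


def filter_sinogram_t(sino: Tensor, detector_spacing: float) -> Tensor:
    def backward(g):
        sino._accum(tg.filter_sinogram(g, detector_spacing))
    return Tensor._make(tg.filter_sinogram(sino.data, detector_spacing),
                        (sino,), backward)


def backproject_t(filtered: Tensor, geometry: tg.Geometry, n: int,
                  pixel_size: float | None = None) -> Tensor:
    def backward(g):
        filtered._accum(tg.backproject_adjoint(g, geometry, pixel_size))
    return Tensor._make(tg.backproject(filtered.data, geometry, n, pixel_size),
                        (filtered,), backward)


def fbp_t(sino: Tensor, geometry: tg.Geometry, n: int,
          pixel_size: float | None = None) -> Tensor:
    """Differentiable FBP: the same filter + back-project kernels as
    :func:`sparsect.tomography.fbp`."""
    return backproject_t(filter_sinogram_t(sino, geometry.detector_spacing),
                         geometry, n, pixel_size)
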