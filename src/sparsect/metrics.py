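"""Image-quality metrics (MSE, PSNR, SSIM) and dose-difference tracking.

All metrics assume the [0, 1] dynamic range of the phantoms (``data_range``
defaults to 1 and is echoed in every report).  SSIM uses the standard
Gaussian-window parameters (11x11 window, sigma 1.5, K1=0.01, K2=0.03) via
scikit-image.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .encoding import DoseTarget, ProjectionEncoding, dose_fraction

__all__ = ["MetricsReport", "mse", "psnr", "ssim", "dose_difference",
           "evaluate_pair"]


def _as_array(x) -> np.ndarray:
    if hasattr(x, "pixels"):
        return x.pixels
    if hasattr(x, "values"):
        return x.values
    return np.asarray(x, dtype=np.float64)


def mse(a, b) -> float:
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(a, b, data_range: float = 1.0) -> float:
    """10 log10(range^2 / mse); +inf for identical inputs."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / err)


def ssim(a, b, data_range: float = 1.0) -> float:
    """Mean local SSIM, 11x11 Gaussian window sigma=1.5, K1=0.01, K2=0.03."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError(f"image smaller than the 11x11 SSIM window: {a.shape}")
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def dose_difference(encoding: ProjectionEncoding | np.ndarray,
                    target: DoseTarget) -> float:
    """|dose_fraction(e) - gamma_l|."""
    return abs(dose_fraction(encoding) - target.gamma_l)


@dataclass(frozen=True)
class MetricsReport:
    ssim: float
    psnr: float
    mse: float
    data_range: float = 1.0
    dose_fraction: float | None = None
    dose_difference: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def evaluate_pair(reconstruction, reference, data_range: float = 1.0,
                  encoding: ProjectionEncoding | None = None,
                  target: DoseTarget | None = None) -> MetricsReport:
    """The evaluation triple on one image pair, plus dose tracking when an
    encoding is in scope."""
    df = dose_fraction(encoding) if encoding is not None else None
    dd = dose_difference(encoding, target) \
        if encoding is not None and target is not None else None
    return MetricsReport(ssim=ssim(reconstruction, reference, data_range),
                         psnr=psnr(reconstruction, reference, data_range),
                         mse=mse(reconstruction, reference),
                         data_range=data_range,
                         dose_fraction=df, dose_difference=dd)
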