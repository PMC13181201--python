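"""Scikit-learn-style front end for the whole pipeline.

``SparseViewReconstructor`` is an estimator: ``fit`` runs the three-step
training on a stack of ground-truth images (or on internally generated
phantoms), ``transform`` maps complete sinograms — or images, which are
first forward-projected — to reconstructed images through the learned
encoder, sinogram-recovery network, FBP, and image-restoration network.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import tomography as tg
from .networks import joint_forward
from .nn import Tensor
from .phantoms import Image
from .training import TrainingConfig, build_dataset, run_joint_training

__all__ = ["SparseViewReconstructor"]

_CONFIG_FIELDS = [f.name for f in dataclasses.fields(TrainingConfig)]


class SparseViewReconstructor(TransformerMixin, BaseEstimator):
    """Learned sparse-view CT acquisition + dual-domain reconstruction.

    Parameters mirror :class:`sparsect.training.TrainingConfig`; notably
    ``gamma_l`` (target dose fraction), ``n`` (image size, divisible by 16),
    ``m2`` (number of projection angles) and the training budget.

    Fitted attributes (trailing underscore): ``encoder_``, ``proj_net_``,
    ``image_net_``, ``history_step2_``, ``history_step3_``, ``report_``.
    """

    def __init__(self, gamma_l: float = 0.4, lr: float = 1e-5,
                 epochs_step2: int = 30, epochs_step3: int = 25,
                 batch_size: int = 4, dose_weight: float = 1.0, seed: int = 0,
                 n: int = 64, m2: int = 60, m1: int | None = None,
                 count: int = 200, hidden: int = 256, channels: int = 64,
                 base_width: int = 32, noise_enabled: bool = False):
        self.gamma_l = gamma_l
        self.lr = lr
        self.epochs_step2 = epochs_step2
        self.epochs_step3 = epochs_step3
        self.batch_size = batch_size
        self.dose_weight = dose_weight
        self.seed = seed
        self.n = n
        self.m2 = m2
        self.m1 = m1
        self.count = count
        self.hidden = hidden
        self.channels = channels
        self.base_width = base_width
        self.noise_enabled = noise_enabled

    def _config(self) -> TrainingConfig:
        kwargs = {k: v for k, v in self.get_params().items()
                  if k in _CONFIG_FIELDS}
        return TrainingConfig(**kwargs)

    def fit(self, X=None, y=None):
        """Run the three training steps.

        ``X``: optional (N, n, n) stack of ground-truth images in [0, 1];
        when omitted, ``count`` random-ellipse phantoms are generated.
        """
        config = self._config()
        if X is None:
            result = run_joint_training(config)
        else:
            X = np.asarray(X, dtype=np.float64)
            if X.ndim != 3 or X.shape[1] != self.n or X.shape[2] != self.n:
                raise ValueError(
                    f"X must be (N, {self.n}, {self.n}), got {X.shape}")
            config = dataclasses.replace(config, count=X.shape[0])
            result = self._fit_images(config, X)
        self.encoder_ = result["encoder"]
        self.proj_net_ = result["proj_net"]
        self.image_net_ = result["image_net"]
        self.history_step2_ = result["history_step2"]
        self.history_step3_ = result["history_step3"]
        self.report_ = result["report"]
        self.geometry_ = config.geometry
        return self

    def _fit_images(self, config: TrainingConfig, X: np.ndarray):
        from .training import (_eval_images, _fbp_inputs, _split, train_step2,
                               train_step3)
        geo = config.geometry
        sinos = np.stack([tg.radon(Image(x), geo).values for x in X])
        encoder, proj_net, hist2 = train_step2(config, X, sinos)
        degraded = _fbp_inputs(config, sinos, encoder, proj_net)
        image_net, hist3 = train_step3(config, X, degraded)
        _, hold = _split(config, X.shape[0])
        s, p, m = _eval_images(image_net, degraded[hold], X[hold])
        codes = encoder.forward(Tensor(sinos[hold][:, None]), train=False)
        report = {"ssim": s, "psnr": p, "mse": m,
                  "dose_fraction": float(codes.data.mean(axis=-1).mean()),
                  "dose_difference": float(np.abs(
                      codes.data.mean(axis=-1) - config.gamma_l).mean())}
        return {"encoder": encoder, "proj_net": proj_net,
                "image_net": image_net, "history_step2": hist2,
                "history_step3": hist3, "report": report}

    def transform(self, X) -> np.ndarray:
        """Reconstruct from (N, m1, m2) sinograms or (N, n, n) images."""
        if not hasattr(self, "encoder_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float64)
        geo = self.geometry_
        if X.ndim != 3:
            raise ValueError(f"expected a 3-D stack, got shape {X.shape}")
        if X.shape[1:] == (self.n, self.n):
            X = np.stack([tg.radon(Image(x), geo).values for x in X])
        if X.shape[1:] != (geo.m1, geo.m2):
            raise ValueError(
                f"inputs must be ({self.n},{self.n}) images or "
                f"({geo.m1},{geo.m2}) sinograms, got {X.shape[1:]}")
        out = np.empty((X.shape[0], self.n, self.n))
        for start in range(0, X.shape[0], self.batch_size):
            batch = Tensor(X[start:start + self.batch_size][:, None])
            _, _, final = joint_forward(self.encoder_, self.proj_net_,
                                        self.image_net_, batch, geo, self.n)
            out[start:start + batch.data.shape[0]] = \
                np.clip(final.data[:, 0], 0.0, 1.0)
        return out
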