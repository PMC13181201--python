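"""Neural layers over the autodiff engine: dense, conv, transposed conv,
batch norm, pooling and fixed bilinear upsampling.

Weights use He-uniform initialization (fan-in), seeded per layer from the
generator handed to the module constructor, so a whole network is a pure
function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "Conv2d", "ConvTranspose2d", "BatchNorm1d",
           "BilinearUp2", "he_uniform"]


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
               fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Tiny parameter container: children and Parameters found by attribute scan."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays that define the module (parameters + buffers), in a
        stable order; used for checkpointing and freeze checks."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state mismatch: {len(own)} arrays expected, "
                             f"got {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"array shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Parameter(he_uniform(rng, (in_features, out_features),
                                           in_features))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 zero_init: bool = False):
        fan_in = in_ch * kernel * kernel
        w = np.zeros((out_ch, in_ch, kernel, kernel)) if zero_init else \
            he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_uniform(rng, (in_ch, out_ch, kernel, kernel),
                                           fan_in))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, self.stride,
                                  self.padding)


class BatchNorm1d(Module):
    """Per-component batch normalization with learnable scale/shift and
    running statistics (momentum 0.1); eval mode uses the running stats."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps).sqrt()
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.ravel()
            # unbiased variance for the running estimate, as torch does
            b = x.data.shape[0]
            corr = b / max(b - 1, 1)
            self.running_var *= 1 - m
            self.running_var += m * var.data.ravel() * corr
        else:
            xhat = (x - self.running_mean) * \
                (1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


#: separable factor-2 bilinear interpolation kernel (align_corners=False)
_BILINEAR_K = np.array([0.25, 0.75, 0.75, 0.25])


class BilinearUp2(Module):
    """Fixed (non-trainable) 2x bilinear upsampling, implemented as a
    depthwise transposed convolution with the separable [1,3,3,1]/4 kernel."""

    def __init__(self):
        k = np.outer(_BILINEAR_K, _BILINEAR_K)
        self._weight = Tensor(k[None, None])  # (1,1,4,4), not a Parameter

    def __call__(self, x: Tensor) -> Tensor:
        n_, c, h, w = x.data.shape
        flat = x.reshape(n_ * c, 1, h, w)
        up = flat.conv_transpose2d(self._weight, stride=2, padding=1)
        return up.reshape(n_, c, 2 * h, 2 * w)
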