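"""The two reconstruction networks and their coupling through FBP.

``SinogramNet`` (G2') recovers the complete sinogram from its
encoding-weighted sparse version: five Conv+ReLU stages followed by five
Deconv+ReLU stages, 64 channels, 3x3 kernels, stride 1, no padding (the
deconv stack exactly undoes the conv shrinkage), with a global residual
connection — at zero weights the network is the identity.

``ImageNet`` (G2'') restores image-domain detail in the FBP of the recovered
sinogram.  It is U-Net-like: a two-conv stem at width 32, four 2x
downsampling modules (maxpool + two convs, width doubling to 512), three 2x
upsampling modules (bilinear interpolation + two convs) with skip fusion at
the matching scales (each skip path is three Conv+ReLU stages), a 1-channel
bridging conv at half resolution, and a 1-channel DBPN 2x super-resolution
head back to full resolution.  Unlike G2', its convs pad by 1 so the skip
shapes align.

``joint_forward`` chains G1 -> columnwise encoding -> G2' -> FBP -> G2'' and
returns all intermediates; every stage is differentiable, so a loss on the
final image reaches the encoder weights.
"""

from __future__ import annotations

import numpy as np

from .encoding import SamplingEncoder, apply_encoding
from .nn import (BilinearUp2, Conv2d, ConvTranspose2d, Module, Tensor, concat,
                 fbp_t, stack)
from .tomography import Geometry

__all__ = ["SinogramNet", "ImageNet", "DBPN", "joint_forward"]

_MIN_SINO = 11  # five unpadded 3x3 convs shrink each axis by 10


class SinogramNet(Module):
    """G2': global-residual conv/deconv stack on 1-channel sinograms."""

    def __init__(self, channels: int = 64, depth: int = 5, seed: int = 0,
                 zero_init: bool = False):
        rng = np.random.default_rng(seed)
        self.convs = [Conv2d(1 if i == 0 else channels, channels, 3, rng,
                             zero_init=zero_init)
                      for i in range(depth)]
        self.deconvs = [ConvTranspose2d(channels,
                                        1 if i == depth - 1 else channels,
                                        3, rng)
                        for i in range(depth)]
        if zero_init:
            for d in self.deconvs:
                d.weight.data[...] = 0.0
        self.depth = depth

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[-2:]
        need = 2 * self.depth + 1
        if h < need or w < need:
            raise ValueError(
                f"sinogram spatial dims must be >= {need} for {self.depth} "
                f"unpadded 3x3 convs, got {(h, w)}")
        out = x
        for c in self.convs:
            out = c(out).relu()
        for d in self.deconvs:
            out = d(out).relu()
        return x + out


class _UpProjection(Module):
    """DBPN up-projection unit (kernel 6, stride 2, padding 2 for 2x)."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.up1 = ConvTranspose2d(ch, ch, 6, rng, stride=2, padding=2)
        self.down = Conv2d(ch, ch, 6, rng, stride=2, padding=2)
        self.up2 = ConvTranspose2d(ch, ch, 6, rng, stride=2, padding=2)

    def __call__(self, lo: Tensor) -> Tensor:
        h0 = self.up1(lo).relu()
        l0 = self.down(h0).relu()
        return h0 + self.up2(l0 - lo).relu()


class _DownProjection(Module):
    def __init__(self, ch: int, rng: np.random.Generator):
        self.down1 = Conv2d(ch, ch, 6, rng, stride=2, padding=2)
        self.up = ConvTranspose2d(ch, ch, 6, rng, stride=2, padding=2)
        self.down2 = Conv2d(ch, ch, 6, rng, stride=2, padding=2)

    def __call__(self, hi: Tensor) -> Tensor:
        l0 = self.down1(hi).relu()
        h0 = self.up(l0).relu()
        return l0 + self.down2(h0 - hi).relu()


class DBPN(Module):
    """1-channel 2x super-resolution head: feature conv, T alternating
    up-/down-projection units, reconstruction conv over the up outputs."""

    def __init__(self, features: int = 32, t_units: int = 2, seed: int = 0,
                 zero_init_recon: bool = False):
        rng = np.random.default_rng(seed)
        self.feat = Conv2d(1, features, 3, rng, padding=1)
        self.ups = [_UpProjection(features, rng) for _ in range(t_units)]
        self.downs = [_DownProjection(features, rng) for _ in range(t_units - 1)]
        self.recon = Conv2d(features * t_units, 1, 3, rng, padding=1,
                            zero_init=zero_init_recon)
        self.t_units = t_units

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != 1:
            raise ValueError(
                f"DBPN expects a 1-channel NCHW input, got shape {x.data.shape}")
        lo = self.feat(x).relu()
        highs = []
        for i, up in enumerate(self.ups):
            hi = up(lo)
            highs.append(hi)
            if i < len(self.downs):
                lo = self.downs[i](hi)
        return self.recon(concat(highs, axis=1))


class _ConvBlock(Module):
    """Two 3x3 Conv+ReLU stages (padding 1)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()


class _SkipBlock(Module):
    """Three Conv+ReLU stages, channel-preserving."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.convs = [Conv2d(ch, ch, 3, rng, padding=1) for _ in range(3)]

    def __call__(self, x: Tensor) -> Tensor:
        for c in self.convs:
            x = c(x).relu()
        return x


class ImageNet(Module):
    """G2'': U-Net-like detail restoration with a DBPN 2x head.

    Encoder widths 32 / 64 / 128 / 256 / 512 at scales 1, 1/2, 1/4, 1/8,
    1/16; skips at 1/2, 1/4, 1/8 (the 1/16 bottleneck has none); decoder
    fuses skips by channel concatenation.

    The network is a global-residual detail *repairer*: it outputs the input
    plus a learned correction, and the DBPN reconstruction conv is
    zero-initialized, so an untrained G2'' is exactly the identity.  This
    mirrors the additive (superposition) structure of the degradation: the
    FBP intermediate already carries the object's profile, and G2'' only has
    to learn the residual detail.
    """

    def __init__(self, base: int = 32, dbpn_features: int = 32,
                 dbpn_t: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = [base, base * 2, base * 4, base * 8, base * 16]  # 32..512
        self.stem = _ConvBlock(1, w[0], rng)
        self.downs = [_ConvBlock(w[i], w[i + 1], rng) for i in range(4)]
        self.skips = [_SkipBlock(w[1], rng), _SkipBlock(w[2], rng),
                      _SkipBlock(w[3], rng)]
        # up path: 1/16 -> 1/8 -> 1/4 -> 1/2
        self.up_blocks = [_ConvBlock(w[4] + w[3], w[3], rng),
                          _ConvBlock(w[3] + w[2], w[2], rng),
                          _ConvBlock(w[2] + w[1], w[1], rng)]
        self.upsample = BilinearUp2()
        self.bridge = Conv2d(w[1], 1, 3, rng, padding=1)
        self.dbpn = DBPN(dbpn_features, dbpn_t, seed=int(rng.integers(2**31)),
                         zero_init_recon=True)

    def __call__(self, x: Tensor) -> Tensor:
        h, w_ = x.data.shape[-2:]
        if h % 16 or w_ % 16 or h != w_:
            raise ValueError(
                f"image size must be square and divisible by 16, got {(h, w_)}")
        f0 = self.stem(x)                       # full res, 32
        enc = [f0]
        cur = f0
        for blk in self.downs:                  # 1/2 .. 1/16
            cur = blk(cur.maxpool2())
            enc.append(cur)
        # enc[1..3] are the skip sources (1/2, 1/4, 1/8)
        cur = enc[4]
        for i, blk in enumerate(self.up_blocks):
            cur = self.upsample(cur)
            skip = self.skips[2 - i](enc[3 - i])
            cur = blk(concat([skip, cur], axis=1))
        half = self.bridge(cur)                 # 1 channel at 1/2 res
        return x + self.dbpn(half)


def joint_forward(encoder: SamplingEncoder, proj_net: SinogramNet,
                  image_net: ImageNet | None, sino_batch: Tensor,
                  geometry: Geometry, n: int, train: bool = False):
    """Full pipeline on a batch (N, 1, m1, m2) of complete sinograms.

    Returns ``(codes (N,m2), recovered sinograms (N,1,m1,m2), images
    (N,1,n,n))``; with ``image_net=None`` the FBP intermediate is returned as
    the final image (the G1 o G2' ablation arm).
    """
    codes = encoder.forward(sino_batch, train=train)
    sparse = apply_encoding(sino_batch, codes)
    recovered = proj_net(sparse)
    imgs = []
    for i in range(sino_batch.data.shape[0]):
        imgs.append(fbp_t(recovered[i, 0], geometry, n))
    fbp_images = stack(imgs)[:, None]
    if image_net is None:
        return codes, recovered, fbp_images
    return codes, recovered, image_net(fbp_images)
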