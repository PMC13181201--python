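"""Three-step training of the joint reconstruction model, plus the
ablation and sampling-comparison experiment drivers.

Step 1 calibrates the biased-ReLU shift ``lambda'`` by bisection so the
encoder's mean dose matches the target ``gamma_l``.  Step 2 trains
G1 o G2' (encoder + sinogram recovery) with an MSE data term plus an
absolute-deviation dose penalty; Step 3 freezes G1 o G2' and trains the
image-domain network G2'' with plain MSE on (FBP of recovered sinogram,
ground truth) pairs.

All randomness flows from ``TrainingConfig.seed``; per-subsystem seeds are
derived, so runs are bit-reproducible on fixed hardware.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import phantoms as ph
from . import tomography as tg
from .encoding import (DoseTarget, ProjectionEncoding, SamplingEncoder,
                       apply_encoding, dose_fraction, equal_interval_encoding)
from .metrics import evaluate_pair, mse as mse_np, psnr as psnr_np, ssim as ssim_np
from .networks import ImageNet, SinogramNet, joint_forward
from .nn import Module, Tensor

__all__ = [
    "TrainingConfig", "TrainingHistory", "Adam",
    "loss_projection", "loss_image", "calibrate_lambda",
    "build_dataset", "train_step2", "train_step3",
    "run_joint_training", "run_ablation", "compare_sampling",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainingConfig:
    """Everything a run needs; defaults follow the reference setup
    (lr 1e-5, 3x3 kernels, batch 4, dose targets in {0.2, 0.3, 0.4})."""

    gamma_l: float = 0.4
    lr: float = 1e-5
    epochs_step2: int = 30
    epochs_step3: int = 25
    batch_size: int = 4
    dose_weight: float = 1.0
    seed: int = 0
    n: int = 64
    m2: int = 60
    m1: int | None = None
    count: int = 200
    k_range: tuple[int, int] = (3, 8)
    hidden: int = 256
    channels: int = 64
    base_width: int = 32
    noise_enabled: bool = False
    I0: float = 1e5
    holdout_fraction: float = 0.2

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs_step2 < 1 or self.epochs_step3 < 1:
            raise ValueError("epoch budgets must be >= 1")
        if self.n % 16:
            raise ValueError(f"n must be divisible by 16, got {self.n}")
        DoseTarget(self.gamma_l)  # validates range

    @property
    def geometry(self) -> tg.Geometry:
        return tg.Geometry.for_image(self.n, self.m2, self.m1)

    @property
    def target(self) -> DoseTarget:
        return DoseTarget(self.gamma_l)

    def derive_seed(self, label: str) -> int:
        h = np.frombuffer(label.encode(), dtype=np.uint8)
        return int(np.random.SeedSequence([self.seed, *h.tolist()])
                   .generate_state(1)[0] % (2**31))


@dataclass
class TrainingHistory:
    """One record per completed epoch."""

    loss: list[float] = field(default_factory=list)
    dose_difference: list[float] = field(default_factory=list)
    ssim: list[float] = field(default_factory=list)
    psnr: list[float] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)

    def to_csv(self) -> str:
        lines = ["epoch,loss,dose_diff,ssim,psnr,mse"]
        for i in range(len(self.loss)):
            def get(lst):
                return f"{lst[i]:.8g}" if i < len(lst) else ""
            lines.append(f"{i},{get(self.loss)},{get(self.dose_difference)},"
                         f"{get(self.ssim)},{get(self.psnr)},{get(self.mse)}")
        return "\n".join(lines) + "\n"


class Adam:
    """Plain Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# -- losses ------------------------------------------------------------------


def loss_projection(m_rec: Tensor, m_full: Tensor, codes: Tensor,
                    target: DoseTarget, dose_weight: float = 1.0) -> Tensor:
    """MSE(M_rec, M) + w_d * mean_i |dose(e_i) - gamma_l| (Step-2 loss)."""
    if m_rec.data.shape != m_full.data.shape:
        raise ValueError(f"shape mismatch {m_rec.data.shape} vs "
                         f"{m_full.data.shape}")
    if dose_weight < 0:
        raise ValueError("dose_weight must be >= 0")
    diff = m_rec - m_full
    data_term = (diff * diff).mean()
    dose = dose_fraction(codes)  # (N,) Tensor
    penalty = (dose - target.gamma_l).abs().mean()
    return data_term + dose_weight * penalty


def loss_image(x_rec: Tensor, x_true: Tensor) -> Tensor:
    """Plain MSE (Step-3 loss)."""
    if x_rec.data.shape != x_true.data.shape:
        raise ValueError(f"shape mismatch {x_rec.data.shape} vs "
                         f"{x_true.data.shape}")
    diff = x_rec - x_true
    return (diff * diff).mean()


# -- step 1: lambda' calibration --------------------------------------------


def calibrate_lambda(encoder: SamplingEncoder, calibration_batch,
                     target: DoseTarget, tol: float = 0.01,
                     max_iter: int = 60) -> tuple[float, float]:
    """Bisect lambda' in [0, lambda_max] until the batch-mean dose is within
    ``tol`` of gamma_l.  Returns (lambda', achieved dose) and sets the
    encoder's bias.  Uses the batch's own BN statistics, purely functionally
    (running statistics are not touched).
    """
    batch = list(calibration_batch)
    if not batch:
        raise ValueError("calibration batch must be non-empty")
    vals = np.stack([s.values for s in batch]).reshape(len(batch), -1)
    h = np.maximum(vals @ encoder.fc1.weight.data + encoder.fc1.bias.data, 0.0)
    v = h @ encoder.fc2.weight.data + encoder.fc2.bias.data
    mu = v.mean(axis=0)
    sd = np.sqrt(v.var(axis=0) + encoder.bn.eps)
    vhat = (v - mu) / sd * encoder.bn.gamma.data + encoder.bn.beta.data

    def dose(lam: float) -> float:
        return float(np.minimum(np.maximum(vhat - lam, 0.0), 1.0).mean())

    d0 = dose(0.0)
    if d0 <= target.gamma_l:
        # dose is non-increasing in lambda'; the bracket cannot raise it
        if abs(d0 - target.gamma_l) < tol:
            encoder.lambda_bias = 0.0
            return 0.0, d0
        raise ValueError(
            f"dose target {target.gamma_l} unreachable: achievable range is "
            f"[0, {d0:.4f}] for lambda' >= 0")
    lo, hi = 0.0, float(vhat.max())
    lam = 0.0
    for _ in range(max_iter):
        lam = 0.5 * (lo + hi)
        d = dose(lam)
        if abs(d - target.gamma_l) < tol:
            break
        if d > target.gamma_l:
            lo = lam
        else:
            hi = lam
    achieved = dose(lam)
    if abs(achieved - target.gamma_l) >= tol:
        raise ValueError(
            f"calibration did not converge: |{achieved:.4f} - "
            f"{target.gamma_l}| >= {tol}")
    encoder.lambda_bias = float(lam)
    return float(lam), achieved


# -- data --------------------------------------------------------------------


def build_dataset(config: TrainingConfig):
    """Phantoms + their (optionally noisy) sinograms; returns
    (images (N,n,n), sinograms (N,m1,m2), geometry)."""
    geo = config.geometry
    data = ph.make_dataset(config.count, config.n, config.k_range,
                           seed=config.derive_seed("phantoms"))
    images = np.stack([img.pixels for img, _ in data])
    sinos = []
    photon = tg.PhotonModel(I0=config.I0, noise_enabled=config.noise_enabled)
    for i, (img, _) in enumerate(data):
        s = tg.radon(img, geo)
        if config.noise_enabled:
            s = tg.measure_sparse(s, np.ones(geo.m2), photon,
                                  seed=config.derive_seed(f"noise{i}"))
        sinos.append(s.values)
    return images, np.stack(sinos), geo


def _split(config: TrainingConfig, count: int) -> tuple[np.ndarray, np.ndarray]:
    n_hold = max(1, int(round(count * config.holdout_fraction)))
    idx = np.arange(count)
    return idx[:-n_hold], idx[-n_hold:]


# -- step 2 ------------------------------------------------------------------


def train_step2(config: TrainingConfig, images: np.ndarray, sinos: np.ndarray,
                encoder: SamplingEncoder | None = None,
                proj_net: SinogramNet | None = None,
                fixed_encoding: ProjectionEncoding | None = None):
    """Train G1 o G2' (or G2' alone under a fixed sampling scheme).

    Returns (encoder, proj_net, history).  The dose-difference entry of the
    history is the held-out eval-mode value after each epoch.
    """
    geo = config.geometry
    if encoder is None:
        encoder = SamplingEncoder(geo.m1, config.m2, config.hidden,
                                  seed=config.derive_seed("encoder"))
    if proj_net is None:
        proj_net = SinogramNet(config.channels,
                               seed=config.derive_seed("projnet"))
    train_idx, hold_idx = _split(config, sinos.shape[0])
    target = config.target

    if fixed_encoding is None:
        calib = [tg.Sinogram(sinos[i], geo) for i in train_idx[:16]]
        calibrate_lambda(encoder, calib, target)
        params = encoder.parameters() + proj_net.parameters()
    else:
        params = proj_net.parameters()
    opt = Adam(params, config.lr)
    rng = np.random.default_rng(config.derive_seed("shuffle2"))
    history = TrainingHistory()

    for epoch in range(config.epochs_step2):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            m_full = Tensor(sinos[idx][:, None])
            if fixed_encoding is None:
                codes, codes_pre = encoder.forward(m_full, train=True,
                                                   return_preclamp=True)
            else:
                codes = Tensor(np.tile(fixed_encoding.e, (len(idx), 1)))
                codes_pre = codes
            sparse = apply_encoding(m_full, codes)
            m_rec = proj_net(sparse)
            loss = loss_projection(m_rec, m_full, codes_pre, target,
                                   config.dose_weight)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"step-2 loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.loss.append(float(np.mean(losses)))
        history.dose_difference.append(
            _eval_dose_diff(encoder, sinos[hold_idx], target, fixed_encoding))
    return encoder, proj_net, history


def _eval_dose_diff(encoder, hold_sinos, target, fixed_encoding) -> float:
    if fixed_encoding is not None:
        return abs(dose_fraction(fixed_encoding) - target.gamma_l)
    codes = encoder.forward(Tensor(hold_sinos[:, None]), train=False)
    return float(np.abs(codes.data.mean(axis=-1) - target.gamma_l).mean())


# -- step 3 ------------------------------------------------------------------


def _fbp_inputs(config: TrainingConfig, sinos: np.ndarray,
                encoder: SamplingEncoder | None, proj_net: SinogramNet | None,
                fixed_encoding: ProjectionEncoding | None = None) -> np.ndarray:
    """Frozen forward pass: FBP of the (recovered) sparse sinograms."""
    geo = config.geometry
    out = np.empty((sinos.shape[0], config.n, config.n))
    for start in range(0, sinos.shape[0], config.batch_size):
        sl = slice(start, start + config.batch_size)
        batch = Tensor(sinos[sl][:, None])
        if fixed_encoding is not None:
            codes = Tensor(np.tile(fixed_encoding.e,
                                   (batch.data.shape[0], 1)))
        else:
            codes = encoder.forward(batch, train=False)
        sparse = apply_encoding(batch, codes)
        rec = proj_net(sparse) if proj_net is not None else sparse
        for b in range(rec.data.shape[0]):
            sino = tg.Sinogram(rec.data[b, 0], geo)
            out[start + b] = tg.fbp(sino, config.n).pixels
    return out


def train_step3(config: TrainingConfig, images: np.ndarray,
                degraded: np.ndarray, image_net: ImageNet | None = None):
    """Train G2'' on (FBP image, ground truth) pairs; the step-2 parameters
    that produced ``degraded`` are untouched by construction."""
    if image_net is None:
        image_net = ImageNet(config.base_width,
                             seed=config.derive_seed("imagenet"))
    train_idx, hold_idx = _split(config, images.shape[0])
    opt = Adam(image_net.parameters(), config.lr)
    rng = np.random.default_rng(config.derive_seed("shuffle3"))
    history = TrainingHistory()

    for epoch in range(config.epochs_step3):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x_rec = image_net(Tensor(degraded[idx][:, None]))
            loss = loss_image(x_rec, Tensor(images[idx][:, None]))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"step-3 loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.loss.append(float(np.mean(losses)))
        s, p, m = _eval_images(image_net, degraded[hold_idx], images[hold_idx])
        history.ssim.append(s)
        history.psnr.append(p)
        history.mse.append(m)
    return image_net, history


def _eval_images(image_net, degraded, references) -> tuple[float, float, float]:
    ss, ps, ms = [], [], []
    for i in range(degraded.shape[0]):
        out = image_net(Tensor(degraded[i][None, None])).data[0, 0] \
            if image_net is not None else degraded[i]
        out = np.clip(out, 0.0, 1.0)
        ss.append(ssim_np(out, references[i]))
        ps.append(psnr_np(out, references[i]))
        ms.append(mse_np(out, references[i]))
    return float(np.mean(ss)), float(np.mean(ps)), float(np.mean(ms))


# -- end-to-end drivers -------------------------------------------------------


def run_joint_training(config: TrainingConfig):
    """Steps 1-3 in order; returns a result dict with the trained modules,
    both histories, and a held-out evaluation report."""
    images, sinos, geo = build_dataset(config)
    encoder, proj_net, hist2 = train_step2(config, images, sinos)
    frozen = [a.copy() for a in encoder.state_arrays() + proj_net.state_arrays()]
    degraded = _fbp_inputs(config, sinos, encoder, proj_net)
    image_net, hist3 = train_step3(config, images, degraded)
    after = encoder.state_arrays() + proj_net.state_arrays()
    if not all(np.array_equal(a, b) for a, b in zip(frozen, after)):
        raise AssertionError("step 3 mutated frozen step-2 parameters")

    _, hold_idx = _split(config, images.shape[0])
    codes = encoder.forward(Tensor(sinos[hold_idx][:, None]), train=False)
    s, p, m = _eval_images(image_net, degraded[hold_idx], images[hold_idx])
    report = {
        "ssim": s, "psnr": p, "mse": m,
        "dose_fraction": float(codes.data.mean(axis=-1).mean()),
        "dose_difference": float(np.abs(codes.data.mean(axis=-1)
                                        - config.gamma_l).mean()),
    }
    return {"encoder": encoder, "proj_net": proj_net, "image_net": image_net,
            "history_step2": hist2, "history_step3": hist3, "report": report,
            "config": config}


def run_ablation(config: TrainingConfig):
    """Three arms under identical budgets: G1oG2' (FBP of recovered
    sinogram), G1oG2'' (FBP of encoded sinogram into a fresh G2''), and the
    full G1oG2'oG2''.  Returns {arm: {ssim, psnr, mse}}."""
    images, sinos, geo = build_dataset(config)
    encoder, proj_net, _ = train_step2(config, images, sinos)
    _, hold_idx = _split(config, images.shape[0])

    # arm 1: no image net
    deg_full = _fbp_inputs(config, sinos, encoder, proj_net)
    s1, p1, m1 = _eval_images(None, np.clip(deg_full[hold_idx], None, None),
                              images[hold_idx])

    # arm 2: no sinogram net — G2'' sees FBP of the raw encoded sinogram
    deg_enc = _fbp_inputs(config, sinos, encoder, None)
    net_b, _ = train_step3(config, images, deg_enc)
    s2, p2, m2 = _eval_images(net_b, deg_enc[hold_idx], images[hold_idx])

    # arm 3: full model
    net_c, _ = train_step3(config, images, deg_full)
    s3, p3, m3 = _eval_images(net_c, deg_full[hold_idx], images[hold_idx])

    return {
        "G1.G2p": {"ssim": s1, "psnr": p1, "mse": m1},
        "G1.G2i": {"ssim": s2, "psnr": p2, "mse": m2},
        "G1.G2p.G2i": {"ssim": s3, "psnr": p3, "mse": m3},
    }


def compare_sampling(config: TrainingConfig):
    """Learned encoding vs equal-interval sampling at matched dose; both arms
    train G2' with the same budget and are scored by held-out SSIM of the
    FBP of the recovered sinogram.  Returns {arm: {ssim, ..., dose_fraction}}."""
    images, sinos, geo = build_dataset(config)
    _, hold_idx = _split(config, images.shape[0])

    enc, net_l, _ = train_step2(config, images, sinos)
    deg_l = _fbp_inputs(config, sinos, enc, net_l)
    s_l, p_l, m_l = _eval_images(None, deg_l[hold_idx], images[hold_idx])
    codes = enc.forward(Tensor(sinos[hold_idx][:, None]), train=False)
    dose_l = float(codes.data.mean(axis=-1).mean())

    fixed = equal_interval_encoding(config.m2, config.target)
    _, net_e, _ = train_step2(config, images, sinos, fixed_encoding=fixed)
    deg_e = _fbp_inputs(config, sinos, None, net_e, fixed_encoding=fixed)
    s_e, p_e, m_e = _eval_images(None, deg_e[hold_idx], images[hold_idx])

    return {
        "learned": {"ssim": s_l, "psnr": p_l, "mse": m_l,
                    "dose_fraction": dose_l},
        "equal_interval": {"ssim": s_e, "psnr": p_e, "mse": m_e,
                           "dose_fraction": dose_fraction(fixed)},
    }


# -- checkpoints -------------------------------------------------------------


def save_checkpoint(path, encoder: SamplingEncoder, proj_net: SinogramNet,
                    image_net: ImageNet, config: TrainingConfig) -> None:
    arrays = {}
    for tag, mod in (("enc", encoder), ("proj", proj_net), ("img", image_net)):
        for i, a in enumerate(mod.state_arrays()):
            arrays[f"{tag}_{i}"] = a
    meta = dict(asdict(config))
    meta["lambda_bias"] = encoder.lambda_bias
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(),
                                        dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Rebuild (encoder, proj_net, image_net, config) from a checkpoint."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    lam = meta.pop("lambda_bias")
    meta["k_range"] = tuple(meta["k_range"])
    config = TrainingConfig(**meta)
    geo = config.geometry
    encoder = SamplingEncoder(geo.m1, config.m2, config.hidden,
                              lambda_bias=lam,
                              seed=config.derive_seed("encoder"))
    proj_net = SinogramNet(config.channels, seed=config.derive_seed("projnet"))
    image_net = ImageNet(config.base_width,
                         seed=config.derive_seed("imagenet"))
    for tag, mod in (("enc", encoder), ("proj", proj_net), ("img", image_net)):
        keys = sorted((k for k in data.files if k.startswith(tag + "_")),
                      key=lambda k: int(k.split("_")[1]))
        mod.load_state_arrays([data[k] for k in keys])
    return encoder, proj_net, image_net, config
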