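# Methods

## Problem

Sparse-view CT reduces patient dose by measuring only part of the projection
data. Classically one keeps every k-th angle and lives with streak
artifacts; learned reconstruction removes some of the damage but takes the
sampling scheme as given. This package implements the complementary idea: a
*trainable* per-angle dose allocation, searched jointly with the
reconstruction networks under an L1 dose constraint, followed by a
two-stage (sinogram-domain, then image-domain) restoration.

## Physical model

Images are n x n attenuation maps on `[-1,1]^2` with values in `[0,1]`
(pixel centers on a uniform grid, row index increasing downward). The
forward operator is the parallel-beam radon transform: `m2` angles uniform
on `[0, pi)`, `m1` detector bins with spacing equal to the pixel size
(default `m1` = smallest odd integer >= n*sqrt(2), covering the diagonal).
Rays are sampled at half-pixel steps with bilinear interpolation; phantom
rendering uses 4x4 subpixel averaging (partial-volume effect), which is what
brings the discrete radon within 2% of the analytic ellipse chord integrals
away from tangent rays.

Reducing the dose at angle theta by a factor `beta in (0,1]` adds the
log-domain degradation `M'' = -ln(beta)` to every line integral at that
angle; `beta` is floored at `exp(-10)` so the term stays bounded, and codes
below 1e-6 are treated as "angle not measured". Two sparsification paths
coexist deliberately:

* `tomography.measure_sparse` — the physics/simulation path, additive
  `M + M''`, with optional Gaussian photon-statistics noise
  (`sigma = 1/sqrt(I0 * beta * exp(-M))`, default `I0 = 1e5`, noise off by
  default since the log-domain model is otherwise exact);
* `encoding.apply_encoding` — the differentiable path used inside the
  networks, columnwise multiplication by the code.

They agree at the ends (`beta = 1`: both identities; `beta -> 0`: column
information destroyed) and the additive path is tested to satisfy exact
superposition.

FBP is a pure Ram-Lak filter (`|omega|` response on an FFT grid of length
next-pow2(2*m1), zero at DC, no smoothing window) followed by linear-
interpolated back-projection at `t = x cos(theta) + y sin(theta)`, scaled by
`pi/m2`. Filtering and back-projection are single implementations shared by
the plain and the differentiable (autodiff-wrapped) paths; the backward
passes are the exact adjoint maps, verified by inner-product identities.

## The sampling encoder G1

Flattened sinogram -> two fully-connected stages (hidden width 256) ->
per-component batch normalization -> biased ReLU `max(0, v - lambda')` ->
clamp at 1. The dose of a code is `||e||_1 / m2`, normalized so the
full-dose code scores exactly 1 and targets are comparable across
geometries (only ratios to full dose are ever meaningful).

Two numerical choices matter here:

* **BN shift initialized to +1.** Post-BN activations are ~N(shift, 1) per
  component; with the conventional zero shift, the expected dose of the
  unbiased code is ~0.32, and targets above that are unreachable by the
  non-negative bias alone. A +1 shift puts the ceiling near 0.68, so all
  practical targets (20-40%) are calibrated from above by bisection.
* **Dose penalty on the pre-clamp code.** Entries saturated at the clamp
  receive zero clamp-gradient; measuring the training-loss dose after the
  clamp lets saturated entries escape the penalty and the realized dose
  ratchets upward. The loss therefore penalizes the unclamped biased-ReLU
  output; the physical (clamped) dose is what histories and reports record.

Step-1 calibration bisects `lambda'` on `[0, max activation]` against the
batch-mean dose (tolerance 0.01, <= 60 iterations), using the calibration
batch's own BN statistics purely functionally. Unreachable targets raise a
diagnostic naming the achievable range.

Because G1 consumes the complete sinogram (which does not exist before
scanning), `export_fixed_encoding` provides the deployable variant: the mean
eval-mode code over a dataset, optionally binarized to the top
`round(m2*gamma)` angles.

## Reconstruction networks

**G2' (sinogram recovery):** five Conv+ReLU then five Deconv+ReLU stages,
64 channels, 3x3 kernels, stride 1, no padding (the deconvs exactly undo
the conv shrinkage; inputs must be >= 11 per axis), with a global residual
so the zero-weight network is the identity.

**G2'' (image detail restoration):** U-Net-like. Encoder: two-conv stem at
width 32, four maxpool+two-conv downsampling modules doubling width to 512
at 1/16 scale. Decoder: three bilinear-2x upsampling modules with skip
fusion (each skip path is three Conv+ReLU stages; skips at 1/2, 1/4, 1/8 —
the bottleneck has none; fusion by channel concatenation), a 1-channel
bridging conv at half resolution, and a 1-channel DBPN 2x super-resolution
head (T=2 alternating up-/down-projection units, kernel 6 / stride 2 /
padding 2) back to full resolution. Unlike G2', these convs pad by 1 —
without padding the skip shapes cannot align. Input size must be square and
divisible by 16.

G2'' is built as a *global-residual repairer*: output = input + correction,
with the DBPN reconstruction conv zero-initialized so the untrained network
is exactly the identity. Rationale: the degradation is additive in the
model's own terms, the FBP intermediate already carries the object profile,
and a freshly He-initialized non-residual head starts at an output scale
that destroys its input and wastes most of a desk-scale budget recovering
it. All other weights are He-uniform, seeded per layer, so a network is a
pure function of its seed.

No deep-learning framework is used: a small reverse-mode autodiff engine
over numpy (im2col convolutions, adjoint-based transposed convolutions,
pooling, batch norm, and custom ops wrapping the FBP kernels) backs all
trainable components. Every op is finite-difference tested.

## Training

Three steps: (1) calibrate `lambda'`; (2) train G1 and G2' with
`MSE(M_rec, M) + w_d * |dose(e) - gamma|` (per-sample dose, `w_d = 1`);
(3) freeze step-2 parameters (verified by array equality), compute FBP of
the recovered sinograms once, and train G2'' with plain MSE. Optimizer is
plain Adam; batch size 4; shuffling, initialization and data generation all
derive from one master seed, so runs are bit-reproducible. BN running
statistics (momentum 0.1) update throughout step 2 and freeze afterwards.
The held-out split is the last 20% of the generated dataset. Reconstructions
are clipped to [0,1] before metrics (data_range 1 throughout).

The reference learning rate is 1e-5. Desk-scale configurations (32x32
images, 30 angles, tens of phantoms) use 3e-4: at 1e-5 nothing measurable
happens within minutes of CPU time, and rates much above 1e-3 destabilize
the deeper image network through Adam's sign-step behavior.

## Synthetic data

The generator emulates the statistical role of CT training sets:
piecewise-smooth objects with internal structure. Each phantom is one
enclosing "body" ellipse (semi-axes 0.6-0.9) plus k-1 inner ellipses
(semi-axes 0.05-0.5, intensities 0.1-0.5, uniform rotation, centers inside
the body), intensities additive then clipped to [0,1]. It does **not**
reproduce anatomy: no directional anisotropy of real organs, no texture, no
beam hardening or scatter, and sinograms of ellipse unions are much smoother
in angle than clinical data. A green test on this world establishes the
mechanics of the method, not clinical performance.

That smoothness has one documented consequence: the learned-vs-equal-
interval comparison. At this scale, inpainting the *known* zero columns of
an equal-interval scheme is an easy, well-posed task, while the learned
continuous per-sample code forces G2' to solve a scale-ambiguity problem (a
conv net with a local receptive field cannot estimate per-column dose
factors it never observes). Measured across doses (0.2, 0.4) and budgets
(12-30 epochs), the equal-interval pipeline scores higher in both sinogram
and image domains here; the comparison driver reports both arms honestly.
On anatomically structured data at full scale, learned allocation is
expected to beat uniform sampling; that advantage does not emerge in this
synthetic world, and the tests report the measured ordering as-is.

## Degenerate inputs and tie-breaks

Non-square or non-finite images, mismatched encoding lengths, empty
geometries, sub-11 sinograms and non-divisible-by-16 images raise
ValueErrors naming the constraint. Binarized fixed encodings break top-k
ties by lower angle index. Equal-interval placement is
`floor(j*m2/k), j = 0..k-1` with `k = round(m2*gamma)`; `k = 0` is
rejected. PSNR of identical images reports infinity.

## Known limitations

Parallel-beam only; per-angle (not per-detector-bin) dose modulation; the
low-flux degradation term and its denoising problem are out of scope; the
autodiff engine is single-threaded numpy and meant for desk-scale images
(<= 128 px), not clinical volumes.
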