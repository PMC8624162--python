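# Methods

`flowrecon` implements conditional normalizing flows for posterior sampling
in linear imaging inverse problems. This note documents the model, the
numerical choices, the synthetic data the package trains and validates on,
and what the shipped benchmarks do and do not demonstrate.

## Model

A measurement is `y = A x + eps` with a known linear operator `A` and noise
`eps`. The package learns the full posterior `p(x | y)` with a conditional
invertible network: a bijection `T(.; h)` between image space and a latent
space of equal dimension, steered by conditioning features `h = H(y)`, with
a tractable base density `p_z`. The conditional density is exact by the
change of variables,

    log p(x | y) = log p_z(T^{-1}(x; H(y))) + log |det J_{T^{-1}}(x; H(y))|,

and training maximizes this likelihood over paired `(x, y)` data.
Reconstruction uses Monte-Carlo posterior moments over `N` samples
`x_i = T(z_i; H(y))`, `z_i ~ p_z`: the conditional mean (reconstruction)
and the pointwise standard deviation (uncertainty map), with the biased
divisor-`N` variance estimator. `N = 100` is the default.

### Invertible building blocks

* **Coupling layers** split the channel axis into `(x1, x2)`; `x1` passes
  unchanged while `x2` is shifted (additive) or scaled-and-shifted
  (affine) by a 3-layer convolutional subnetwork of `x1` and, when
  conditional, of the conditioning features. The affine log-scale passes
  through `clamp * tanh(s / clamp)` (default clamp 2.0), which bounds the
  singular values of the Jacobian in both directions and prevents the
  exploding-inverse failure of unbounded scales. The subnetwork's last
  convolution is zero-initialized so every coupling starts as the identity.
  The first channel block takes `c1 = ceil(c/2)` channels.
* **Channel mixing** is a fixed (frozen after initialization) invertible
  1x1 convolution, orthogonal by default (logdet 0); a plain random
  channel permutation is available as a config switch. One mixing layer
  follows every coupling.
* **Invertible downsampling**: checkerboard rearrangement (a pure
  permutation) or the orthonormal 2-D Haar transform; both map
  `(c, h, w) -> (4c, h/2, w/2)` with logdet 0. Odd spatial sizes are
  rejected rather than padded — invertibility must be exact — and a
  `pad_to_multiple` utility is provided for callers.
* **Input normalization**: a fixed elementwise affine map built once from
  training-data statistics (per-pixel mean and standard deviation) brings
  images to roughly unit scale before the flow; its log-determinant,
  `-sum(log std)`, is exact and constant. Without it the flow spends much
  of its budget learning the data's gross location and scale.

Log-determinants are accumulated per sample in double precision (the whole
package computes in float64).

### Architectures

* **Multi-scale flow**: per scale, couplings -> downsampling -> couplings
  -> channel split; half the channels exit directly to the latent output
  at each scale. Conditioning features are consumed at the resolution at
  which each coupling operates. Affine couplings are the default here.
* **Invertible UNet (iUNet)**: a down path (coupling -> channel split ->
  downsampling, the split-off half kept as a skip), a bottom coupling, and
  an up path (invertible upsampling -> concat skip -> coupling) that
  re-absorbs the skips step by step; the latent has the input image's
  shape. Additive couplings are the default: their unit Jacobian keeps the
  inverse pass of this deep nested topology numerically exact. The package
  stores the skip at the resolution *above* its downsampling step — the
  channel/element bookkeeping of an invertible UNet forces the split to
  act before the downsampling on the path that continues down; this is the
  only ordering for which upsample-then-concat reproduces the mirror-image
  down-path shapes.
* Single-channel inputs are first passed through one fixed checkerboard
  rearrangement ("entry squeeze") so couplings have at least two channels
  to split; spatial sizes must then be divisible by `2^L`.
* A per-pass stability monitor reports the maximum absolute clamped
  log-scale across all couplings (identically 0 for additive stacks).

### Base distributions

Standard normal, and the radial Gaussian: uniform direction on the unit
sphere with half-normal radius `r = |r_hat|`, `r_hat ~ N(0, 1)`, giving

    log p(z) = log(2 / (sqrt(2 pi) S_n)) - (n - 1) log ||z|| - ||z||^2 / 2,

with `S_n = 2 pi^{n/2} / Gamma(n/2)` computed in log-space. The constant
is re-derived from the construction (half-normal radius density divided by
the sphere-shell area `r^{n-1} S_n`) and verified by numerical
normalization for n in {1, 2, 3}. For n >= 2 the density is singular at
z = 0; evaluation there raises rather than clamps, because silent clamping
would corrupt likelihood bookkeeping. Log-densities are always reported
fully normalized — nothing is dropped as "constant" — so validation NLLs
are comparable across base distributions.

The radial base exists because in high dimension the standard normal's
mode lies far from its typical set (radius ~ sqrt(n)); aligning the
high-density region with the typical set can make single samples from the
trained flow noticeably cleaner.

### Conditioning network

The conditioning path is a *model-based inversion layer* followed by a
learned feature extractor. The inversion layer `A-dagger` is a classical
linear reconstruction: Moore-Penrose pseudo-inverse or TV-regularized
inverse `(A^T A + lambda G^T G)^{-1} A^T` (default `lambda = 0.02`; `G` is
the forward-difference gradient with zero-flux boundaries, which keeps
`G^T G` symmetric positive semidefinite) for compressed sensing, filtered
back-projection for CT, and the zero-filled inverse FFT (magnitude image)
for MRI. Measurements in CT/MRI have global, non-image topology that plain
CNNs handle poorly; the inversion layer moves feature extraction into
image space.

Four extractors are provided, in increasing capacity (their parameter
counts are ordered by construction): `avg_pool` (one learned convolution,
then average pooling per scale), `cnn` (fully convolutional stack),
`resnet` (residual blocks, strided convolutions instead of pooling), and
`unet` (encoder-decoder whose encoder/decoder activations condition the
iUNet's down/up paths and whose zero-initialized head outputs an
image-space reconstruction). Conditioning networks train jointly with the
flow by default; a freeze flag supports pre-trained conditioning.

## Training

Per-sample NLL in nats, Adam at learning rate 1e-4 (reference protocol;
the desk-scale experiments below use larger rates), reduce-on-plateau
schedule with factor 0.8 on the validation NLL, and model selection by
minimal validation NLL. Options: Gaussian training noise added to the
ground-truth images fresh each epoch (variance 0.005 in the reference
ablation; a dequantization/augmentation step), and a supervised
conditional loss `alpha * MSE(H(y), x)` on the UNet conditioning head
(`alpha = 1.0` in the reference ablation). The train/validation split is
by index before shuffling (default 90/10). NaN losses abort training and
restore the last finite checkpoint.

Because every coupling transforms only half of its channels, a latent
direction that never lands in the transformed half keeps its unconditioned
prior; with `k` couplings and random orthogonal mixing roughly `2^-k` of
directions stay untouched. Conditional accuracy therefore improves
markedly with coupling depth; the posterior-recovery benchmark uses 4
couplings per scale for this reason.

Small conditional problems also need surprisingly many training pairs: on
the 16-pixel reference problem a few thousand pairs let the flow memorize
(training NLL near the posterior entropy while validation NLL stays near
the prior entropy); with tens of thousands of pairs the validation NLL
approaches the posterior entropy and the learned conditional mean
generalizes. The posterior-recovery benchmark trains on 24k pairs.

## Sample refinement

Post-hoc data consistency by plain gradient descent on the variational
Tikhonov objective `||A x - y||^2 - lambda log p(x | y)`, initialized at a
flow sample, 100 iterations at step 1e-4 by default, with the lambda grid
{0, 0.01, 0.1, 1.0, 10.0}. The gradient of the prior term is obtained by
differentiating the flow's exact log-density with respect to the input
image. Non-finite objectives stop the iteration at the last finite
iterate.

## Forward operators and synthetic data

* **Gaussian compressed sensing**: dense `m x n` matrix with i.i.d.
  `N(0, 1/m)` entries (default m 196, n 784 — 4x undersampling);
  "10% relative noise" is Gaussian noise whose expected norm is 10% of the
  per-sample measurement norm.
* **Radon transform**: assembled as a sparse matrix by ray-driven sampling
  (bilinear interpolation at step 0.5 px along each ray; angles uniform on
  [0, pi); detector count `ceil(side * sqrt(2)) + 1` at unit spacing), so
  the adjoint is the exact transpose and the dot-product test holds to
  machine precision. FBP uses the band-limited spatial-domain Ram-Lak
  kernel (the naive `|nu|` DFT sampling has a DC bias that produces
  cupping), zero-padded to avoid circular convolution, with an optional
  frequency cutoff; the discrete inversion constant is `pi / n_angles`
  at unit detector spacing. A single-parameter Poisson photon-count model
  (`counts ~ Pois(N0 exp(-y))`, log-transformed back, default N0 = 4096)
  emulates low-dose noise; it is deliberately simpler than a full clinical
  simulation pipeline.
* **Masked Fourier (MRI)**: centered orthonormal 2-D DFT with a Cartesian
  column mask — all `round(0.08 w)` center columns plus uniformly random
  higher frequencies up to `round(w / 4)` columns (acceleration 4). Masks
  sample frequency columns (1-D phase-encode undersampling); zero
  frequency sits at the array center.
* **Phantoms**: random ellipse superpositions (3-8 ellipses, clipped to
  [0, 1]) and sparse-stroke "digits-like" images (smoothed random walks).
  Datasets regenerate bit-identically from their seed and export to HDF5.
* **Linear-Gaussian reference problem**: 4x4 images, prior
  `N(0.5, Sigma0)` with a squared-exponential covariance (scale 0.3,
  length 1 px) plus a 0.005 white-noise nugget (keeping `Sigma0` well
  conditioned), m = 8 Gaussian measurements, noise std 0.08 (about 10%
  relative for prior draws). Its posterior is Gaussian and closed-form,
  making it the one configuration where a trained model can be compared
  with the exact answer.

## What the benchmarks show — and what they do not

The shipped experiments run at desk scale (images 4x4 to 128x128, minutes
of CPU): they verify exact invertibility and exact log-determinants
against brute-force Jacobians, the radial density against quadrature and
sampling law, density estimation against an analytic optimum, posterior
recovery against a closed-form Gaussian posterior, operator accuracy
against analytic projections, refinement descent against the
normal-equations solution, and the direction of the conditioning-quality
effect (TV-regularized inverse beats the pseudo-inverse as conditioning
input at matched budgets). Problem sizes for the trained benchmarks — 2-D
density toy, 16-pixel posterior recovery, 16x16 compressed sensing — are
the package's chosen desk-scale configurations.

Synthetic phantoms are much simpler than clinical images: they have no
anatomy, no scanner physics, no dataset shift. Passing these benchmarks
shows the machinery is correct and the method behaves as theory predicts
on problems where theory gives the answer; it does not certify
reconstruction quality on real CT/MRI data, which requires training at
full scale on real datasets.

## Known limitations

* Dense Jacobian oracles limit exact logdet verification to small inputs
  (<= 256 elements); larger models rely on compositionality.
* The numpy backend is single-threaded per operation; training beyond
  ~64x64 images is slow. The architecture code is backend-agnostic in
  design but not in implementation.
* The Poisson CT noise model is a one-parameter emulation, not a clinical
  low-dose pipeline.
* Learnable invertible downsampling and conditional/mixture base
  distributions are out of scope.
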