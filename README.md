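# flowrecon

**Conditional invertible neural networks for posterior sampling in imaging
inverse problems.**

Image reconstruction in computed tomography (CT), accelerated MRI and
compressed sensing is an ill-posed inverse problem: measurements
`y = A x + eps` under-determine the image `x`, and point reconstructions
hide the remaining ambiguity. `flowrecon` learns the *full posterior*
`p(x | y)` with a conditional normalizing flow — an invertible network
`T(z; H(y))` that maps a simple latent density to the posterior, with the
exact likelihood

```
log p(x | y) = log p_z(T^{-1}(x; H(y))) + log |det J_{T^{-1}}(x; H(y))|
```

available in closed form. Reconstruction is the Monte-Carlo conditional
mean over `N` posterior samples and the pointwise standard deviation is a
per-pixel uncertainty map. The package is aimed at researchers studying
uncertainty quantification for linear imaging inverse problems who want a
compact, fully inspectable implementation with exact Jacobian accounting.

It provides:

* **Invertible building blocks** — additive/affine (conditional) coupling
  layers with clamped log-scales, fixed invertible 1x1 channel mixing,
  checkerboard and orthonormal Haar invertible downsampling — each with
  its exact log-determinant;
* **Two architectures** — the Real-NVP-style multi-scale flow and an
  invertible UNet (additive couplings by default, avoiding the exploding
  inverse);
* **Base distributions** — standard normal and the radial Gaussian
  (uniform direction, half-normal radius), whose high-density region sits
  on the typical set in high dimension;
* **Conditioning networks** — a model-based inversion layer (pseudo- or
  TV-regularized inverse, filtered back-projection, zero-filled IFFT)
  followed by a learned feature pyramid (average-pooling / CNN / ResNet /
  UNet variants);
* **Forward operators & synthetic data** — Gaussian compressed sensing,
  a sparse-matrix parallel-beam Radon transform with Ram-Lak FBP, masked
  Fourier (Cartesian MRI undersampling), noise models, random phantoms,
  and a linear-Gaussian reference problem with a closed-form posterior;
* **Training & inference** — maximum-likelihood training with validation
  model selection, conditional-mean/std reconstruction, variational
  sample refinement, PSNR/SSIM evaluation;
* sklearn-style estimators (`FlowDensity`,
  `ConditionalFlowReconstructor`) and a `flowrecon` command-line
  interface (`train` / `reconstruct` / `refine` / `evaluate`).

Everything runs on a small numpy reverse-mode autodiff core included in
the package (`flowrecon._autodiff`), in float64, on a single CPU.

## Worked example

Train a conditional flow on the linear-Gaussian reference problem — the
one setting where the exact posterior is known — and compare:

```python
import numpy as np
import flowrecon as fr

prob = fr.make_linear_gaussian_problem()        # 4x4 images, m=8, known posterior
x, y = prob.sample_joint(24000, np.random.default_rng(0))

est = fr.ConditionalFlowReconstructor(
    forward_model=prob.model, architecture="multiscale", conditioning="cnn",
    inversion="pseudo_inverse", n_scales=2, blocks_per_scale=4,
    hidden_width=24, cond_channels=16, learning_rate=3e-3,
    epochs=30, batch_size=256, seed=1)
est.fit(x, y)

_, y_test = prob.sample_joint(5, np.random.default_rng(9001))
mu_exact = prob.posterior_mean(y_test)
for i in range(5):
    s = est.posterior(y_test[i], n_samples=100, seed=i)
    rel = np.linalg.norm(s.mean - mu_exact[i]) / np.linalg.norm(mu_exact[i])
    print(f"measurement {i}: rel. L2 error of conditional mean = {rel:.3f}")
```

```
measurement 0: rel. L2 error of conditional mean = 0.040
measurement 1: rel. L2 error of conditional mean = 0.025
measurement 2: rel. L2 error of conditional mean = 0.024
measurement 3: rel. L2 error of conditional mean = 0.017
measurement 4: rel. L2 error of conditional mean = 0.044
```

The Monte-Carlo conditional mean over 100 flow samples lands within a few
percent of the analytic Gaussian posterior mean, and the model's
validation NLL (`est.validation_nll_`, here -12.6 nats) approaches the
posterior entropy; `s.std` is the matching per-pixel uncertainty map,
which rank-correlates strongly with the analytic posterior standard
deviation.

From the shell, the same machinery runs on the built-in CT / MRI /
compressed-sensing toys:

```bash
flowrecon train --problem cs --size 16 --epochs 10 --outdir runs/cs
flowrecon evaluate --checkpoint runs/cs/model.npz --problem cs --out metrics.csv
```

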