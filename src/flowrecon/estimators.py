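"""Scikit-learn style estimators wrapping the conditional-flow machinery.

``FlowDensity`` is an unconditional density estimator (fit / score_samples
/ sample), and ``ConditionalFlowReconstructor`` learns the posterior
p(x | y) of an imaging inverse problem from paired (image, measurement)
data (fit / predict / sample / score_samples).  Both follow sklearn
conventions: constructor arguments are stored verbatim, fitted state lives
in trailing-underscore attributes, and ``get_params``/``set_params`` work
with model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .architectures import IUNetConfig, MultiScaleConfig, build_flow
from .base_dists import make_base
from .conditioning import InversionLayer, make_conditioning_net
from .inference import PosteriorSummary, posterior_summary
from .models import CINNModel
from .operators import NoiseSpec, SyntheticDataset
from .training import TrainConfig, train

__all__ = ["FlowDensity", "ConditionalFlowReconstructor"]


class FlowDensity(BaseEstimator):
    """Unconditional normalizing-flow density estimator on vector data.

    Data of dimension d is carried as a d-channel 1x1 image so the same
    coupling machinery used for images applies; subnetworks are 1x1
    convolutions (dense layers).
    """

    def __init__(self, n_blocks: int = 4, hidden_width: int = 24,
                 base: str = "normal", clamp: float = 2.0,
                 learning_rate: float = 1e-3, epochs: int = 40,
                 batch_size: int = 128, plateau_factor: float = 0.8,
                 plateau_patience: int = 5, val_fraction: float = 0.2,
                 seed: int = 0, verbose: bool = False):
        self.n_blocks = n_blocks
        self.hidden_width = hidden_width
        self.base = base
        self.clamp = clamp
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.val_fraction = val_fraction
        self.seed = seed
        self.verbose = verbose

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expected (n_samples, n_features) data")
        n, d = X.shape
        if d < 2:
            raise ValueError("need at least 2 features for coupling layers")
        self.n_features_in_ = d
        rng = np.random.default_rng(self.seed)
        cfg = MultiScaleConfig(
            input_shape=(d, 1, 1), n_scales=1, blocks_per_scale=self.n_blocks,
            coupling="affine", clamp=self.clamp, hidden_width=self.hidden_width,
            kernel=1, mixing="orthogonal", initial_squeeze=False,
        )
        flow = build_flow(cfg, kind="multiscale", rng=rng)
        model = CINNModel(flow, make_base(self.base, d))
        dataset = SyntheticDataset(
            images=X.reshape(n, d, 1, 1), measurements=np.zeros((n, 1)),
            seed=self.seed, forward_model=None,
            noise_spec=NoiseSpec(kind="none"),
        )
        tcfg = TrainConfig(
            learning_rate=self.learning_rate, plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.seed, val_fraction=self.val_fraction,
            verbose=self.verbose,
        )
        self.model_, self.history_ = train(model, dataset, tcfg)
        self.validation_nll_ = self.history_.best_val_nll
        return self

    def score_samples(self, X) -> np.ndarray:
        """Per-sample log-density in nats."""
        X = np.asarray(X, dtype=np.float64)
        return self.model_.log_prob(X.reshape(len(X), self.n_features_in_, 1, 1))

    def score(self, X, y=None) -> float:
        return float(np.mean(self.score_samples(X)))

    def sample(self, n_samples: int = 1, seed: int | None = None) -> np.ndarray:
        rng = np.random.default_rng(self.seed if seed is None else seed)
        x = self.model_.sample(None, n_samples, rng)
        return x.reshape(n_samples, self.n_features_in_)


class ConditionalFlowReconstructor(BaseEstimator):
    """Conditional invertible network for posterior sampling.

    Parameters mirror the reference training protocol: Adam with plateau
    learning-rate decay, optional training-noise augmentation and optional
    supervised conditional loss (``alpha``); the conditioning path is a
    model-based inversion layer (chosen by ``inversion``) followed by a
    feature-extractor network (``conditioning``).
    """

    def __init__(self, forward_model=None, architecture: str = "multiscale",
                 conditioning: str = "avg_pool", inversion: str = "pseudo_inverse",
                 tv_lambda: float = 0.02, n_scales: int = 2,
                 blocks_per_scale: int = 2, coupling: str | None = None,
                 base: str = "normal", clamp: float = 2.0,
                 hidden_width: int = 32, cond_channels: int = 16,
                 downsampling: str = "checkerboard",
                 learning_rate: float = 1e-3, epochs: int = 20,
                 batch_size: int = 32, alpha: float = 0.0,
                 train_noise_variance: float = 0.0,
                 plateau_factor: float = 0.8, plateau_patience: int = 5,
                 n_posterior_samples: int = 100, val_fraction: float = 0.1,
                 seed: int = 0, verbose: bool = False):
        self.forward_model = forward_model
        self.architecture = architecture
        self.conditioning = conditioning
        self.inversion = inversion
        self.tv_lambda = tv_lambda
        self.n_scales = n_scales
        self.blocks_per_scale = blocks_per_scale
        self.coupling = coupling
        self.base = base
        self.clamp = clamp
        self.hidden_width = hidden_width
        self.cond_channels = cond_channels
        self.downsampling = downsampling
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.alpha = alpha
        self.train_noise_variance = train_noise_variance
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.n_posterior_samples = n_posterior_samples
        self.val_fraction = val_fraction
        self.seed = seed
        self.verbose = verbose

    # -- construction helpers -------------------------------------------------
    def _image_batch(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4:
            raise ValueError("expected images of shape (n, h, w) or (n, c, h, w)")
        return X

    def _build_model(self, image_shape) -> CINNModel:
        rng = np.random.default_rng(self.seed)
        coupling = self.coupling
        if coupling is None:
            coupling = "additive" if self.architecture == "iunet" else "affine"
        cfg_cls = IUNetConfig if self.architecture == "iunet" else MultiScaleConfig
        cfg = cfg_cls(
            input_shape=tuple(image_shape), n_scales=self.n_scales,
            blocks_per_scale=self.blocks_per_scale, coupling=coupling,
            downsampling=self.downsampling, clamp=self.clamp,
            hidden_width=self.hidden_width, cond_channels=self.cond_channels,
        )
        flow = build_flow(cfg, kind=self.architecture, rng=rng)
        inversion = InversionLayer(self.inversion, self.forward_model,
                                  tv_lambda=self.tv_lambda)
        cond_net = make_conditioning_net(
            self.conditioning, tuple(image_shape), flow.cond_shapes(), rng=rng
        )
        base = make_base(self.base, flow.n_latent)
        return CINNModel(flow, base, cond_net=cond_net, inversion=inversion)

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y):
        """Fit on images X (n, h, w) and measurements y (n, ...)."""
        if self.forward_model is None:
            raise ValueError("forward_model is required")
        X = self._image_batch(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("images and measurements disagree in length")
        self.image_shape_ = X.shape[1:]
        model = self._build_model(self.image_shape_)
        dataset = SyntheticDataset(
            images=X, measurements=y, seed=self.seed,
            forward_model=self.forward_model, noise_spec=NoiseSpec(kind="none"),
        )
        tcfg = TrainConfig(
            learning_rate=self.learning_rate, plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience, batch_size=self.batch_size,
            epochs=self.epochs, alpha=self.alpha,
            train_noise_variance=self.train_noise_variance, seed=self.seed,
            val_fraction=self.val_fraction, verbose=self.verbose,
        )
        self.model_, self.history_ = train(model, dataset, tcfg)
        self.validation_nll_ = self.history_.best_val_nll
        self.n_parameters_ = model.n_parameters()
        return self

    def posterior(self, y_single, n_samples: int | None = None,
                  seed: int | None = None) -> PosteriorSummary:
        n = n_samples or self.n_posterior_samples
        rng = np.random.default_rng(self.seed if seed is None else seed)
        return posterior_summary(self.model_, y_single, n_samples=n, rng=rng)

    def predict(self, Y, n_samples: int | None = None,
                seed: int | None = None) -> np.ndarray:
        """Conditional-mean reconstruction for each measurement row."""
        Y = np.asarray(Y)
        n = n_samples or self.n_posterior_samples
        rng = np.random.default_rng(self.seed if seed is None else seed)
        means = []
        for i in range(len(Y)):
            summary = posterior_summary(self.model_, Y[i], n_samples=n, rng=rng)
            means.append(summary.mean)
        return np.stack(means)

    def sample(self, y_single, n_samples: int = 1,
               seed: int | None = None) -> np.ndarray:
        rng = np.random.default_rng(self.seed if seed is None else seed)
        return self.model_.sample(y_single, n_samples, rng)

    def score_samples(self, X, y) -> np.ndarray:
        X = self._image_batch(X)
        return self.model_.log_prob(X, np.asarray(y))

    def score(self, X, y) -> float:
        """Mean conditional log-likelihood (higher is better)."""
        return float(np.mean(self.score_samples(X, y)))
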