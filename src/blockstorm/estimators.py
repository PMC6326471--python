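"""Scikit-learn-style estimator facades over the two localizers.

Both follow the sklearn protocol (``get_params``/``set_params``,
``fit``/``predict``, fitted attributes with a trailing underscore) so they
can be swapped inside the evaluation sweep or composed with sklearn model
selection.  ``predict`` takes a camera-grid frame stack and returns a
localization table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .baseline import DetectionConfig, localize_stack
from .nn.gan import (
    DiscriminatorSpec,
    GeneratorSpec,
    LossWeights,
    PsfKernel,
    TrainConfig,
    infer_stack,
    maps_to_table,
    train,
)

__all__ = ["BaselineLocalizer", "GanLocalizer"]


class BaselineLocalizer(BaseEstimator):
    """Classical filter/threshold/fit localizer as an sklearn estimator.

    The estimator has no trainable state; ``fit`` only validates and
    freezes the configuration.
    """

    def __init__(self, filter_sigma: float = 1.3, peak_threshold_k: float = 3.0,
                 fit_window: int = 7, pixel_size: float = 100.0):
        self.filter_sigma = filter_sigma
        self.peak_threshold_k = peak_threshold_k
        self.fit_window = fit_window
        self.pixel_size = pixel_size

    def fit(self, X=None, y=None) -> "BaselineLocalizer":
        self.config_ = DetectionConfig(
            filter_sigma=self.filter_sigma,
            peak_threshold_k=self.peak_threshold_k,
            fit_window=self.fit_window,
        )
        return self

    def predict(self, X: np.ndarray) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit()
        return localize_stack(np.asarray(X), self.config_, self.pixel_size)


class GanLocalizer(BaseEstimator):
    """Conditional-GAN localizer as an sklearn estimator.

    ``fit`` takes a list of (frame, map) :class:`~blockstorm.simulate.FramePair`
    training pairs; ``predict`` runs the trained generator over a camera-grid
    stack and extracts a localization table.
    """

    def __init__(self, depth: int = 3, base_channels: int = 16,
                 lambda_cgan: float = 3.0, lambda_l1: float = 100.0,
                 lambda_l1s: float = 100.0, cgan_warmup_iters: int = 1000,
                 cgan_active_every: int = 3, learning_rate: float = 1e-4,
                 adam_beta1: float = 0.25, batch_size: int = 4,
                 epochs: int = 10, psf_sigma_map_px: float = 2.0,
                 threshold_fraction: float = 0.3, pixel_size: float = 100.0,
                 upsample: int = 5, seed: int = 0):
        self.depth = depth
        self.base_channels = base_channels
        self.lambda_cgan = lambda_cgan
        self.lambda_l1 = lambda_l1
        self.lambda_l1s = lambda_l1s
        self.cgan_warmup_iters = cgan_warmup_iters
        self.cgan_active_every = cgan_active_every
        self.learning_rate = learning_rate
        self.adam_beta1 = adam_beta1
        self.batch_size = batch_size
        self.epochs = epochs
        self.psf_sigma_map_px = psf_sigma_map_px
        self.threshold_fraction = threshold_fraction
        self.pixel_size = pixel_size
        self.upsample = upsample
        self.seed = seed

    def fit(self, X, y=None) -> "GanLocalizer":
        gspec = GeneratorSpec(depth=self.depth, base_channels=self.base_channels)
        dspec = DiscriminatorSpec(base_channels=self.base_channels)
        weights = LossWeights(
            lambda_cgan=self.lambda_cgan, lambda_l1=self.lambda_l1,
            lambda_l1s=self.lambda_l1s,
            cgan_warmup_iters=self.cgan_warmup_iters,
            cgan_active_every=self.cgan_active_every,
        )
        tc = TrainConfig(
            learning_rate=self.learning_rate, adam_beta1=self.adam_beta1,
            batch_size=self.batch_size, epochs=self.epochs, seed=self.seed,
        )
        self.model_ = train(
            list(X), gspec, dspec, weights, tc,
            psf=PsfKernel(sigma=self.psf_sigma_map_px),
        )
        self.history_ = self.model_.history
        return self

    def predict(self, X: np.ndarray) -> pd.DataFrame:
        maps = self.predict_maps(X)
        return maps_to_table(
            maps, self.threshold_fraction, self.pixel_size, self.upsample
        )

    def predict_maps(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("GanLocalizer must be fitted before predicting")
        return infer_stack(self.model_, np.asarray(X), upsample=self.upsample)
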