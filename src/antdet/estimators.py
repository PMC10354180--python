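"""scikit-learn-style estimators over the detector trainers.

Each estimator wraps one learning procedure from :mod:`antdet.training`
behind the familiar ``fit`` / ``predict`` interface (``get_params`` /
``set_params`` via :class:`sklearn.base.BaseEstimator`), so detectors
compose with sklearn model selection. ``X`` is an (N, H, W) stack of
grayscale frames in [0, 1]; dense predictions are (N, H, W) class maps
over {0: background, 1: ant body, 2: ant boundary}.

Fitted attributes: ``model_`` (the trained network), ``loss_history_``
and, for the distillers, ``selection_log_``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .evaluation import labelmap_to_centers
from .models import build_model, predict_labelmap, predict_proba
from .training import (AnnotationSource, EnsembleConfig, TrainConfig,
                       train_hybrid, train_probabilistic_nn_fit,
                       train_random_nn_fit, train_single_source)

__all__ = [
    "PseudoLabelDetector",
    "ProbabilisticNNFitDistiller",
    "RandomNNFitDistiller",
    "HybridDetector",
]


class _BaseDetector(BaseEstimator):
    """Shared construction, validation and prediction plumbing."""

    _n_heads = 1

    def __init__(self, architecture="unet", depth=2, base_channels=8,
                 batch_size=8, lr_initial=5e-4, lr_after=5e-5,
                 lr_switch_iter=1500, total_iters=2000, crop_size=32,
                 class_weights=None, random_state=0):
        self.architecture = architecture
        self.depth = depth
        self.base_channels = base_channels
        self.batch_size = batch_size
        self.lr_initial = lr_initial
        self.lr_after = lr_after
        self.lr_switch_iter = lr_switch_iter
        self.total_iters = total_iters
        self.crop_size = crop_size
        self.class_weights = class_weights
        self.random_state = random_state

    # ------------------------------------------------------------ helpers
    def _train_config(self) -> TrainConfig:
        return TrainConfig(batch_size=self.batch_size,
                           lr_initial=self.lr_initial,
                           lr_after=self.lr_after,
                           lr_switch_iter=min(self.lr_switch_iter,
                                              self.total_iters),
                           total_iters=self.total_iters,
                           crop_size=self.crop_size,
                           seed=self.random_state,
                           class_weights=self.class_weights)

    def _build(self):
        return build_model(architecture=self.architecture, depth=self.depth,
                           base_channels=self.base_channels,
                           n_heads=self._n_heads, seed=self.random_state)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted yet; call fit first")

    # --------------------------------------------------------- prediction
    def predict(self, X):
        """Dense class-map prediction, (N, H, W) uint8."""
        self._check_fitted()
        return predict_labelmap(self.model_, X, fuse=self._fuse_mode())

    def predict_proba(self, X):
        """Per-pixel class probabilities, (N, H, W, 3)."""
        self._check_fitted()
        probs = predict_proba(self.model_, X)
        if self.model_.n_heads == 1:
            return probs[0]
        summed = probs[0] + probs[1]
        return summed / summed.sum(axis=-1, keepdims=True)

    def predict_centers(self, X, min_area=5, connectivity=8):
        """Detected ant centers per frame: list of (n, 2) (x, y) arrays."""
        maps = self.predict(X)
        return [labelmap_to_centers(lm, min_area=min_area,
                                    connectivity=connectivity) for lm in maps]

    def _fuse_mode(self):
        return "head1"


class PseudoLabelDetector(_BaseDetector):
    """Dense detector trained on a single annotation source.

    ``fit(X, y)`` takes frames and one dense label map per frame — an
    algorithm-generated pseudo-annotation stack, rendered human
    annotations, or clean rasterized ground truth.
    """

    def fit(self, X, y):
        model = self._build()
        model, history = train_single_source(X, y, model,
                                             self._train_config())
        self.model_ = model
        self.loss_history_ = history
        return self


class ProbabilisticNNFitDistiller(_BaseDetector):
    """Probabilistic NN-Fit student distilled from K annotation versions.

    ``fit(X, sources)`` takes a list of K label-map stacks (or
    :class:`AnnotationSource` objects) over the same frames. Per iteration
    each sample's source is drawn with probability
    ``softmax(-distance / temperature)`` against the student's current
    prediction; ``warmup_iters`` initial iterations select uniformly.
    """

    def __init__(self, architecture="unet", depth=2, base_channels=8,
                 batch_size=8, lr_initial=5e-4, lr_after=5e-5,
                 lr_switch_iter=1500, total_iters=2000, crop_size=32,
                 class_weights=None, random_state=0,
                 temperature=0.1, distance="pixel_ce", warmup_iters=0):
        super().__init__(architecture=architecture, depth=depth,
                         base_channels=base_channels, batch_size=batch_size,
                         lr_initial=lr_initial, lr_after=lr_after,
                         lr_switch_iter=lr_switch_iter,
                         total_iters=total_iters, crop_size=crop_size,
                         class_weights=class_weights,
                         random_state=random_state)
        self.temperature = temperature
        self.distance = distance
        self.warmup_iters = warmup_iters

    def fit(self, X, sources):
        ecfg = EnsembleConfig(temperature=self.temperature,
                              distance=self.distance,
                              warmup_iters=self.warmup_iters,
                              seed=self.random_state)
        model = self._build()
        model, history, sel_log = train_probabilistic_nn_fit(
            X, sources, model, self._train_config(), ecfg)
        self.model_ = model
        self.loss_history_ = history
        self.selection_log_ = sel_log
        return self


class RandomNNFitDistiller(_BaseDetector):
    """Two-stage Random/NN-Fit baseline (uniform, then greedy nearest)."""

    def __init__(self, architecture="unet", depth=2, base_channels=8,
                 batch_size=8, lr_initial=5e-4, lr_after=5e-5,
                 lr_switch_iter=1500, total_iters=2000, crop_size=32,
                 class_weights=None, random_state=0,
                 switch_iter=1000, distance="pixel_ce"):
        super().__init__(architecture=architecture, depth=depth,
                         base_channels=base_channels, batch_size=batch_size,
                         lr_initial=lr_initial, lr_after=lr_after,
                         lr_switch_iter=lr_switch_iter,
                         total_iters=total_iters, crop_size=crop_size,
                         class_weights=class_weights,
                         random_state=random_state)
        self.switch_iter = switch_iter
        self.distance = distance

    def fit(self, X, sources):
        model = self._build()
        model, history, sel_log = train_random_nn_fit(
            X, sources, model, self._train_config(),
            switch_iter=self.switch_iter, distance=self.distance,
            sel_seed=self.random_state)
        self.model_ = model
        self.loss_history_ = history
        self.selection_log_ = sel_log
        return self


class HybridDetector(_BaseDetector):
    """Two-headed detector trained on algorithm + human annotations.

    ``fit(X, algorithm_labels, human_labels, algorithm_indices,
    human_indices)``: head 1 learns from the algorithm-annotated frames,
    head 2 from the human-annotated frames, and the shared trunk from
    both. At test time the two heads' probability maps are summed before
    the argmax (``fuse="sum"``, recommended) or head 2 is used alone
    (``fuse="head2"``).
    """

    _n_heads = 2

    def __init__(self, architecture="unet", depth=2, base_channels=8,
                 batch_size=8, lr_initial=5e-4, lr_after=5e-5,
                 lr_switch_iter=1500, total_iters=2000, crop_size=32,
                 class_weights=None, random_state=0, fuse="sum",
                 head_weighting="equal"):
        super().__init__(architecture=architecture, depth=depth,
                         base_channels=base_channels, batch_size=batch_size,
                         lr_initial=lr_initial, lr_after=lr_after,
                         lr_switch_iter=lr_switch_iter,
                         total_iters=total_iters, crop_size=crop_size,
                         class_weights=class_weights,
                         random_state=random_state)
        self.fuse = fuse
        self.head_weighting = head_weighting

    def fit(self, X, algorithm_labels=None, human_labels=None,
            algorithm_indices=None, human_indices=None):
        model = self._build()
        model, history, head_losses = train_hybrid(
            X, algorithm_labels, human_labels, model, self._train_config(),
            aa_indices=algorithm_indices, ha_indices=human_indices,
            head_weighting=self.head_weighting)
        self.model_ = model
        self.loss_history_ = history
        self.head_loss_history_ = head_losses
        # with no algorithm pool head 1 is untrained: force head-2 output
        no_aa = algorithm_labels is None or (
            algorithm_indices is not None and len(algorithm_indices) == 0)
        self.effective_fuse_ = "head2" if no_aa else self.fuse
        return self

    def _fuse_mode(self):
        return getattr(self, "effective_fuse_", self.fuse)
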