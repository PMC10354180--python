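"""Motion-based foreground extraction and pseudo-annotation generation.

Two extractors produce per-frame binary foreground masks from a clip with
a (near-)static background:

* :func:`extract_foreground_fe1` — per-pixel temporal mean/standard
  deviation thresholding: pixel (p, q) of frame i is foreground when
  ``|x[i,p,q] - mean[p,q]| > T * std[p,q]`` (strict inequality; sample
  std with the N-1 denominator). By the empirical rule T is typically 2,
  2.5 or 3; the default is 2.5.
* :func:`extract_foreground_median` — a robust alternative using the
  per-pixel temporal median as the background model and the scaled median
  absolute deviation (1.4826 * MAD, floored at ``EPS_SCALE``) as the
  dispersion scale. Its different background model makes its errors
  diverge from FE-1's, which is what the multi-source ensemble stage
  needs.

:func:`make_pseudo_annotation` converts a mask into the three-class dense
label map {0: background, 1: ant body, 2: ant boundary}; the boundary ring
(morphological dilation minus the body) keeps nearby or touching ants
separable in the dense prediction.

Color frames are converted to luma grayscale before statistics by default;
a per-channel mode flags a pixel as foreground when any channel triggers.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from skimage.morphology import dilation as _dilation, disk, remove_small_objects
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PixelStatistics",
    "compute_pixel_statistics",
    "extract_foreground_fe1",
    "extract_foreground_median",
    "make_pseudo_annotation",
    "annotate_sequence",
    "PixelStatsExtractor",
    "MedianExtractor",
    "EPS_SCALE",
]

#: floor on the scaled-MAD dispersion to avoid zero-scale comparisons
EPS_SCALE = 1e-6

_LUMA = np.array([0.299, 0.587, 0.114])


class PixelStatistics(NamedTuple):
    """Per-pixel temporal mean and sample standard deviation maps."""

    mean: np.ndarray
    std: np.ndarray


def _prepare(frames, color_mode="luma"):
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 4 and frames.shape[-1] == 1:
        frames = frames[..., 0]
    if frames.ndim == 4:
        if frames.shape[-1] != 3:
            raise ValueError("color frames must have 3 channels")
        if color_mode == "luma":
            frames = frames @ _LUMA
    elif frames.ndim != 3:
        raise ValueError("frames must be (N, H, W) or (N, H, W, C)")
    return frames


def compute_pixel_statistics(frames, color_mode="luma") -> PixelStatistics:
    """Temporal mean and sample std (N-1 denominator) per pixel.

    Requires at least two frames (the sample std is undefined otherwise).
    """
    frames = _prepare(frames, color_mode)
    if frames.shape[0] < 2:
        raise ValueError("pixel statistics require at least 2 frames")
    return PixelStatistics(mean=frames.mean(axis=0),
                           std=frames.std(axis=0, ddof=1))


def extract_foreground_fe1(frames, stats: PixelStatistics = None, T: float = 2.5,
                           color_mode: str = "luma") -> np.ndarray:
    """Mean/std thresholding: foreground where ``|x - mean| > T * std``.

    The comparison is strictly greater-than, so pixels with zero temporal
    std are never foreground. The rule is invariant to positive affine
    intensity transforms of the whole sequence. Returns (N, H, W) bool
    (per-channel color mode ORs the channel decisions).
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    frames = _prepare(frames, color_mode)
    if stats is None:
        if frames.shape[0] < 2:
            raise ValueError("pixel statistics require at least 2 frames")
        stats = PixelStatistics(mean=frames.mean(axis=0),
                                std=frames.std(axis=0, ddof=1))
    if stats.mean.shape != frames.shape[1:]:
        raise ValueError(
            f"statistics shape {stats.mean.shape} does not match frame "
            f"shape {frames.shape[1:]}")
    fg = np.abs(frames - stats.mean) > T * stats.std
    if fg.ndim == 4:
        fg = fg.any(axis=-1)
    return fg


def extract_foreground_median(frames, k_mad: float = 3.0,
                              color_mode: str = "luma") -> np.ndarray:
    """Median/MAD thresholding: foreground where
    ``|x - median| > k_mad * max(1.4826 * MAD, EPS_SCALE)``.

    Requires at least 3 frames. The ``EPS_SCALE`` floor lets gross
    outliers at otherwise perfectly stable pixels still be detected while
    keeping constant videos all-background.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be > 0")
    frames = _prepare(frames, color_mode)
    if frames.shape[0] < 3:
        raise ValueError("median extractor requires at least 3 frames")
    med = np.median(frames, axis=0)
    mad = np.median(np.abs(frames - med), axis=0)
    scale = np.maximum(1.4826 * mad, EPS_SCALE)
    fg = np.abs(frames - med) > k_mad * scale
    if fg.ndim == 4:
        fg = fg.any(axis=-1)
    return fg


def make_pseudo_annotation(mask, min_area: int = 5, boundary_radius: int = 2
                           ) -> np.ndarray:
    """Binary mask -> three-class label map.

    Connected components with area < ``min_area`` are removed (speckle
    suppression); remaining foreground becomes class 1; the Euclidean-disk
    dilation of class 1 minus class 1 becomes class 2; everything else is
    class 0. Classes are mutually exclusive and jointly exhaustive.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("make_pseudo_annotation expects a single 2-D mask")
    if min_area > 1:
        # remove components with area < min_area (i.e. area <= min_area - 1)
        body = remove_small_objects(mask, max_size=min_area - 1)
    else:
        body = mask.copy()
    lm = np.zeros(mask.shape, dtype=np.uint8)
    if boundary_radius > 0:
        ring = _dilation(body, disk(boundary_radius)) & ~body
        lm[ring] = 2
    lm[body] = 1
    return lm


def annotate_sequence(masks, min_area: int = 5, boundary_radius: int = 2
                      ) -> np.ndarray:
    """Apply :func:`make_pseudo_annotation` frame-by-frame."""
    masks = np.asarray(masks, dtype=bool)
    return np.stack([make_pseudo_annotation(m, min_area, boundary_radius)
                     for m in masks])


class PixelStatsExtractor(TransformerMixin, BaseEstimator):
    """Mean/std motion extractor as a scikit-learn transformer.

    ``fit`` computes the per-pixel temporal statistics of the clip;
    ``transform`` thresholds (the spec of the method requires transforming
    the same clip the statistics came from). ``transform`` returns the
    three-class pseudo-annotation stack; use ``transform_mask`` for the
    raw binary masks.
    """

    def __init__(self, T=2.5, min_area=5, boundary_radius=2,
                 color_mode="luma"):
        self.T = T
        self.min_area = min_area
        self.boundary_radius = boundary_radius
        self.color_mode = color_mode

    def fit(self, X, y=None):
        self.statistics_ = compute_pixel_statistics(X, self.color_mode)
        return self

    def transform_mask(self, X):
        return extract_foreground_fe1(X, self.statistics_, T=self.T,
                                      color_mode=self.color_mode)

    def transform(self, X):
        return annotate_sequence(self.transform_mask(X), self.min_area,
                                 self.boundary_radius)


class MedianExtractor(TransformerMixin, BaseEstimator):
    """Median/MAD motion extractor as a scikit-learn transformer."""

    def __init__(self, k_mad=3.0, min_area=5, boundary_radius=2,
                 color_mode="luma"):
        self.k_mad = k_mad
        self.min_area = min_area
        self.boundary_radius = boundary_radius
        self.color_mode = color_mode

    def fit(self, X, y=None):
        frames = _prepare(X, self.color_mode)
        self.median_ = np.median(frames, axis=0)
        return self

    def transform_mask(self, X):
        return extract_foreground_median(X, k_mad=self.k_mad,
                                         color_mode=self.color_mode)

    def transform(self, X):
        return annotate_sequence(self.transform_mask(X), self.min_area,
                                 self.boundary_radius)
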