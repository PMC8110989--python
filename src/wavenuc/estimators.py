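"""Scikit-learn-style estimator interface to the four segmenters.

Each estimator treats a 3D volume (numpy array indexed ``[z, y, x]``) as one
sample and behaves like a clusterer over its voxels: ``fit(volume)``
segments and exposes the results as fitted attributes (``labels_``,
``nuclei_``, ``centroids_``); ``fit_predict(volume)`` returns the label
volume.  Parameters follow the get_params/set_params protocol, so the
estimators compose with scikit-learn model selection utilities.

The module-level functions in :mod:`wavenuc.segmentation` and
:mod:`wavenuc.baselines` do the actual work; these classes are the stateful
front end.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import baselines
from .segmentation import SegmentationConfig, segment

__all__ = [
    "WaveletSegmenter",
    "PointwiseDetector",
    "OtsuSegmenter",
    "DerivativesSumSegmenter",
]


class _VolumeSegmenterMixin:
    """Shared fit/predict plumbing over a 3D volume."""

    def _validate_volume(self, X) -> np.ndarray:
        v = np.asarray(X, dtype=float)
        if v.ndim != 3 or v.size == 0:
            raise ValueError(f"expected a non-empty 3D volume, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        return v

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Segment ``X`` and return its label volume."""
        return self.fit(X, y).labels_


class WaveletSegmenter(_VolumeSegmenterMixin, BaseEstimator):
    """Wavelet-based 3D nuclei segmentation.

    Parameters mirror :class:`wavenuc.segmentation.SegmentationConfig`; the
    only required one is ``radius``, the expected nucleus radius in pixels.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (Nz, Ny, Nx) integer label volume, 0 = background.
    nuclei_ : list of :class:`wavenuc.segmentation.Nucleus3D`.
    centroids_ : (n, 3) array of nucleus centroids (x, y, z).
    result_ : the full :class:`wavenuc.segmentation.SegmentationResult`.
    """

    def __init__(
        self,
        radius: float = 9.0,
        similarity_tol: float = 0.10,
        overlap_thresh: float = 0.80,
        intensity_floor: float = 0.20,
        shift_frac: float = 1.0 / 3.0,
        min_size_frac: float = 0.20,
        colocation_tol: float = 2.0,
        h_frac: float = 0.02,
        mother_sigma: float | None = None,
        voxel_size: tuple[float, float, float] | None = None,
    ):
        self.radius = radius
        self.similarity_tol = similarity_tol
        self.overlap_thresh = overlap_thresh
        self.intensity_floor = intensity_floor
        self.shift_frac = shift_frac
        self.min_size_frac = min_size_frac
        self.colocation_tol = colocation_tol
        self.h_frac = h_frac
        self.mother_sigma = mother_sigma
        self.voxel_size = voxel_size

    def _config(self) -> SegmentationConfig:
        kwargs = dict(
            similarity_tol=self.similarity_tol,
            overlap_thresh=self.overlap_thresh,
            intensity_floor=self.intensity_floor,
            shift_frac=self.shift_frac,
            min_size_frac=self.min_size_frac,
            colocation_tol=self.colocation_tol,
            h_frac=self.h_frac,
            voxel_size=self.voxel_size,
        )
        if self.mother_sigma is not None:
            kwargs["mother_sigma"] = self.mother_sigma
        return SegmentationConfig(**kwargs)

    def fit(self, X, y=None) -> "WaveletSegmenter":
        v = self._validate_volume(X)
        result = segment(v, radius=self.radius, config=self._config())
        self.result_ = result
        self.nuclei_ = result.nuclei
        self.labels_ = result.label_volume
        self.centroids_ = result.centroids
        return self


class PointwiseDetector(_VolumeSegmenterMixin, BaseEstimator):
    """Point-wise centre detector baseline (no masks, centres only)."""

    def __init__(self, h_frac: float = 0.10):
        self.h_frac = h_frac

    def fit(self, X, y=None) -> "PointwiseDetector":
        v = self._validate_volume(X)
        res = baselines.pointwise_segment(v, h_frac=self.h_frac)
        self.result_ = res
        self.centroids_ = res.centroids
        self.intensities_ = res.intensities
        self.labels_ = None
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Detect centres in ``X`` and return them as an (n, 3) array."""
        return self.fit(X, y).centroids_


class OtsuSegmenter(_VolumeSegmenterMixin, BaseEstimator):
    """Multilevel-Otsu threshold segmentation baseline."""

    def __init__(
        self,
        radius: float | None = None,
        min_size_frac: float = 0.20,
        classes: int = 3,
        gaussian_sigma: float = 2.0,
        sharpen_radius: float = 2.0,
        sharpen_amount: float = 1.0,
        wiener_window: int = 5,
    ):
        self.radius = radius
        self.min_size_frac = min_size_frac
        self.classes = classes
        self.gaussian_sigma = gaussian_sigma
        self.sharpen_radius = sharpen_radius
        self.sharpen_amount = sharpen_amount
        self.wiener_window = wiener_window

    def fit(self, X, y=None) -> "OtsuSegmenter":
        v = self._validate_volume(X)
        result = baselines.otsu_segment(
            v,
            radius=self.radius,
            min_size_frac=self.min_size_frac,
            classes=self.classes,
            gaussian_sigma=self.gaussian_sigma,
            sharpen_radius=self.sharpen_radius,
            sharpen_amount=self.sharpen_amount,
            wiener_window=self.wiener_window,
        )
        self.result_ = result
        self.nuclei_ = result.nuclei
        self.labels_ = result.label_volume
        self.centroids_ = result.centroids
        return self


class DerivativesSumSegmenter(_VolumeSegmenterMixin, BaseEstimator):
    """Derivatives-Sum (DS) segmentation baseline."""

    def __init__(
        self,
        w_grad: float = 1.0,
        w_lap: float = 1.0,
        w_hess: float = 1.0,
        radius: float | None = None,
        min_size_frac: float = 0.20,
        gaussian_sigma: float = 2.0,
        chain_overlap: float = 0.5,
    ):
        self.w_grad = w_grad
        self.w_lap = w_lap
        self.w_hess = w_hess
        self.radius = radius
        self.min_size_frac = min_size_frac
        self.gaussian_sigma = gaussian_sigma
        self.chain_overlap = chain_overlap

    def fit(self, X, y=None) -> "DerivativesSumSegmenter":
        v = self._validate_volume(X)
        result = baselines.ds_segment(
            v,
            weights=baselines.DSWeights(self.w_grad, self.w_lap, self.w_hess),
            radius=self.radius,
            min_size_frac=self.min_size_frac,
            gaussian_sigma=self.gaussian_sigma,
            chain_overlap=self.chain_overlap,
        )
        self.result_ = result
        self.nuclei_ = result.nuclei
        self.labels_ = result.label_volume
        self.centroids_ = result.centroids
        return self
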