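"""ROI masking, feature standardization and PCA reduction.

The classifier never sees the whole face: the aligned 300x300 image is
multiplied by the binary fat-pad mask (grayscale BT.601 luma, [0, 1] range,
everything outside the mask forced to 0), described with HOG, z-scored with
statistics fitted on the training split only, and projected onto the top
100 principal components of the training features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .hog import HogParams, hog, hog_length

__all__ = ["apply_mask", "Standardizer", "PcaModel", "extract_hog_features"]

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


def apply_mask(face: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Merge a face image with its {0,255} ROI mask.

    Returns a grayscale image in [0, 1]: masked-out pixels are exactly 0,
    masked-in pixels keep the (luma-converted) face value.
    """
    face = np.asarray(face, dtype=np.float64)
    mask = np.asarray(mask)
    if face.shape[:2] != mask.shape:
        raise ValueError(f"shape mismatch: face {face.shape[:2]} vs mask {mask.shape}")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError("mask is not binary {0,255}")
    gray = face @ _LUMA if face.ndim == 3 else face
    return np.where(mask == 255, gray, 0.0)


@dataclass
class Standardizer:
    """Per-feature z-scoring with population sigma, fitted on training data.

    Constant features (sigma = 0) are passed through centered but unscaled,
    so they standardize to exactly 0.
    """

    _scaler: StandardScaler | None = field(default=None, repr=False)

    @property
    def mean(self) -> np.ndarray:
        self._require_fit()
        return self._scaler.mean_

    @property
    def sd(self) -> np.ndarray:
        self._require_fit()
        return self._scaler.scale_

    def _require_fit(self) -> None:
        if self._scaler is None:
            raise RuntimeError("Standardizer used before fit")

    def fit(self, vectors: np.ndarray) -> "Standardizer":
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] < 2:
            raise ValueError("need at least 2 training vectors")
        # StandardScaler uses population variance and replaces zero scales by 1
        self._scaler = StandardScaler().fit(vectors)
        return self

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        self._require_fit()
        return self._scaler.transform(np.asarray(vectors, dtype=np.float64))


def fit_standardizer(train_vectors: np.ndarray) -> Standardizer:
    return Standardizer().fit(train_vectors)


@dataclass
class PcaModel:
    """Top-k principal components of the training features.

    Component signs are fixed so each component's largest-magnitude loading
    is positive, making the projection deterministic across runs.
    """

    components: np.ndarray  # (k, d), orthonormal rows
    center: np.ndarray  # (d,)
    explained_variance: np.ndarray  # (k,)

    def reduce(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.asarray(vectors, dtype=np.float64)
        return (vectors - self.center) @ self.components.T

    def reconstruct(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.components + self.center

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


def fit_pca(train_vectors: np.ndarray, k: int = 100, seed: int = 0) -> PcaModel:
    """Fit PCA on training vectors; k must not exceed min(n_samples, n_features)."""
    x = np.asarray(train_vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    bound = min(x.shape)
    if k > bound:
        raise ValueError(
            f"k={k} exceeds min(n_samples, n_features)={bound}"
        )
    pca = PCA(n_components=k, svd_solver="auto", random_state=seed).fit(x)
    comps = pca.components_.copy()
    flip = comps[np.arange(k), np.abs(comps).argmax(axis=1)] < 0
    comps[flip] *= -1.0
    return PcaModel(
        components=comps,
        center=pca.mean_,
        explained_variance=pca.explained_variance_,
    )


def extract_hog_features(
    roi_images: "list[np.ndarray]", params: HogParams = HogParams()
) -> np.ndarray:
    """Stack HOG descriptors of ROI images into an (n, L) float32 matrix."""
    if not roi_images:
        raise ValueError("no images given")
    h, w = roi_images[0].shape
    out = np.empty((len(roi_images), hog_length(w, h, params)), dtype=np.float32)
    for i, img in enumerate(roi_images):
        out[i] = hog(img, params)
    return out
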