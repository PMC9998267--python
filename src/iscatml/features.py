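"""User-defined spatio-temporal feature matrix + isolation-forest classification.

For one analysis frame t of the ratiometric (DRA) stack, every unmasked pixel
is described by a feature vector combining temporal statistics over a window
of frames centered on t (mean, standard deviation, slope, min, max) and
spatial statistics of frame t itself (normalized correlation with a Gaussian
PSF template and local variance).  Landing events are rare, so the pixels
they occupy are anomalies of the per-pixel feature distribution; an isolation
forest flags them without any supervision.  A morphological filter then
removes isolated flagged pixels, which are overwhelmingly false positives:
a real event is a PSF and always covers several neighboring pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage
from sklearn.ensemble import IsolationForest

from .dra import RatiometricStack
from .simulator import DEFAULT_PSF_HWHM, gaussian_psf, hwhm_to_sigma

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "AnomalyMask",
    "build_feature_matrix",
    "iforest_classify",
    "morphological_filter",
]

TEMPORAL_FEATURES = ("mean", "std", "slope", "min", "max")
SPATIAL_FEATURES = ("psf_correlation", "local_variance")


class FeatureSpec(BaseModel):
    """Feature-bank definition.

    ``window_half_width`` is in ratiometric-stack frames; the temporal window
    is ``[t - w, t + w]``.  The default bank covers the categories a
    practitioner would reach for — temporal moments and extrema plus
    PSF-shaped spatial structure — and is a re-derived default, configurable
    per dataset.
    """

    window_half_width: int = Field(2, ge=1)
    temporal_features: list[str] = list(TEMPORAL_FEATURES)
    spatial_features: list[str] = list(SPATIAL_FEATURES)
    psf_hwhm: float = Field(DEFAULT_PSF_HWHM, gt=0.0)

    def model_post_init(self, __context) -> None:
        for f in self.temporal_features:
            if f not in TEMPORAL_FEATURES:
                raise ValueError(f"unknown temporal feature {f!r}")
        for f in self.spatial_features:
            if f not in SPATIAL_FEATURES:
                raise ValueError(f"unknown spatial feature {f!r}")
        if not self.temporal_features or not self.spatial_features:
            raise ValueError("need at least one temporal and one spatial feature")


@dataclass
class FeatureMatrix:
    """Per-pixel feature table for one analysis frame.

    ``values``: (n_unmasked_pixels, n_features), column-standardized.
    ``pixel_index``: (n_unmasked_pixels, 2) integer (row, col) map back to
    frame geometry.  ``frame_shape`` restores mask geometry downstream.
    """

    values: np.ndarray
    pixel_index: np.ndarray
    columns: list[str]
    frame_index: int
    frame_shape: tuple[int, int]


@dataclass
class AnomalyMask:
    """Boolean anomaly frame (True = anomalous pixel)."""

    mask: np.ndarray
    frame_index: int
    path: str = "features"
    params: dict = field(default_factory=dict)


def _psf_correlation(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Zero-mean Gaussian-template correlation, per pixel.

    Equivalent to convolving with a mean-subtracted PSF template: responds to
    PSF-shaped bumps of either sign's magnitude preserved (signed response).
    """
    size = max(3, int(round(4 * sigma)) | 1)
    half = size // 2
    template = gaussian_psf((size, size), (half, half), sigma)
    template -= template.mean()
    template /= np.sqrt((template**2).sum())
    return ndimage.correlate(frame, template, mode="nearest")


def build_feature_matrix(ratio_stack: RatiometricStack | np.ndarray, t: int,
                         spec: FeatureSpec,
                         mask: np.ndarray | None = None) -> FeatureMatrix:
    """Assemble the standardized feature matrix for analysis frame ``t``.

    Temporal features are computed per pixel over ``t ± window_half_width``;
    spatial features on frame ``t``.  Each enabled feature becomes one
    standardized column (zero mean, unit variance over the unmasked pixels;
    constant columns are set to zero).  ``mask`` (True = keep) defaults to
    all finite pixels of frame t.
    """
    data = ratio_stack.data if isinstance(ratio_stack, RatiometricStack) else np.asarray(ratio_stack)
    w = spec.window_half_width
    if t - w < 0 or t + w >= data.shape[0]:
        raise ValueError(f"temporal window [{t - w}, {t + w}] outside stack "
                         f"of {data.shape[0]} frames")
    cube = np.asarray(data[t - w: t + w + 1], dtype=float)
    frame = cube[w]
    if mask is None:
        mask = np.isfinite(frame)
    else:
        mask = np.asarray(mask, bool) & np.isfinite(frame)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in spec.temporal_features:
        if name == "mean":
            f = cube.mean(axis=0)
        elif name == "std":
            f = cube.std(axis=0)
        elif name == "min":
            f = cube.min(axis=0)
        elif name == "max":
            f = cube.max(axis=0)
        elif name == "slope":
            tt = np.arange(cube.shape[0]) - w
            f = np.tensordot(tt, cube, axes=(0, 0)) / np.sum(tt**2)
        cols.append(f)
        names.append(f"t_{name}")

    filled = np.where(np.isfinite(frame), frame, 0.0)
    sigma = hwhm_to_sigma(spec.psf_hwhm)
    for name in spec.spatial_features:
        if name == "psf_correlation":
            f = _psf_correlation(filled, sigma)
        elif name == "local_variance":
            mean = ndimage.uniform_filter(filled, 3, mode="nearest")
            mean2 = ndimage.uniform_filter(filled**2, 3, mode="nearest")
            f = np.maximum(mean2 - mean**2, 0.0)
        cols.append(f)
        names.append(f"s_{name}")

    values = np.stack([c[mask] for c in cols], axis=1)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = np.inf  # constant columns -> zeros
    values = (values - mu) / sd
    pixel_index = np.argwhere(mask)
    return FeatureMatrix(values=values, pixel_index=pixel_index, columns=names,
                         frame_index=t, frame_shape=frame.shape)


def iforest_classify(matrix: FeatureMatrix, contamination: float = 0.01,
                     n_trees: int = 100, seed: int = 0,
                     max_samples: int = 256) -> AnomalyMask:
    """Isolation-forest anomaly classification of the feature matrix.

    Scores from a seeded forest are thresholded at the contamination
    quantile, so the flagged fraction equals ``contamination`` up to ties.
    A degenerate matrix (all rows identical) yields an empty mask with a
    warning — there is nothing to isolate.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 rows to classify")
    if not 0.0 < contamination < 0.5:
        raise ValueError("contamination must be in (0, 0.5)")
    out = np.zeros(matrix.frame_shape, dtype=bool)
    if np.allclose(matrix.values, matrix.values[0]):
        warnings.warn("degenerate feature matrix (all rows identical); "
                      "returning empty anomaly mask", stacklevel=2)
        return AnomalyMask(out, matrix.frame_index, path="features",
                           params={"contamination": contamination, "degenerate": True})
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(max_samples, matrix.values.shape[0]),
        contamination=contamination, random_state=seed)
    forest.fit(matrix.values)
    scores = forest.score_samples(matrix.values)  # lower = more anomalous
    threshold = np.quantile(scores, contamination)
    flagged = scores <= threshold
    out[matrix.pixel_index[flagged, 0], matrix.pixel_index[flagged, 1]] = True
    return AnomalyMask(out, matrix.frame_index, path="features",
                       params={"contamination": contamination,
                               "n_trees": n_trees, "seed": seed})


def morphological_filter(mask: AnomalyMask | np.ndarray,
                         min_connected: int = 2) -> AnomalyMask | np.ndarray:
    """Remove connected components smaller than ``min_connected`` pixels.

    8-connectivity.  A genuine landing event is a PSF and covers neighboring
    pixels; isolated flagged pixels are noise.  ``min_connected=1`` is the
    identity; raising it trades detection yield for false-positive
    suppression (the hardest, smallest-protein regimes warrant 3).
    """
    if min_connected < 1:
        raise ValueError("min_connected must be >= 1")
    arr = mask.mask if isinstance(mask, AnomalyMask) else np.asarray(mask, bool)
    if min_connected == 1:
        filtered = arr.copy()
    else:
        labels, n = ndimage.label(arr, structure=np.ones((3, 3), int))
        sizes = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, bool)
        keep[1:] = sizes[1:] >= min_connected
        filtered = keep[labels]
    if isinstance(mask, AnomalyMask):
        return AnomalyMask(filtered, mask.frame_index, path=mask.path,
                           params={**mask.params, "min_connected": min_connected})
    return filtered
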