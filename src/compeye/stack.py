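"""Depth-from-focus surface reconstruction.

A microscope focus stack images the same eye at fixed focal-depth
increments ``delta_h``.  Where the eye surface passes through a layer's
focal plane, local contrast is maximal, so the per-pixel argmax of a
local-contrast score across layers encodes surface height.  The
reconstruction yields a height map, an eye mask, and an all-in-focus
composite image used downstream for sphere fitting and facet detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator

from .exceptions import NoFocusableSurfaceError, ValidationError

__all__ = [
    "FocusStack",
    "EyeSurface",
    "SurfaceReconstructor",
    "focus_metric",
    "reconstruct_surface",
]


@dataclass
class FocusStack:
    """An ordered through-focus image series.

    Parameters
    ----------
    layers : ndarray, shape (n_layers, H, W)
        Grayscale images ordered by focal depth.  Layer 0 defines height 0;
        height increases with layer index.
    delta_h : float
        Focal-depth step between consecutive layers, micrometers.
    pixel_scale : float
        Micrometers per pixel in the image plane.
    """

    layers: np.ndarray
    delta_h: float
    pixel_scale: float

    def __post_init__(self) -> None:
        try:
            self.layers = np.asarray(self.layers, dtype=float)
        except ValueError as exc:
            raise ValidationError(
                "layers of mismatched shapes cannot be stacked"
            ) from exc
        if self.layers.ndim != 3:
            raise ValidationError(
                "layers must be a 3D array (n_layers, H, W); layers of "
                "mismatched shapes cannot be stacked"
            )
        if self.layers.shape[0] < 2:
            raise ValidationError("a focus stack needs at least 2 layers")
        if not self.delta_h > 0:
            raise ValidationError("delta_h must be positive")
        if not self.pixel_scale > 0:
            raise ValidationError("pixel_scale must be positive")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def depth_range(self) -> float:
        """Total height span covered by the stack, micrometers."""
        return (self.n_layers - 1) * self.delta_h


@dataclass
class EyeSurface:
    """Reconstructed 3D eye surface.

    ``heights`` is in micrometers above layer 0's focal plane and is NaN
    outside ``mask``.  ``composite`` is the all-in-focus image.
    """

    heights: np.ndarray
    mask: np.ndarray
    composite: np.ndarray
    delta_h: float
    pixel_scale: float
    meta: dict = field(default_factory=dict)

    def points(self) -> np.ndarray:
        """Masked surface pixels as (N, 3) points in micrometers (x, y, z)."""
        rows, cols = np.nonzero(self.mask)
        return np.column_stack(
            [
                cols * self.pixel_scale,
                rows * self.pixel_scale,
                self.heights[rows, cols],
            ]
        )


def focus_metric(stack: FocusStack, window: int = 5) -> np.ndarray:
    """Per-layer local-contrast score maps.

    The score is the standard deviation of intensity within a square
    ``window`` centered on each pixel, which is invariant to adding a
    constant to all intensities.

    Returns
    -------
    ndarray, shape (n_layers, H, W), non-negative.
    """
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 3")
    scores = np.empty_like(stack.layers)
    for k, layer in enumerate(stack.layers):
        mean = ndimage.uniform_filter(layer, size=window, mode="nearest")
        mean_sq = ndimage.uniform_filter(layer**2, size=window, mode="nearest")
        var = np.maximum(mean_sq - mean**2, 0.0)
        scores[k] = np.sqrt(var)
    return scores


def _parabolic_refine(scores: np.ndarray, best: np.ndarray) -> np.ndarray:
    """Sub-layer refinement of the argmax by a 3-point parabola.

    ``scores`` is (n_layers, H, W); ``best`` the integer argmax per pixel.
    Edge layers and degenerate (flat) triplets keep the integer argmax.
    Offsets are clipped to [-0.5, 0.5] so refinement never crosses a layer.
    """
    n = scores.shape[0]
    refined = best.astype(float)
    interior = (best > 0) & (best < n - 1)
    if not interior.any():
        return refined
    rows, cols = np.nonzero(interior)
    k = best[rows, cols]
    s_lo = scores[k - 1, rows, cols]
    s_mid = scores[k, rows, cols]
    s_hi = scores[k + 1, rows, cols]
    denom = s_lo - 2.0 * s_mid + s_hi
    offset = np.zeros_like(s_mid)
    ok = np.abs(denom) > 1e-12
    offset[ok] = 0.5 * (s_lo[ok] - s_hi[ok]) / denom[ok]
    offset = np.clip(offset, -0.5, 0.5)
    refined[rows, cols] = k + offset
    return refined


class SurfaceReconstructor(BaseEstimator):
    """Estimator mapping a :class:`FocusStack` to an :class:`EyeSurface`.

    Parameters
    ----------
    window : int, default 5
        Side of the square local-contrast window, pixels (odd, >= 3).
    mask_threshold : float, default 0.1
        Pixels whose best focus score exceeds this fraction of the global
        maximum form the candidate eye region; the largest connected
        component is kept and holes are filled.
    interpolate : bool, default True
        Parabolic sub-layer interpolation of the argmax (ties broken
        toward the lower layer index by the argmax itself).
    """

    def __init__(self, window: int = 5, mask_threshold: float = 0.1,
                 interpolate: bool = True):
        self.window = window
        self.mask_threshold = mask_threshold
        self.interpolate = interpolate

    def fit(self, stack: FocusStack) -> "SurfaceReconstructor":
        scores = focus_metric(stack, self.window)
        best_score = scores.max(axis=0)
        global_max = best_score.max()
        if global_max <= 0:
            raise NoFocusableSurfaceError(
                "no focusable surface: all focus scores are zero"
            )
        best = scores.argmax(axis=0)

        mask = best_score > self.mask_threshold * global_max
        labels = measure.label(mask, connectivity=2)
        if labels.max() > 0:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = labels == sizes.argmax()
        mask = ndimage.binary_fill_holes(mask)

        if self.interpolate:
            layer_idx = _parabolic_refine(scores, best)
        else:
            layer_idx = best.astype(float)
        heights = np.clip(layer_idx * stack.delta_h, 0.0, stack.depth_range)
        heights = np.where(mask, heights, np.nan)

        rows, cols = np.indices(best.shape)
        composite = stack.layers[best, rows, cols]

        self.scores_ = scores
        self.surface_ = EyeSurface(
            heights=heights,
            mask=mask,
            composite=composite,
            delta_h=stack.delta_h,
            pixel_scale=stack.pixel_scale,
        )
        return self

    def transform(self, stack: FocusStack) -> EyeSurface:
        return self.fit(stack).surface_

    fit_transform = transform


def reconstruct_surface(stack: FocusStack, window: int = 5,
                        mask_threshold: float = 0.1) -> EyeSurface:
    """Functional wrapper over :class:`SurfaceReconstructor`."""
    return SurfaceReconstructor(window=window,
                                mask_threshold=mask_threshold).transform(stack)
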