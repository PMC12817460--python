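"""Radiograph preprocessing: resizing, Otsu background removal, morphological
contrast enhancement, and cartoon-texture decomposition.

These are the alternatives compared by the classification harness; plain
resizing is the default pipeline.  All operations take and return 2-D float
or integer grayscale arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology
from skimage.restoration import denoise_tv_chambolle
from skimage.transform import resize as _sk_resize


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined, e.g. thresholding a constant image."""


@dataclass(frozen=True)
class ThresholdResult:
    """Otsu threshold and its between-class statistics.

    ``var_between = p0 * p1 * (m0 - m1)^2`` where p0/p1 are the background /
    foreground probabilities and m0/m1 their mean intensities at threshold T.
    """

    T: float
    var_between: float
    p0: float
    p1: float
    m0: float
    m1: float


def resize_image(pixels: np.ndarray, target_size: int | tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``target_size`` (side length or (rows, cols))."""
    if isinstance(target_size, int):
        target_size = (target_size, target_size)
    if target_size[0] <= 0 or target_size[1] <= 0:
        raise ValueError(f"target_size must be positive, got {target_size}")
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape == tuple(target_size):
        return pixels.copy()
    return _sk_resize(pixels, target_size, order=1, anti_aliasing=False, preserve_range=True)


def otsu_candidates(pixels: np.ndarray) -> np.ndarray:
    """The 256 candidate cut values scored by :func:`otsu_threshold`.

    Candidates are evenly spaced over (lo, hi] of the image's intensity
    range — a 256-level quantization grid that is independent of the input
    bit depth.  For 8-bit data with full range this is the classic per-level
    threshold sweep.
    """
    flat = np.asarray(pixels, dtype=float).ravel()
    lo, hi = flat.min(), flat.max()
    return lo + (hi - lo) * np.arange(1, 257) / 256.0


def otsu_threshold(pixels: np.ndarray) -> ThresholdResult:
    """Between-class-variance-maximizing global threshold.

    Every candidate cut T (256-level grid, see :func:`otsu_candidates`) is
    scored with var(T) = P0(T)·P1(T)·(m0(T) − m1(T))², where class 0 holds
    the pixels strictly below T; class statistics are exact (computed from
    the pixel values, not bin centers).  Ties resolve to the lowest T.
    """
    pixels = np.asarray(pixels)
    values = np.unique(pixels.astype(float))
    if values.size < 2:
        raise DegenerateImageError("Otsu threshold undefined for a constant image")
    flat = np.sort(pixels.astype(float).ravel())
    n = flat.size
    cum_sum = np.concatenate([[0.0], np.cumsum(flat)])
    candidates = otsu_candidates(pixels)
    # k[i] = number of pixels strictly below candidate i
    k = np.searchsorted(flat, candidates, side="left")
    p0 = k / n
    p1 = 1.0 - p0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cum_sum[k] / np.maximum(k, 1)
        m1 = (cum_sum[-1] - cum_sum[k]) / np.maximum(n - k, 1)
    var = p0 * p1 * (m0 - m1) ** 2
    var = np.where((k > 0) & (k < n), var, -np.inf)
    t = int(np.argmax(var))  # argmax returns the first (lowest) maximizer
    return ThresholdResult(
        T=float(candidates[t]),
        var_between=float(var[t]),
        p0=float(p0[t]),
        p1=float(p1[t]),
        m0=float(m0[t]),
        m1=float(m1[t]),
    )


def remove_background(pixels: np.ndarray) -> np.ndarray:
    """Zero out pixels below the Otsu threshold; foreground is untouched."""
    result = otsu_threshold(pixels)
    pixels = np.asarray(pixels)
    out = pixels.copy()
    out[pixels < result.T] = 0
    return out


def top_bottom_hat(pixels: np.ndarray, radius: int = 15) -> np.ndarray:
    """Contrast enhancement: input + white top-hat − black bottom-hat.

    The top-hat (opening residual) lifts small bright structures and the
    bottom-hat (closing residual) deepens small dark ones; a disk structuring
    element of the given radius sets the feature scale.  Output is clipped to
    the input range.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    pixels = np.asarray(pixels, dtype=float)
    footprint = morphology.disk(radius)
    top = morphology.white_tophat(pixels, footprint)
    bottom = morphology.black_tophat(pixels, footprint)
    return np.clip(pixels + top - bottom, pixels.min(), pixels.max())


def cartoon_texture(pixels: np.ndarray, scale: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Split an image into a piecewise-smooth cartoon and an oscillatory texture.

    The cartoon is the total-variation-regularized component (Chambolle
    projection, regularization weight proportional to ``scale``); the texture
    is the exact residual, so ``cartoon + texture == input`` to machine
    precision.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    pixels = np.asarray(pixels, dtype=float)
    span = pixels.max() - pixels.min()
    if span == 0:
        return pixels.copy(), np.zeros_like(pixels)
    # TV weight expressed relative to the intensity span so behaviour is
    # bit-depth independent.
    cartoon = denoise_tv_chambolle(pixels, weight=0.02 * scale * span)
    texture = pixels - cartoon
    return cartoon, texture
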