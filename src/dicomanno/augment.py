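"""Training-time augmentation: random batch transforms, polarity inversion,
and SMOTE oversampling of tail classes.

The batch transform applies, per image and with independent draws: a
dihedral-group op (p=0.5), an extra rotation of up to ±10° (p=0.75), a zoom
in [0.9, 1.1] with perspective warp of magnitude 0.2 (p=0.75), a brightness/
contrast change of at most 0.2 (p=0.75), and a random resize-crop with area
scale in [0.9, 1.0].  Random inversion (p=0.5) balances dark- and
light-background radiographs.  SMOTE interpolates synthetic tail-class
samples between nearest same-class neighbours until classes are balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, resize as _sk_resize, warp as _sk_warp
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class AugmentationConfig:
    """Batch-transform parameters; the defaults are the training protocol's."""

    p_dihedral: float = 0.5
    p_rotate: float = 0.75
    max_extra_deg: float = 10.0
    p_zoom: float = 0.75
    zoom_range: tuple[float, float] = (0.9, 1.1)
    warp: float = 0.2
    p_light: float = 0.75
    light_scale: float = 0.2
    crop_scale: tuple[float, float] = (0.9, 1.0)
    p_invert: float = 0.5
    smote_k: int = 5

    def __post_init__(self) -> None:
        for p in (self.p_dihedral, self.p_rotate, self.p_zoom, self.p_light, self.p_invert):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.zoom_range[0] > self.zoom_range[1] or self.crop_scale[0] > self.crop_scale[1]:
            raise ValueError("zoom/crop ranges must be ordered")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        """A configuration under which the batch transform is the identity."""
        return cls(p_dihedral=0, p_rotate=0, p_zoom=0, p_light=0, crop_scale=(1.0, 1.0), p_invert=0)


@dataclass
class FeatureMatrix:
    """Rectangular per-sample feature rows plus one class label per row."""

    rows: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.rows.ndim != 2 or self.rows.shape[0] != self.labels.shape[0]:
            raise ValueError("rows must be 2-D with one label per row")


def _dihedral(img: np.ndarray, op: int) -> np.ndarray:
    """One of the 8 symmetries of the square (4 rotations x optional flip)."""
    out = np.rot90(img, op % 4)
    if op >= 4:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def _zoom_warp(img: np.ndarray, scale: float, warp_mag: float, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape
    src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    center = np.array([w / 2.0, h / 2.0])
    # Zoom about the center: scale > 1 magnifies.
    dst = center + (src - center) / scale
    # Perspective warp: displace each corner by at most warp_mag/2 of the side.
    dst = dst + rng.uniform(-warp_mag / 2, warp_mag / 2, size=(4, 2)) * [w, h]
    tform = ProjectiveTransform.from_estimate(dst, src)
    return _sk_warp(img, tform, order=1, mode="edge", preserve_range=True)


def _resize_crop(img: np.ndarray, area_scale: float, rng: np.random.Generator) -> np.ndarray:
    if area_scale >= 1.0:
        return img
    h, w = img.shape
    ch = max(1, int(round(h * np.sqrt(area_scale))))
    cw = max(1, int(round(w * np.sqrt(area_scale))))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    crop = img[top : top + ch, left : left + cw]
    return _sk_resize(crop, (h, w), order=1, anti_aliasing=False, preserve_range=True)


def random_batch_transform(
    batch: np.ndarray,
    cfg: AugmentationConfig = AugmentationConfig(),
    rng: np.random.Generator | None = None,
    return_log: bool = False,
):
    """Apply the stochastic batch transform to a (N, H, W) image stack.

    Each image receives independent draws; output shape equals input shape.
    With ``return_log=True`` a dict of per-op application counts is returned
    alongside the batch (used to audit the configured application rates).
    """
    rng = rng if rng is not None else np.random.default_rng()
    batch = np.asarray(batch, dtype=float)
    out = np.empty_like(batch)
    log = {"dihedral": 0, "rotate": 0, "zoom": 0, "light": 0, "n": batch.shape[0]}
    for i, img in enumerate(batch):
        lo, hi = img.min(), img.max()
        if rng.random() < cfg.p_dihedral:
            img = _dihedral(img, int(rng.integers(0, 8)))
            log["dihedral"] += 1
        if rng.random() < cfg.p_rotate:
            angle = rng.uniform(-cfg.max_extra_deg, cfg.max_extra_deg)
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=lo)
            log["rotate"] += 1
        if rng.random() < cfg.p_zoom:
            scale = rng.uniform(*cfg.zoom_range)
            img = _zoom_warp(img, scale, cfg.warp, rng)
            log["zoom"] += 1
        if rng.random() < cfg.p_light:
            span = hi - lo
            brightness = rng.uniform(-cfg.light_scale, cfg.light_scale) * span
            contrast = 1.0 + rng.uniform(-cfg.light_scale, cfg.light_scale)
            img = np.clip((img - img.mean()) * contrast + img.mean() + brightness, lo, hi)
            log["light"] += 1
        if cfg.crop_scale != (1.0, 1.0):
            img = _resize_crop(img, rng.uniform(*cfg.crop_scale), rng)
        out[i] = img
    return (out, log) if return_log else out


def random_invert(
    batch: np.ndarray, p: float = 0.5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Invert each image with probability ``p`` (v -> min + max - v).

    Inversion is an involution about the image's own intensity range, so
    applying it twice restores the original exactly.
    """
    rng = rng if rng is not None else np.random.default_rng()
    batch = np.asarray(batch, dtype=float)
    out = batch.copy()
    for i, img in enumerate(batch):
        if rng.random() < p:
            out[i] = img.min() + img.max() - img
    return out


def smote_tail_oversample(
    X: FeatureMatrix,
    k: int = 5,
    target_count: int | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """Balance tail classes with SMOTE interpolation.

    Every class below ``target_count`` (default: the largest class count, so
    the tail of the long-tailed distribution) is filled up.  Each synthetic
    row is x + u * (x_nn - x) with u ~ Uniform(0, 1) and x_nn one of the k
    nearest same-class neighbours, so it lies on a segment between two
    same-class originals.  Originals are retained verbatim; afterwards all
    class counts equal ``target_count``.  A single-member class falls back
    to duplication with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng()
    labels, counts = np.unique(X.labels, return_counts=True)
    if target_count is None:
        target_count = int(counts.max())
    new_rows = [X.rows]
    new_labels = [X.labels]
    for label, count in zip(labels, counts):
        if count >= target_count:
            continue
        rows = X.rows[X.labels == label]
        n_needed = target_count - count
        if count == 1:
            warnings.warn(
                f"class {label!r} has a single sample; SMOTE falls back to duplication",
                stacklevel=2,
            )
            synth = np.repeat(rows, n_needed, axis=0)
        else:
            k_eff = min(k, count - 1)
            nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(rows)
            _, idx = nn.kneighbors(rows)  # column 0 is the point itself
            base = rng.integers(0, count, size=n_needed)
            pick = rng.integers(1, k_eff + 1, size=n_needed)
            u = rng.uniform(0.0, 1.0, size=n_needed)[:, None]
            x = rows[base]
            x_nn = rows[idx[base, pick]]
            synth = x + u * (x_nn - x)
        new_rows.append(synth)
        new_labels.append(np.full(n_needed, label, dtype=X.labels.dtype))
    return FeatureMatrix(rows=np.vstack(new_rows), labels=np.concatenate(new_labels))


def images_to_features(images: np.ndarray, labels: np.ndarray, size: int = 32) -> FeatureMatrix:
    """Flatten a (N, H, W) stack into SMOTE feature rows (downsampled pixels)."""
    images = np.asarray(images, dtype=float)
    if images.shape[1:] != (size, size):
        images = np.stack(
            [_sk_resize(im, (size, size), order=1, anti_aliasing=False, preserve_range=True) for im in images]
        )
    return FeatureMatrix(rows=images.reshape(images.shape[0], -1), labels=labels)
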