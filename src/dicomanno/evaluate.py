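"""Evaluation: metrics, per-class report, multi-label confusion, t-SNE, CAM.

Precision/recall/F1 are macro-averaged by default (micro and weighted are
available), which is the convention consistent with a long-tailed class
distribution: overall accuracy can be high while macro precision stays low
because tail classes weigh equally.  Multi-label accuracy is subset
(exact-match) accuracy by default, with Hamming accuracy behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn import metrics as _skm
from sklearn.manifold import TSNE


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame  # columns: class, precision, recall, f1, support

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class MultiLabelConfusion:
    """Per-class TP/FP/TN/FN counts (+ cross-class table in single-label mode)."""

    classes: list
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    cross: pd.DataFrame | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.classes, "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}
        )


def _to_indicator(y, classes) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 2:
        return y.astype(int)
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(y), len(classes)), dtype=int)
    for i, label in enumerate(y):
        out[i, index[label]] = 1
    return out


def _infer_classes(y_true, y_pred, classes):
    if classes is not None:
        return list(classes)
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.ndim == 2:
        return list(range(y_true.shape[1]))
    return sorted(set(y_true.tolist()) | set(y_pred.tolist()))


def compute_metrics(
    y_true,
    y_pred,
    mode: str = "single",
    classes=None,
    average: str = "macro",
    multilabel_accuracy: str = "subset",
) -> MetricsReport:
    """Accuracy plus averaged precision/recall/F1 and a per-class report.

    Single-label inputs are label vectors; multi-label inputs are indicator
    matrices (or vectors of label sets via ``classes``).  Multi-label
    accuracy is exact-match by default (``multilabel_accuracy='hamming'``
    for per-label accuracy).
    """
    if len(np.asarray(y_true)) == 0:
        raise ValueError("empty input")
    classes = _infer_classes(y_true, y_pred, classes)
    T = _to_indicator(y_true, classes)
    P = _to_indicator(y_pred, classes)
    if mode == "single":
        accuracy = float((T.argmax(axis=1) == P.argmax(axis=1)).mean())
    elif multilabel_accuracy == "subset":
        accuracy = float((T == P).all(axis=1).mean())
    elif multilabel_accuracy == "hamming":
        accuracy = float((T == P).mean())
    else:
        raise ValueError(f"unknown multilabel_accuracy {multilabel_accuracy!r}")
    prec, rec, f1, support = _skm.precision_recall_fscore_support(
        T, P, average=None, zero_division=0
    )
    avg_prec, avg_rec, avg_f1, _ = _skm.precision_recall_fscore_support(
        T, P, average=average, zero_division=0
    )
    per_class = pd.DataFrame(
        {"class": classes, "precision": prec, "recall": rec, "f1": f1, "support": support}
    )
    return MetricsReport(
        accuracy=accuracy,
        precision=float(avg_prec),
        recall=float(avg_rec),
        f1=float(avg_f1),
        per_class=per_class,
    )


def confusion_matrix(y_true, y_pred, classes=None) -> MultiLabelConfusion:
    """Per-class TP/FP/TN/FN; adds the cross-class table for single-label input."""
    classes = _infer_classes(y_true, y_pred, classes)
    T = _to_indicator(y_true, classes)
    P = _to_indicator(y_pred, classes)
    mcm = _skm.multilabel_confusion_matrix(T, P)
    tn, fp, fn, tp = mcm[:, 0, 0], mcm[:, 0, 1], mcm[:, 1, 0], mcm[:, 1, 1]
    cross = None
    y_true_arr = np.asarray(y_true)
    if y_true_arr.ndim == 1:
        cm = _skm.confusion_matrix(y_true, y_pred, labels=classes)
        cross = pd.DataFrame(cm, index=classes, columns=classes)
    return MultiLabelConfusion(classes=classes, tp=tp, fp=fp, tn=tn, fn=fn, cross=cross)


def tsne_projection(features: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """Seed-deterministic 2-D t-SNE embedding (one (x, y) row per sample)."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 3:
        raise ValueError("t-SNE projection needs at least 3 samples")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, init="pca", perplexity=perplexity)
    return tsne.fit_transform(features)


def export_tsne_csv(coords: np.ndarray, labels, path) -> None:
    pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": list(labels)}).to_csv(
        path, index=False
    )


def class_activation_map(model, image: np.ndarray, class_id: int, normalize: bool = True) -> np.ndarray:
    """CAM heatmap: classifier-weighted sum of final conv feature maps.

    The backbone must expose ``feature_maps(batch)`` (N, C, h, w) and
    ``class_weights`` (C, n_classes) — i.e. end in global average pooling
    followed by a linear head.  The weighted map is upsampled to the image
    size and min-max normalized to [0, 1] (an all-zero map stays zero).
    """
    trained_model = getattr(model, "model", model)  # accept TrainedModel or backbone
    if not hasattr(trained_model, "feature_maps") or not hasattr(trained_model, "class_weights"):
        raise TypeError(
            "backbone does not expose GAP feature maps; CAM requires a "
            "global-average-pooled convolutional architecture"
        )
    image = np.asarray(image, dtype=float)
    maps = trained_model.feature_maps(image[None, :, :])[0]  # (C, h, w)
    w = np.asarray(trained_model.class_weights)[:, class_id]
    cam = np.tensordot(w, maps, axes=(0, 0))
    cam = _sk_resize(cam, image.shape, order=1, anti_aliasing=False, preserve_range=True)
    if not normalize:
        return cam
    lo, hi = cam.min(), cam.max()
    if hi == lo:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)
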